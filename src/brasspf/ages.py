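"""Age-group grids for abridged (5-year) demographic schedules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AgeGroupGrid:
    """A contiguous sequence of equal-width age groups.

    Parameters
    ----------
    lower_bounds : tuple of int
        Lower bound (in completed years) of each group, strictly increasing
        and contiguous: ``lower_bounds[i+1] == lower_bounds[i] + width``.
    width : int
        Width of every group in years.

    The default grid is the seven reproductive-age groups 15-19 ... 45-49
    conventional in fertility analysis.
    """

    lower_bounds: tuple = (15, 20, 25, 30, 35, 40, 45)
    width: int = 5

    def __post_init__(self):
        bounds = tuple(int(b) for b in self.lower_bounds)
        object.__setattr__(self, "lower_bounds", bounds)
        if len(bounds) == 0:
            raise ValueError("grid needs at least one age group")
        if self.width <= 0:
            raise ValueError("width must be a positive integer")
        for a, b in zip(bounds, bounds[1:]):
            if b != a + self.width:
                raise ValueError(
                    f"age groups must be contiguous and increasing: "
                    f"{a} followed by {b} with width {self.width}"
                )

    def __len__(self) -> int:
        return len(self.lower_bounds)

    @property
    def labels(self) -> list:
        """Human-readable labels such as ``'15-19'``."""
        return [f"{lo}-{lo + self.width - 1}" for lo in self.lower_bounds]

    @property
    def midpoints(self) -> list:
        """Exact midpoint age of each interval (e.g. 17.5 for 15-19)."""
        return [lo + self.width / 2 for lo in self.lower_bounds]

    def index_of(self, lower: int) -> int:
        """Index of the group whose lower bound is ``lower``."""
        try:
            return self.lower_bounds.index(lower)
        except ValueError:
            raise KeyError(f"no age group starts at {lower}") from None

    def label_of(self, index: int) -> str:
        return self.labels[index]


DEFAULT_GRID = AgeGroupGrid()
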