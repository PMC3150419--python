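"""Fertility and parity schedules on 5-year age groups.

Two measures of childbearing drive the P/F comparison:

* a *period* age-specific fertility schedule (ASFRs estimated from births
  reported in the 12 months before a survey), and
* a *cohort* parity schedule (mean children ever born, CEB, by age group).

ASFRs are stored explicitly on one of two scales.  The ``interval`` scale is
births per woman over the whole 5-year group (the convention of the source
tables, under which the TFR is the plain sum of the schedule); the
``annual`` scale is births per woman per year, one fifth of the interval
value.  The scale is a mandatory field and conversion is always explicit —
a silently misread scale would be a 5-fold error in every downstream number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .ages import AgeGroupGrid, DEFAULT_GRID

INTERVAL = "interval"
ANNUAL = "annual"


def _as_float_array(values, name: str, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{name} must be a 1-d sequence of length {n}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FertilitySchedule:
    """Age-specific fertility rates :math:`f_i` on a 5-year grid.

    Parameters
    ----------
    grid : AgeGroupGrid
    f : array-like
        Non-negative rates, one per age group.
    scale : {"interval", "annual"}
        ``interval``: births per woman over the whole age interval
        (TFR = sum of ``f``); ``annual``: births per woman per year.
    se : array-like, optional
        Standard error of each rate, on the same scale as ``f``.  Required
        only for stochastic adjustment.
    """

    grid: AgeGroupGrid = field(default_factory=lambda: DEFAULT_GRID)
    f: Sequence[float] = ()
    scale: str = INTERVAL
    se: Optional[Sequence[float]] = None

    def __post_init__(self):
        if self.scale not in (INTERVAL, ANNUAL):
            raise ValueError(f"scale must be 'interval' or 'annual', got {self.scale!r}")
        f = _as_float_array(self.f, "f", len(self.grid))
        neg = np.flatnonzero(f < 0)
        if neg.size:
            bad = self.grid.label_of(int(neg[0]))
            raise ValueError(f"negative fertility rate in age group {bad}")
        object.__setattr__(self, "f", f)
        if self.se is not None:
            se = _as_float_array(self.se, "se", len(self.grid))
            if np.any(se < 0):
                raise ValueError("standard errors must be non-negative")
            object.__setattr__(self, "se", se)

    @property
    def tfr(self) -> float:
        """Total fertility rate, the sum of the interval-scale schedule."""
        return float(np.sum(self.to_interval().f))

    def to_interval(self) -> "FertilitySchedule":
        """Return the schedule on the interval scale (multiply annual by width)."""
        if self.scale == INTERVAL:
            return self
        w = self.grid.width
        return replace(
            self,
            f=self.f * w,
            se=None if self.se is None else self.se * w,
            scale=INTERVAL,
        )

    def to_annual(self) -> "FertilitySchedule":
        """Return the schedule on the annual scale (divide interval by width)."""
        if self.scale == ANNUAL:
            return self
        w = self.grid.width
        return replace(
            self,
            f=self.f / w,
            se=None if self.se is None else self.se / w,
            scale=ANNUAL,
        )

    def scaled(self, factor: float) -> "FertilitySchedule":
        """Return a copy with every rate multiplied by ``factor``."""
        return replace(self, f=self.f * factor, se=None)


@dataclass(frozen=True)
class ParitySchedule:
    """Mean children ever born :math:`P_i` by age group.

    ``se`` (standard error of each mean) and ``n`` (women contributing to
    each mean) are optional and only needed for the stochastic method.
    """

    grid: AgeGroupGrid = field(default_factory=lambda: DEFAULT_GRID)
    P: Sequence[float] = ()
    se: Optional[Sequence[float]] = None
    n: Optional[Sequence[int]] = None

    def __post_init__(self):
        P = _as_float_array(self.P, "P", len(self.grid))
        if np.any(P < 0):
            raise ValueError("mean children ever born must be non-negative")
        object.__setattr__(self, "P", P)
        if self.se is not None:
            se = _as_float_array(self.se, "se", len(self.grid))
            if np.any(se < 0):
                raise ValueError("standard errors must be non-negative")
            object.__setattr__(self, "se", se)
        if self.n is not None:
            n = np.asarray(self.n, dtype=int)
            if n.size != len(self.grid):
                raise ValueError("n must have one entry per age group")
            if np.any(n < 1):
                raise ValueError("sample sizes must be >= 1")
            object.__setattr__(self, "n", n)
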