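"""Intrinsic population growth from a fertility/mortality schedule pair.

The discrete Euler-Lotka characteristic equation on 5-year age intervals,

.. math:: \\sum_a e^{-r\\,a_{mid}}\\; L_a\\, m_a = 1,

defines the asymptotic (intrinsic) annual growth rate ``r`` of a
population closed to migration with fixed rates.  ``L_a`` is person-years
lived in interval *a* per birth (radix 1), ``m_a`` the annual rate of
daughter births per woman (``fraction_female x interval ASFR / width``),
and ``a_mid`` the interval midpoint.  Evaluating the left side at
``r = 0`` gives the net reproduction rate (NRR); NRR = 1 exactly when
``r = 0``.  The left side is strictly decreasing in ``r``, so the root is
found by bracketing and Brent's method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ages import AgeGroupGrid
from .schedules import FertilitySchedule

#: daughters per birth under a sex ratio at birth of 105 boys per 100 girls
DEFAULT_FRACTION_FEMALE = 100.0 / 205.0


@dataclass(frozen=True)
class MortalitySchedule:
    """Person-years lived ``L_a`` per 5-year interval per birth (radix 1).

    The grid runs from birth through (at least) the end of reproduction;
    each ``L_a`` lies in ``[0, width]``.
    """

    grid: AgeGroupGrid
    L: Sequence[float] = ()

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if L.size != len(self.grid):
            raise ValueError("L must have one entry per age group")
        if np.any((L < 0) | (L > self.grid.width)):
            raise ValueError(f"each L_a must lie in [0, {self.grid.width}]")
        object.__setattr__(self, "L", L)


@dataclass(frozen=True)
class GrowthResult:
    r_annual: float
    r_pct: float
    nrr: float
    converged: bool
    iterations: int


def _net_maternity(
    fertility: FertilitySchedule,
    mortality: MortalitySchedule,
    fraction_female: float,
):
    """Per-interval net maternity ``φ_a = L_a m_a`` and midpoint ages."""
    fert = fertility.to_interval()
    if fert.grid.width != mortality.grid.width:
        raise ValueError("fertility and mortality grids have different widths")
    m_annual = fraction_female * fert.f / fert.grid.width
    try:
        idx = [mortality.grid.index_of(lo) for lo in fert.grid.lower_bounds]
    except KeyError as exc:
        raise ValueError(f"mortality schedule does not cover the fertile ages: {exc}")
    phi = mortality.L[idx] * m_annual
    a_mid = np.asarray(fert.grid.midpoints)
    return phi, a_mid


def euler_lotka_r(
    fertility: FertilitySchedule,
    mortality: MortalitySchedule,
    fraction_female: float = DEFAULT_FRACTION_FEMALE,
) -> GrowthResult:
    """Solve the discrete Euler-Lotka equation for the intrinsic rate.

    Returns the annual rate ``r`` (and ``100·r``, since growth-rate tables
    are commonly printed in percent) together with the NRR.  The root is
    located by expanding a bracket around zero and polishing with Brent's
    method to a residual below 1e-10.  All-zero fertility has no root
    (``r → -∞``) and raises a ``ValueError``.
    """
    phi, a_mid = _net_maternity(fertility, mortality, fraction_female)
    nrr = float(phi.sum())
    if nrr == 0.0:
        raise ValueError("all-zero net maternity: no finite growth rate (r -> -inf)")

    def g(r):
        return float(np.sum(phi * np.exp(-r * a_mid)) - 1.0)

    lo, hi = -0.5, 0.5
    for _ in range(60):
        if g(lo) > 0 > g(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the Euler-Lotka root")
    r, info = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, full_output=True)
    residual = g(r)
    converged = info.converged and abs(residual) < 1e-10
    return GrowthResult(
        r_annual=float(r),
        r_pct=float(100.0 * r),
        nrr=nrr,
        converged=bool(converged),
        iterations=int(info.iterations),
    )


@dataclass
class SensitivityResult:
    """Growth rates per fertility variant plus pairwise differences."""

    table: pd.DataFrame  # index: variant label; columns: r_annual, r_pct, nrr
    differences: pd.DataFrame  # pairwise r_pct differences (row - column)

    def summary(self) -> str:
        return (
            "Euler-Lotka growth by fertility variant (r in % per year)\n"
            + self.table.to_string()
            + "\n\nPairwise percent-point differences (row - column)\n"
            + self.differences.to_string()
        )


def sensitivity_table(
    variants: Mapping[str, FertilitySchedule],
    mortality: MortalitySchedule,
    fraction_female: float = DEFAULT_FRACTION_FEMALE,
) -> SensitivityResult:
    """Growth-rate sensitivity across alternative fertility estimates.

    Computes ``r`` for each labelled variant against one fixed mortality
    schedule and tabulates all pairwise differences in percentage points —
    the scale on which the impact of choosing one fertility estimate over
    another is usually judged.
    """
    if len(variants) < 2:
        raise ValueError("need at least two fertility variants to compare")
    rows = {}
    for label, fert in variants.items():
        res = euler_lotka_r(fert, mortality, fraction_female)
        rows[label] = {"r_annual": res.r_annual, "r_pct": res.r_pct, "nrr": res.nrr}
    table = pd.DataFrame.from_dict(rows, orient="index")
    labels = list(table.index)
    diffs = pd.DataFrame(
        [[table.loc[a, "r_pct"] - table.loc[b, "r_pct"] for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    return SensitivityResult(table=table, differences=diffs)
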