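"""Monte-Carlo propagation of sampling uncertainty through the P/F ratio.

Both inputs to a P/F ratio are survey estimates with sampling error: the
age-specific fertility risks (a binomial proportion of women reporting a
birth in the last 12 months, treated by its normal approximation) and the
mean children ever born (a sample mean, treated as normal).  Drawing
repeatedly from those input distributions — ASFR groups and the parity mean
sampled independently — and recomputing ``R = P / F`` on each draw yields
an empirical distribution for the adjustment ratio, hence uncertainty
bounds for every adjusted rate and for the TFR.

Two 95%-interval constructions are offered:

``percentile``
    The empirical 2.5th/97.5th percentiles of the ratio draws — the spread
    of the ratio itself, the statistically meaningful interval for a new
    analysis.  This is the default.
``mc_se``
    ``mean ± z · sd/√N_draws`` — uncertainty in the *estimated mean* ratio,
    which shrinks with the number of draws.  Kept because published
    applications of the method have printed bounds of exactly this width.

Because a ratio of independent draws is convex in its denominator, the
Monte-Carlo mean of ``P/F`` exceeds the plug-in ratio ``μ_P/μ_F`` by
approximately ``(μ_P/μ_F)·σ_F²/μ_F²`` (Jensen's inequality, second-order
Taylor term): the stochastic point estimate is systematically a little
larger than the deterministic one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .brass import AdjustedSchedule, BrassPF, BrassPFResults, PFRatioTable
from .schedules import ANNUAL, INTERVAL, FertilitySchedule

logger = logging.getLogger(__name__)

#: draws whose cumulative-fertility denominator falls at or below this are
#: discarded (a ratio against a vanishing denominator is meaningless)
DENOMINATOR_EPS = 1e-9

#: abort if more than this fraction of draws is rejected
MAX_REJECT_FRACTION = 1e-3

BINOMIAL = "binomial_normal_approx"
NORMAL = "normal"


@dataclass(frozen=True)
class RateDistribution:
    """Sampling distribution of one input estimate (a rate or a mean).

    ``kind="binomial_normal_approx"`` marks a proportion whose variance
    came from ``p(1-p)/n`` (requires ``n`` and an annual-scale mean in
    [0, 1]); ``kind="normal"`` is a generic normal with given mean and
    standard error.  ``scale`` declares whether a fertility rate is per
    year or per 5-year interval; conversion is explicit via
    :meth:`to_interval` / :meth:`to_annual`.
    """

    mean: float
    sd: float
    kind: str = NORMAL
    n: Optional[int] = None
    scale: str = INTERVAL

    def __post_init__(self):
        if self.kind not in (BINOMIAL, NORMAL):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.scale not in (INTERVAL, ANNUAL):
            raise ValueError(f"scale must be 'interval' or 'annual', got {self.scale!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.kind == BINOMIAL:
            if self.n is None:
                raise ValueError("binomial_normal_approx requires a sample size n")
            if self.scale == ANNUAL and not 0 <= self.mean <= 1:
                raise ValueError("a binomial annual-scale mean must lie in [0, 1]")

    def to_interval(self, width: int = 5) -> "RateDistribution":
        """Convert an annual-scale rate to the interval scale.

        The mean scales by ``width`` and the variance by ``width²``
        (Var(wX) = w² Var(X)).
        """
        if self.scale == INTERVAL:
            return self
        logger.info(
            "converting rate distribution annual->interval: variance x%d", width**2
        )
        return replace(self, mean=self.mean * width, sd=self.sd * width, scale=INTERVAL)

    def to_annual(self, width: int = 5) -> "RateDistribution":
        if self.scale == ANNUAL:
            return self
        return replace(self, mean=self.mean / width, sd=self.sd / width, scale=ANNUAL)


def binomial_risk_variance(p_hat: float, n: int) -> float:
    """Normal-approximation variance ``p(1-p)/n`` of a binomial proportion.

    ``p_hat`` is the annual-scale proportion of women reporting a birth in
    the last 12 months.  A proportion of exactly 0 or 1 yields zero
    variance and a degenerate-distribution warning.
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError(f"proportion must lie in [0, 1], got {p_hat}")
    if p_hat in (0.0, 1.0):
        warnings.warn(
            f"binomial proportion {p_hat} gives a degenerate (zero-variance) distribution",
            stacklevel=2,
        )
        return 0.0
    return p_hat * (1.0 - p_hat) / n


def binomial_rate_distribution(p_hat: float, n: int, scale: str = ANNUAL) -> RateDistribution:
    """Convenience constructor: annual birth-risk distribution from (p̂, n)."""
    var = binomial_risk_variance(p_hat, n)
    dist = RateDistribution(mean=p_hat, sd=float(np.sqrt(var)), kind=BINOMIAL, n=n, scale=ANNUAL)
    return dist.to_interval() if scale == INTERVAL else dist


def estimate_ceb_distribution(values: Sequence[float]) -> RateDistribution:
    """Sampling distribution of a mean children-ever-born estimate.

    Returns a normal with the sample mean and the standard error of the
    mean, using the maximum-likelihood (1/n) variance: ``sd(x)/√n``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least two children-ever-born values")
    if np.any(arr < 0):
        raise ValueError("children-ever-born counts must be non-negative")
    se = float(arr.std(ddof=0) / np.sqrt(arr.size))
    return RateDistribution(mean=float(arr.mean()), sd=se, kind=NORMAL, n=int(arr.size))


class KSNormalityResult(NamedTuple):
    statistic: float
    p_value: float
    passed: bool  # True when normality is not rejected at the 5% level


def ks_normality_check(values: Sequence[float], alpha: float = 0.05) -> KSNormalityResult:
    """One-sample Kolmogorov-Smirnov check against a fitted normal.

    The reference normal uses the sample's own mean and s.d., which makes
    the test conservative (the Lilliefors caveat); it is advisory only —
    the pipeline proceeds on failure with a logged warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError("need at least 5 values for a normality check")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    passed = bool(p >= alpha)
    if not passed:
        logger.warning(
            "KS normality check rejected (D=%.4f, p=%.4g); proceeding anyway", stat, p
        )
    return KSNormalityResult(float(stat), float(p), passed)


@dataclass(frozen=True)
class RatioDistribution:
    """Monte-Carlo distribution of the selected P/F ratio."""

    mean: float
    sd: float
    n_draws: int
    seed: Optional[int]
    percentiles: dict
    n_rejected: int = 0
    draws: Optional[np.ndarray] = None

    def quantile(self, q) -> np.ndarray:
        if self.draws is None:
            raise ValueError("draws were not retained; cannot compute quantiles")
        return np.quantile(self.draws, q)


def simulate_pf_ratio(
    asfr_dists: Sequence[RateDistribution],
    parity_dist: RateDistribution,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    truncate_negative_draws: bool = False,
    keep_draws: bool = True,
) -> RatioDistribution:
    """Simulate the distribution of ``R = P / F`` at the selected group.

    Parameters
    ----------
    asfr_dists : sequence of RateDistribution
        Interval-scale ASFR distributions for every group up to and
        including the ratio group; each draw of ``F`` is the sum of one
        independent normal draw per group.
    parity_dist : RateDistribution
        Normal distribution of the mean CEB in the ratio group, sampled
        independently of the fertility stream.
    n_draws, seed
        Number of Monte-Carlo draws and RNG seed.  One seeded generator is
        used, consumed in fixed order (ASFR groups ascending, then parity),
        so results are bit-reproducible per seed.
    truncate_negative_draws : bool
        Clip negative ASFR draws from the normal approximation at zero.
        Off by default: the plain normal approximation is used as-is.

    Draws with ``F ≤ 1e-9`` are rejected and counted; more than 0.1% of
    them aborts the simulation.
    """
    if len(asfr_dists) < 1:
        raise ValueError("need at least one ASFR distribution")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for d in asfr_dists:
        if d.scale != INTERVAL:
            raise ValueError(
                "ASFR distributions must be on the interval scale; call .to_interval() first"
            )
    if parity_dist.kind != NORMAL:
        raise ValueError("parity distribution must have kind='normal'")

    rng = np.random.default_rng(seed)
    F = np.zeros(n_draws)
    for d in asfr_dists:  # ascending group order: the documented protocol
        draws = rng.normal(d.mean, d.sd, n_draws)
        if truncate_negative_draws:
            draws = np.maximum(draws, 0.0)
        F += draws
    P = rng.normal(parity_dist.mean, parity_dist.sd, n_draws)

    ok = F > DENOMINATOR_EPS
    n_rejected = int(n_draws - ok.sum())
    if n_rejected > MAX_REJECT_FRACTION * n_draws:
        raise RuntimeError(
            f"{n_rejected}/{n_draws} draws rejected: the cumulative-fertility "
            "denominator distribution is too close to zero for a meaningful ratio"
        )
    if n_rejected:
        logger.warning("rejected %d/%d draws with near-zero denominator", n_rejected, n_draws)
    R = P[ok] / F[ok]
    percentiles = {
        q: float(np.quantile(R, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)
    }
    if R.size > 1 and R.min() == R.max():
        # degenerate (all-zero-sd) limit: report the exact constant so the
        # simulation collapses onto the deterministic ratio bit-for-bit
        mean, sd = float(R[0]), 0.0
    else:
        mean = float(R.mean())
        sd = float(R.std(ddof=1)) if R.size > 1 else 0.0
    return RatioDistribution(
        mean=mean,
        sd=sd,
        n_draws=int(R.size),
        seed=seed,
        percentiles=percentiles,
        n_rejected=n_rejected,
        draws=R if keep_draws else None,
    )


def stochastic_adjust(
    schedule: FertilitySchedule,
    ratio_dist: RatioDistribution,
    interval_mode: str = "percentile",
    level: float = 0.95,
    ratio_index: int = 0,
    clamp_bounds: bool = False,
) -> AdjustedSchedule:
    """Adjust a schedule by a simulated ratio, with uncertainty bounds.

    The point estimate is ``f_i × mean(R)``.  Bounds multiply each rate by
    a lower/upper ratio whose construction depends on ``interval_mode``:
    ``percentile`` uses the empirical (1±level)/2 quantiles of the ratio
    draws (the predictive spread of the ratio); ``mc_se`` uses
    ``mean ± z·sd/√N`` (precision of the estimated mean ratio only — far
    tighter, and the construction matching historically printed tables).
    Bounds are not clamped at zero unless ``clamp_bounds`` is set, so a
    noisy low rate can show a negative lower bound, as the plain normal
    machinery implies.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    sched = schedule.to_interval()
    point_ratio = ratio_dist.mean
    if interval_mode == "mc_se":
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * ratio_dist.sd / np.sqrt(ratio_dist.n_draws)
        r_lo, r_hi = point_ratio - half, point_ratio + half
    elif interval_mode == "percentile":
        if ratio_dist.n_draws < 2:
            raise ValueError("percentile bounds need at least 2 draws")
        lo_q, hi_q = 0.5 - level / 2, 0.5 + level / 2
        r_lo, r_hi = (float(x) for x in ratio_dist.quantile([lo_q, hi_q]))
    else:
        raise ValueError(f"unknown interval_mode {interval_mode!r}")

    f_adj = sched.f * point_ratio
    lower = sched.f * r_lo
    upper = sched.f * r_hi
    tfr = float(sched.f.sum())
    tfr_lower, tfr_upper = tfr * r_lo, tfr * r_hi
    if clamp_bounds:
        lower = np.maximum(lower, 0.0)
        tfr_lower = max(tfr_lower, 0.0)
    return AdjustedSchedule(
        grid=sched.grid,
        f_adj=f_adj,
        tfr_adj=float(f_adj.sum()),
        ratio_used=float(point_ratio),
        ratio_index=int(ratio_index),
        lower=lower,
        upper=upper,
        tfr_lower=float(tfr_lower),
        tfr_upper=float(tfr_upper),
    )


def fit_stochastic(
    model: BrassPF,
    table: PFRatioTable,
    ratio_index: int,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    interval_mode: str = "percentile",
    level: float = 0.95,
    truncate_negative_draws: bool = False,
    clamp_bounds: bool = False,
    keep_draws: bool = True,
) -> "StochasticBrassPFResults":
    """Stochastic fit behind ``BrassPF.fit(method="stochastic")``.

    Requires standard errors on the fertility schedule (groups up to the
    ratio group) and on the parity mean of the ratio group.
    """
    fert = model.fertility
    if fert.se is None:
        raise ValueError(
            "stochastic fit needs fertility standard errors (FertilitySchedule.se)"
        )
    if model.parity.se is None:
        raise ValueError("stochastic fit needs parity standard errors (ParitySchedule.se)")
    asfr_dists = [
        RateDistribution(mean=float(fert.f[i]), sd=float(fert.se[i]), kind=NORMAL)
        for i in range(ratio_index + 1)
    ]
    parity_dist = RateDistribution(
        mean=float(model.parity.P[ratio_index]),
        sd=float(model.parity.se[ratio_index]),
        kind=NORMAL,
        n=None if model.parity.n is None else int(model.parity.n[ratio_index]),
    )
    ratio_dist = simulate_pf_ratio(
        asfr_dists,
        parity_dist,
        n_draws=n_draws,
        seed=seed,
        truncate_negative_draws=truncate_negative_draws,
        keep_draws=keep_draws,
    )
    adjusted = stochastic_adjust(
        fert,
        ratio_dist,
        interval_mode=interval_mode,
        level=level,
        ratio_index=ratio_index,
        clamp_bounds=clamp_bounds,
    )
    return StochasticBrassPFResults(
        model,
        table,
        adjusted,
        ratio_dist,
        interval_mode=interval_mode,
        level=level,
        requested_draws=n_draws,
        truncate_negative_draws=truncate_negative_draws,
        clamp_bounds=clamp_bounds,
    )


class StochasticBrassPFResults(BrassPFResults):
    """Results of a stochastic Brass P/F fit: point estimates plus bounds."""

    def __init__(
        self,
        model,
        pf_ratios,
        adjusted,
        ratio_dist: RatioDistribution,
        interval_mode: str,
        level: float,
        requested_draws: int,
        truncate_negative_draws: bool = False,
        clamp_bounds: bool = False,
    ):
        super().__init__(model, pf_ratios, adjusted)
        self.ratio_dist = ratio_dist
        self.interval_mode = interval_mode
        self.level = level
        self.requested_draws = requested_draws
        self.truncate_negative_draws = truncate_negative_draws
        self.clamp_bounds = clamp_bounds

    @property
    def metadata(self) -> dict:
        return {
            "ratio_mean": self.ratio_dist.mean,
            "ratio_sd": self.ratio_dist.sd,
            "n_draws": self.ratio_dist.n_draws,
            "n_rejected": self.ratio_dist.n_rejected,
            "seed": self.ratio_dist.seed,
            "interval_mode": self.interval_mode,
            "level": self.level,
            "truncate_negative_draws": self.truncate_negative_draws,
            "clamp_bounds": self.clamp_bounds,
        }

    def to_frame(self, emulate_paper_rounding: bool = False):
        from ._utils import round_half_up

        df = super().to_frame().drop(columns=["pf_ratio"])
        df["lower95"] = self.adjusted.lower
        df["upper95"] = self.adjusted.upper
        if emulate_paper_rounding:
            for col in df.columns[1:]:
                df[col] = round_half_up(df[col].to_numpy(), 3)
        return df

    def summary(self) -> str:
        grid = self.model.fertility.grid
        md = self.metadata
        lines = [
            "Brass P/F ratio adjustment (stochastic)",
            f"  ratio group   : {grid.label_of(self.ratio_index)}",
            f"  ratio mean    : {md['ratio_mean']:.3f}  (sd {md['ratio_sd']:.3f})",
            f"  draws         : {md['n_draws']} (rejected {md['n_rejected']}), seed {md['seed']}",
            f"  interval mode : {md['interval_mode']} at level {md['level']}",
            f"  TFR (input)   : {self.model.fertility.tfr:.3f}",
            f"  TFR (adj.)    : {self.tfr_adj:.3f} "
            f"[{self.adjusted.tfr_lower:.3f}, {self.adjusted.tfr_upper:.3f}]",
            "",
            self.to_frame(emulate_paper_rounding=True).to_string(index=False),
        ]
        return "\n".join(lines)
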