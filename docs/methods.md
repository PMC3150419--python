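# Methods

## The deterministic adjustment

`brasspf` implements the two-survey variant of the P/F ratio method: a
period fertility schedule (ASFRs from births reported in the 12 months
before one survey) and a cohort parity schedule (mean children ever born,
CEB, from another survey) on the same 5-year age grid, 15–19 … 45–49.

Schedules are stored on the **interval scale** — births per woman over
the whole 5-year group, five times the annual rate — because that is how
the source tables print them and it makes the TFR a plain sum. The scale
is a mandatory, explicit field with an explicit ×5/÷5 converter; it is
never inferred, since a silent misreading would propagate a five-fold
error.

Cumulative period fertility is the plain prefix sum
`F_i = Σ_{j≤i} f_j`. No parity-equivalent interpolation multipliers
(the k_i coefficients of classical indirect-estimation manuals) are
applied: this package targets the plain-cumulation formulation, which is
what its packaged worked examples use. The ratio `P_i/F_i` is computed per
group; a group with `F_i = 0` is flagged non-computable (NaN) rather than
infinite, and selecting it is an error.

Ratio selection has **no automatic stability heuristic**. The default is
the 25–29 group (P3/F3, the common guideline), with the 20–24 alternative
and an arbitrary fixed index available; the choice is logged. Adjustment
multiplies every rate by the selected, *unrounded* ratio.

**Rounding.** All internal arithmetic is unrounded. A presentation layer
(`emulate_paper_rounding`) rounds half-up to 3 decimals, reproducing the
packaged tables cell-for-cell (e.g. 0.275 × 3.910/2.640 = 0.40729 →
0.407). Cross-population TFR summaries offer the same emulation mode, in
which per-case TFRs are rounded to 3 decimals before differencing — the
arithmetic used when such comparisons are assembled from published
3-decimal tables (this is how the packaged five-province comparison
yields a mean increase of 1.915; full-precision arithmetic gives 1.916).

## Stochastic uncertainty propagation

Inputs are modelled as:

- ASFR per group: binomial proportion of women reporting a birth in the
  last 12 months, via the normal approximation; variance `p(1−p)/n` on
  the annual scale. When converted to the interval scale, the variance is
  multiplied by 25 (`Var(5X) = 25 Var(X)`); the conversion is explicit
  and logged.
- Parity mean: normal with the standard error of the mean. The module
  uses the maximum-likelihood (1/n) sample variance in that standard
  error — indistinguishable from the unbiased version at survey sample
  sizes. A Kolmogorov–Smirnov check against a normal with the
  sample-estimated mean/s.d. is provided as an *advisory* diagnostic; the
  estimated parameters make it conservative (the Lilliefors caveat), and
  it never gates the pipeline.

`simulate_pf_ratio` draws every ASFR group and the parity mean mutually
independently (no covariance structure is modelled) from one seeded
`numpy` Generator, consumed in a fixed documented order — ASFR groups
ascending, then parity — so results are bit-reproducible per seed.
Negative ASFR draws from the normal approximation are **kept** by
default (a truncate-at-zero flag exists and is recorded in the output
metadata); keeping them is the behaviour consistent with normal-theory
bounds that can dip below zero for noisy low rates. Draws whose
denominator `F ≤ 1e−9` are rejected and counted; more than 0.1% of
rejections aborts the run, since the ratio is then dominated by
near-zero denominators.

Because `E[P/F] ≈ (μ_P/μ_F)(1 + σ_F²/μ_F²)` for independent inputs with
small coefficients of variation, the simulated ratio mean sits slightly
*above* the plug-in ratio (Jensen's inequality in the denominator), so
stochastic point estimates systematically exceed deterministic ones. The
tests pin this second-order term against a large-sample brute-force
oracle.

**Interval semantics.** Two 95% constructions are implemented and
labelled explicitly, because they answer different questions:

- `percentile` (default): empirical 2.5th/97.5th percentiles of the
  ratio draws — the uncertainty of the *ratio itself*, the interval a new
  analysis should report;
- `mc_se`: `mean ± z·sd/√N_draws` — the Monte-Carlo precision of the
  *estimated mean* ratio, which shrinks indefinitely with more draws.
  With typical ratio s.d. ≈ 0.4 and 10,000 draws this gives half-widths
  of ~0.009 on the ratio — the construction whose widths match
  historically printed bounds, which is why it is retained as an
  emulation mode.

Bounds are not clamped at zero by default (an optional flag clamps).

## Synthetic microdata generator

`TruePopulationSpec` defines the ground truth: per-group annual fertility
risk, per-group probability that a period birth is *reported*
(underreporting acts only on the 12-month indicator, never on CEB,
mirroring the premise that CEB is reliably recalled; an optional
`ceb_recall_factor` lets tests induce old-age recall decay), sample sizes,
and the CEB model. Defaults describe a DHS-scale survey of a
high-fertility population: constant annual risk giving a true TFR of 4.0
over seven groups, 30% underreporting (factor 0.7) uniform across ages,
10,000 women per group, Poisson CEB.

**CEB alignment.** A woman's expected CEB is the true cumulated interval
fertility through her group. Anchoring it at the *end* of the group
(`interval_end`, the default) makes the identity `E[P_i]/F_i =
1/underreport_factor` exact, so the plain-cumulation adjustment inverts
uniform underreporting in expectation — the property the recovery
experiment tests. Anchoring at the group *midpoint* (`midpoint` option)
is the demographically realistic alternative — women observed
mid-interval have lived only ~2.5 years into it — and reproduces the
systematic shortfall of plain P/F ratios that interpolation-based
refinements exist to absorb. Both conventions are modelling choices about
within-group age heterogeneity; the default keeps the generator aligned
with the estimator it is meant to validate.

CEB counts are Poisson by default (the minimal count model);
a rounded, zero-truncated normal alternative (`ceb_model="normal"`,
dispersion `ceb_noise_sd`) exercises the normality assumption that the
KS diagnostic encodes.

`recovery_experiment` replicates generate → estimate → adjust
(deterministic and stochastic) and reports bias, RMSE, the
deterministic/stochastic ratio gap, and the empirical coverage of the
percentile interval for the true plug-in ratio. At the defaults
(200 replicates, 10,000 draws) it runs in seconds and shows |bias| well
under 1% with coverage within a point or two of 95%. What this does *not*
show: robustness to age-varying underreporting, fertility trends,
migration or mortality effects — none of which the generator models,
because the estimator assumes them away.

## Euler-Lotka growth

The discrete characteristic equation `Σ_a e^{−r·a_mid} L_a m_a = 1` is
solved on 5-year intervals with midpoint ages (`a_mid = lower + 2.5`),
matching how the data arrive; `L_a` is person-years lived per birth
(radix 1, each `L_a ∈ [0, 5]`) and `m_a = fraction_female × f_a/5` is the
annual daughter-birth rate. `fraction_female` defaults to 100/205 (sex
ratio at birth of 105), configurable. The left side is strictly
decreasing in `r`, so the solver expands a bracket around zero and uses
Brent's method (residual < 1e−10); evaluating at `r = 0` gives the NRR,
and `NRR = 1 ⟺ r = 0`. `r` is reported both per year and ×100, since
growth rates are conventionally printed in percent. All-zero fertility
has no finite root and raises. The tests cross-check against an
independent birth-flow Leslie-matrix eigenvalue oracle; the two
conventions agree to O(r²·width²/generation time), far inside 1e−3 per
year for plausible rates.

## Numerical and design notes

- Half-up rounding is implemented on the shortest decimal representation
  of the float (via `decimal`), not on its binary expansion, so
  0.4075 → 0.408 as a printed table would have it.
- The degenerate all-zero-variance simulation detects constant draws and
  returns the constant exactly, collapsing onto the deterministic ratio
  bit-for-bit.
- Grid contiguity, non-negative rates, scale declarations and 0/1 birth
  indicators are validated at construction/read time with the offending
  row or group named.
- The CLI records input checksums, the effective configuration, the seed
  and the package version on every run; per its documented precedence, a
  `--config` YAML file overrides command-line flags.
- Problem sizes used by the shipped validation: 10⁶ draws for the
  Monte-Carlo oracle comparisons, 200 replicates × 10⁴ women per group
  for recovery, 20–25 random schedules for the Leslie cross-check —
  chosen so the full battery completes in well under a minute while
  keeping Monte-Carlo error an order of magnitude below every tolerance.

## Known limitations

- Only the plain-cumulation, single-ratio (B3-style) adjustment is
  implemented: no parity-equivalent interpolation, no changing-fertility
  variants, no mortality/migration bias corrections.
- Independence of input draws is assumed; survey design effects
  (clustering, weights) on variances are out of scope.
- The normal approximation for a binomial proportion is poor for very
  rare births with small n (e.g. a 15–19 group with a handful of
  respondents); the packaged Goa example shows how small samples inflate
  young-age ratios.
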