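# brasspf

Indirect estimation of fertility from imperfect survey data, for
demographers and epidemiologists working where vital registration is
incomplete. `brasspf` implements the Brass Parity/Fertility (P/F) ratio
adjustment of age-specific fertility schedules (the two-source variant that
combines a period fertility survey with a children-ever-born survey),
extends it with Monte-Carlo propagation of the inputs' sampling
uncertainty into 95% bounds on the adjusted rates, and quantifies the
demographic stakes of the adjustment through the Euler-Lotka intrinsic
growth rate.

## The method

Survey-reported births in the last 12 months are notoriously incomplete,
biasing period age-specific fertility rates (ASFRs) downward. Children
ever born (CEB), by contrast, is usually well recalled. For 5-year age
groups *i* = 15–19, …, 45–49:

- **F_i** — cumulated period fertility, the partial sum of interval-scale
  ASFRs: `F_i = Σ_{j≤i} f_j` (so `F_last = TFR`);
- **P_i** — mean CEB of women currently in group *i* (cohort fertility).

Under constant fertility and complete CEB recall, `P_i ≈ F_i`, so the
ratio `P_i/F_i > 1` measures underreporting. One ratio — conventionally
**P3/F3** (ages 25–29) — rescales the whole schedule:

```
f*_i = f_i · (P_3/F_3),    TFR* = (P_3/F_3) · Σ f_i
```

preserving the age pattern while correcting the level.

Both `P_3` and the ASFRs behind `F_3` are survey estimates with sampling
error (binomial for the birth-risk proportions via the normal
approximation, a normal standard error of the mean for CEB). The
stochastic mode draws each input from its sampling distribution
(independently, 10,000 draws by default), recomputes `R = P/F` per draw,
and turns the resulting ratio distribution into bounds on every adjusted
rate. Two interval constructions are provided — empirical percentiles of
the ratio draws (default), and the much tighter `mean ± z·sd/√N_draws`
standard-error-of-the-mean form (`mc_se`) that matches how published
applications have reported bounds — see `docs/methods.md`.

## Worked example

The package ships the five Indian province schedules (SRS 1997 ASFRs, DHS
1998 CEB) as packaged CSV datasets:

```python
from brasspf import BrassPF
from brasspf.datasets import load_province

fert, par = load_province("bihar")
res = BrassPF(fert, par).fit()   # deterministic P3/F3 adjustment
print(res.summary())
```

```
Brass P/F ratio adjustment (deterministic)
  ratio group : 25-29
  P/F ratio   : 1.481
  TFR (input) : 4.360
  TFR (adj.)  : 6.457

age_group  asfr  cum_fertility  ceb  pf_ratio  adjusted_asfr
    15-19 0.275          0.275 1.47     5.345          0.407
    20-24 1.210          1.485 3.50     2.357          1.792
    25-29 1.155          2.640 3.91     1.481          1.711
    30-34 0.890          3.530 5.04     1.428          1.318
    35-39 0.495          4.025 5.59     1.389          0.733
    40-44 0.260          4.285 6.21     1.449          0.385
    45-49 0.075          4.360 6.45     1.479          0.111
```

Reading: observed cumulative fertility by 25–29 is 2.640 children, but
women that age report 3.910 children ever born — a P/F ratio of 1.481,
i.e. roughly a third of recent births go unreported. Scaling the schedule
by that ratio raises the TFR from 4.360 to 6.457 children per woman.
Across the five provinces the adjustment adds 1.915 children to the TFR
on average.

With standard errors on the inputs (`asfr_se`, `ceb_se` columns, or
woman-level microdata via `brasspf.synthetic.estimate_schedules`),
`BrassPF(...).fit(method="stochastic", n_draws=10_000, seed=42)` returns
the same point adjustment plus 95% bounds and the full simulated ratio
distribution.

A `brasspf` command-line tool wraps the same operations
(`adjust`, `adjust-stochastic`, `simulate`, `growth`, `compare-tfr`).

## Synthetic validation

`brasspf.synthetic` generates woman-level survey microdata with known
true fertility, configurable age-specific underreporting of period births
and complete CEB reporting. Because uniform underreporting with complete
CEB makes every expected P/F ratio equal `1/underreport_factor`, the
adjustment should invert the underreporting exactly in expectation —
`recovery_experiment` replicates the full generate → estimate → adjust
pipeline and reports bias, RMSE and interval coverage against the truth.

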