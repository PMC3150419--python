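"""Monte-Carlo ratio propagation: oracles, determinism, interval semantics."""

import numpy as np
import pytest
from scipy import stats

from brasspf import (
    BrassPF,
    FertilitySchedule,
    ParitySchedule,
    RateDistribution,
    RatioDistribution,
    binomial_rate_distribution,
    binomial_risk_variance,
    compute_pf_ratios,
    estimate_ceb_distribution,
    ks_normality_check,
    select_ratio,
    simulate_pf_ratio,
    stochastic_adjust,
)
from brasspf._utils import round_half_up
from brasspf.stochastic import NORMAL

from _oracles import brute_force_ratio_mean

# frozen 1e7-draw brute-force oracle for E[P/F], P~N(4,0.2), F~N(2,0.1);
# the second-order expansion (mu_P/mu_F)(1 + sd_F^2/mu_F^2) gives 2.005
ORACLE_RATIO_MEAN = 2.005041
ORACLE_RATIO_SD = 0.14237


def _dists(means, sds):
    return [RateDistribution(mean=m, sd=s, kind=NORMAL) for m, s in zip(means, sds)]


class TestInputDistributions:
    def test_binomial_variance_analytic(self):
        assert binomial_risk_variance(0.5, 100) == pytest.approx(0.0025)
        assert binomial_risk_variance(0.2, 50) == pytest.approx(0.0032)

    def test_binomial_variance_boundaries(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert binomial_risk_variance(0.0, 50) == 0.0
        with pytest.raises(ValueError):
            binomial_risk_variance(0.5, 0)
        with pytest.raises(ValueError):
            binomial_risk_variance(1.5, 10)

    def test_scale_conversion_multiplies_variance_by_25(self):
        annual = binomial_rate_distribution(0.2, 50)
        interval = annual.to_interval()
        assert interval.mean == pytest.approx(1.0)
        assert interval.sd**2 == pytest.approx(25 * annual.sd**2)
        assert interval.to_annual().sd == pytest.approx(annual.sd)

    def test_binomial_kind_requires_n(self):
        with pytest.raises(ValueError, match="sample size"):
            RateDistribution(mean=0.2, sd=0.01, kind="binomial_normal_approx", scale="annual")

    def test_ceb_distribution_analytic(self):
        d = estimate_ceb_distribution([2, 2, 2, 2])
        assert (d.mean, d.sd) == (2.0, 0.0)
        d = estimate_ceb_distribution([0, 4])
        assert d.mean == 2.0
        assert d.sd == pytest.approx(2.0 / np.sqrt(2))

    def test_ceb_distribution_consistency(self):
        # sample mean of a large Poisson sample lands near the truth
        values = np.random.default_rng(7).poisson(3.0, 1000)
        d = estimate_ceb_distribution(values)
        assert abs(d.mean - 3.0) < 4 * d.sd

    def test_ceb_distribution_rejects_bad_input(self):
        with pytest.raises(ValueError):
            estimate_ceb_distribution([2.0])
        with pytest.raises(ValueError):
            estimate_ceb_distribution([2.0, -1.0])


class TestKSNormality:
    def test_size_under_normal_samples(self):
        rng = np.random.default_rng(42)
        passed = sum(
            ks_normality_check(rng.normal(3, 1, 1000)).passed for _ in range(100)
        )
        # estimated-parameter KS is conservative, so near-universal passes
        assert passed >= 90

    def test_power_against_exponential(self):
        values = np.random.default_rng(0).exponential(1.0, 1000)
        result = ks_normality_check(values)
        assert not result.passed and result.p_value < 0.05

    def test_degenerate_and_short_samples(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality_check([1, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            ks_normality_check([1.0, 2.0])


class TestSimulatePFRatio:
    def test_zero_variance_reproduces_deterministic_ratio(self, bihar):
        fert, par = bihar
        dists = _dists(fert.f[:3], [0, 0, 0])
        parity = RateDistribution(mean=par.P[2], sd=0.0, kind=NORMAL)
        rd = simulate_pf_ratio(dists, parity, n_draws=1000, seed=1)
        _, det = select_ratio(compute_pf_ratios(par, fert))
        assert rd.mean == det
        assert rd.sd == 0.0
        assert round_half_up(rd.mean, 3) == 1.481

    def test_seeded_bit_reproducibility(self):
        dists = _dists([0.3, 1.2, 1.1], [0.02, 0.05, 0.05])
        parity = RateDistribution(mean=3.9, sd=0.1, kind=NORMAL)
        a = simulate_pf_ratio(dists, parity, n_draws=5000, seed=123)
        b = simulate_pf_ratio(dists, parity, n_draws=5000, seed=123)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert (a.mean, a.sd, a.percentiles) == (b.mean, b.sd, b.percentiles)

    def test_mean_matches_brute_force_oracle_and_taylor(self):
        n = 10**6
        rd = simulate_pf_ratio(
            _dists([2.0], [0.1]),
            RateDistribution(mean=4.0, sd=0.2, kind=NORMAL),
            n_draws=n,
            seed=2024,
        )
        mc_se = ORACLE_RATIO_SD / np.sqrt(n)
        assert rd.mean == pytest.approx(ORACLE_RATIO_MEAN, abs=3 * mc_se)
        assert rd.mean == pytest.approx(2.005, abs=3 * mc_se + 1e-4)
        # spot-check the frozen oracle itself at a reduced size
        fresh = brute_force_ratio_mean(4.0, 0.2, 2.0, 0.1, 10**6, seed=5)
        assert fresh == pytest.approx(ORACLE_RATIO_MEAN, abs=4 * mc_se)

    def test_jensen_direction(self):
        # convexity in the denominator inflates the ratio mean above plug-in
        n = 4 * 10**5
        rd = simulate_pf_ratio(
            _dists([2.0], [0.2]),
            RateDistribution(mean=4.0, sd=0.1, kind=NORMAL),
            n_draws=n,
            seed=11,
        )
        plug_in = 4.0 / 2.0
        second_order = plug_in * (0.2 / 2.0) ** 2
        mc_se = rd.sd / np.sqrt(n)
        assert rd.mean > plug_in
        assert rd.mean - plug_in == pytest.approx(second_order, abs=3 * mc_se)

    def test_parity_sd_monotonically_widens_ratio_sd(self):
        dists = _dists([0.3, 1.2, 1.1], [0.01, 0.02, 0.02])
        sds = []
        for parity_sd in (0.05, 0.1, 0.2, 0.4):
            rd = simulate_pf_ratio(
                dists,
                RateDistribution(mean=3.9, sd=parity_sd, kind=NORMAL),
                n_draws=10**5,
                seed=99,
            )
            sds.append(rd.sd)
        assert all(a < b for a, b in zip(sds, sds[1:]))

    def test_near_zero_denominator_aborts(self):
        dists = _dists([0.0], [1e-12])
        parity = RateDistribution(mean=1.0, sd=0.1, kind=NORMAL)
        with pytest.raises(RuntimeError, match="denominator"):
            simulate_pf_ratio(dists, parity, n_draws=1000, seed=3)

    def test_healthy_run_rejects_nothing(self):
        rd = simulate_pf_ratio(
            _dists([2.0], [0.1]),
            RateDistribution(mean=4.0, sd=0.2, kind=NORMAL),
            n_draws=10**4,
            seed=8,
        )
        assert rd.n_rejected == 0 and rd.n_draws == 10**4

    def test_input_validation(self):
        parity = RateDistribution(mean=4.0, sd=0.2, kind=NORMAL)
        with pytest.raises(ValueError, match="interval"):
            simulate_pf_ratio(
                [RateDistribution(mean=0.1, sd=0.01, kind=NORMAL, scale="annual")],
                parity,
                seed=0,
            )
        with pytest.raises(ValueError):
            simulate_pf_ratio([], parity, seed=0)


class TestStochasticAdjust:
    def _ratio_dist(self, mean=1.771, sd=0.439, n_draws=10_000, draws=None):
        return RatioDistribution(
            mean=mean, sd=sd, n_draws=n_draws, seed=0,
            percentiles={0.025: mean - 2 * sd, 0.975: mean + 2 * sd}, draws=draws,
        )

    def test_point_estimate_from_reported_ratio_mean(self, bihar):
        # 20-24 rate 1.210 times a simulated ratio mean of 1.771
        fert, _ = bihar
        adj = stochastic_adjust(fert, self._ratio_dist(), interval_mode="mc_se")
        assert round_half_up(adj.f_adj[1], 3) == 2.143

    def test_mc_se_half_width_closed_form(self, bihar):
        fert, _ = bihar
        adj = stochastic_adjust(fert, self._ratio_dist(), interval_mode="mc_se")
        z = stats.norm.ppf(0.975)
        expected = 1.210 * z * 0.439 / np.sqrt(10_000)
        assert (adj.upper[1] - adj.f_adj[1]) == pytest.approx(expected)
        assert (adj.f_adj[1] - adj.lower[1]) == pytest.approx(expected)
        assert expected == pytest.approx(0.0104, abs=5e-4)

    def test_zero_sd_collapses_bounds(self, bihar):
        fert, _ = bihar
        rd = self._ratio_dist(sd=0.0, draws=np.full(100, 1.771))
        for mode in ("mc_se", "percentile"):
            adj = stochastic_adjust(fert, rd, interval_mode=mode)
            np.testing.assert_allclose(adj.lower, adj.f_adj)
            np.testing.assert_allclose(adj.upper, adj.f_adj)

    def test_percentile_mode_uses_empirical_quantiles(self, bihar):
        fert, _ = bihar
        draws = np.random.default_rng(5).normal(1.8, 0.4, 20_000)
        rd = RatioDistribution(
            mean=float(draws.mean()), sd=float(draws.std(ddof=1)),
            n_draws=draws.size, seed=5, percentiles={}, draws=draws,
        )
        adj = stochastic_adjust(fert, rd, interval_mode="percentile")
        lo, hi = np.quantile(draws, [0.025, 0.975])
        np.testing.assert_allclose(adj.lower, fert.f * lo)
        np.testing.assert_allclose(adj.upper, fert.f * hi)
        assert adj.tfr_lower == pytest.approx(fert.tfr * lo)

    def test_negative_lower_bound_kept_unless_clamped(self):
        sched = FertilitySchedule(f=[0.005, 0.1, 0.2, 0.1, 0.05, 0.01, 0.005])
        draws = np.random.default_rng(1).normal(2.0, 3.0, 10_000)
        rd = RatioDistribution(
            mean=2.0, sd=3.0, n_draws=draws.size, seed=1, percentiles={}, draws=draws,
        )
        free = stochastic_adjust(sched, rd, interval_mode="percentile")
        assert free.lower.min() < 0
        clamped = stochastic_adjust(sched, rd, interval_mode="percentile", clamp_bounds=True)
        assert clamped.lower.min() == 0.0

    def test_bad_mode_and_level(self, bihar):
        fert, _ = bihar
        with pytest.raises(ValueError):
            stochastic_adjust(fert, self._ratio_dist(), interval_mode="bayes")
        with pytest.raises(ValueError):
            stochastic_adjust(fert, self._ratio_dist(), level=1.5)


class TestModelIntegration:
    def _model(self):
        fert = FertilitySchedule(
            f=[0.275, 1.210, 1.155, 0.890, 0.495, 0.260, 0.075],
            se=[0.01, 0.02, 0.02, 0.02, 0.01, 0.01, 0.005],
        )
        par = ParitySchedule(
            P=[1.47, 3.5, 3.91, 5.04, 5.59, 6.21, 6.45],
            se=[0.05, 0.06, 0.07, 0.08, 0.09, 0.1, 0.11],
        )
        return BrassPF(fert, par)

    def test_fit_stochastic_metadata_and_bounds(self):
        res = self._model().fit(method="stochastic", n_draws=5000, seed=42)
        md = res.metadata
        assert md["seed"] == 42 and md["n_draws"] == 5000 and md["n_rejected"] == 0
        assert res.interval_mode == "percentile"
        np.testing.assert_array_less(res.adjusted.lower, res.f_adj)
        np.testing.assert_array_less(res.f_adj, res.adjusted.upper)
        assert "seed" in res.summary()

    def test_mc_se_bounds_much_tighter_than_percentile(self):
        model = self._model()
        wide = model.fit(method="stochastic", n_draws=5000, seed=1)
        tight = model.fit(method="stochastic", n_draws=5000, seed=1, interval_mode="mc_se")
        assert tight.ratio_dist.mean == wide.ratio_dist.mean  # same draws per seed
        assert (tight.adjusted.tfr_upper - tight.adjusted.tfr_lower) < 0.1 * (
            wide.adjusted.tfr_upper - wide.adjusted.tfr_lower
        )

    def test_missing_standard_errors_rejected(self, bihar):
        fert, par = bihar
        with pytest.raises(ValueError, match="standard error"):
            BrassPF(fert, par).fit(method="stochastic", seed=0)


def test_mc_se_half_width_scales_inverse_root_n():
    dists = _dists([0.3, 1.2, 1.1], [0.02, 0.05, 0.05])
    parity = RateDistribution(mean=3.9, sd=0.4, kind=NORMAL)
    sched = FertilitySchedule(f=[0.3, 1.2, 1.1, 0.9, 0.5, 0.25, 0.07])
    widths = {}
    for n in (10**2, 10**4, 10**6):
        rd = simulate_pf_ratio(dists, parity, n_draws=n, seed=77)
        adj = stochastic_adjust(sched, rd, interval_mode="mc_se")
        widths[n] = adj.tfr_upper - adj.tfr_lower
    # each 100-fold increase in draws shrinks the width ~10-fold
    assert widths[10**2] / widths[10**4] == pytest.approx(10, rel=0.2)
    assert widths[10**4] / widths[10**6] == pytest.approx(10, rel=0.2)
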