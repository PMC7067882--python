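import numpy as np
import pytest
from scipy.stats import norm, skewnorm

from mtclock.dating import (CalibrationSpec, DateDistribution, GridSpec,
                            RateDistribution, combine_topologies,
                            fit_skew_normal, node_date_distribution,
                            offset_lognormal_quantiles, rate_distribution)


class TestFitSkewNormal:
    def test_symmetric_input_reduces_to_normal(self):
        spec = fit_skew_normal(4.0, 4.0 - 1.96, 4.0 + 1.96)
        assert abs(spec.shape) < 0.05
        assert abs(spec.location - 4.0) < 0.05
        assert abs(spec.scale - 1.0) < 0.05

    def test_published_calibration_right_skewed(self):
        """4.92 My with CI 3.86-6.92: upper tail longer, so shape > 0 and
        the fitted quantiles reproduce the inputs within 1%."""
        spec = fit_skew_normal(4.92, 3.86, 6.92)
        assert spec.shape > 0
        q = spec.ppf([0.025, 0.5, 0.975])
        np.testing.assert_allclose(q, [3.86, 4.92, 6.92], rtol=0.01)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad

        spec = fit_skew_normal(4.92, 3.86, 6.92)
        val, _ = quad(spec.pdf, -20, 40)
        assert abs(val - 1.0) < 1e-6

    def test_non_monotone_triple_rejected(self):
        with pytest.raises(ValueError):
            fit_skew_normal(4.0, 5.0, 6.0)


class TestOffsetLognormal:
    def test_published_root_prior_median(self):
        _, med, _ = offset_lognormal_quantiles(0.82, 0.33, 2.65)
        assert med == pytest.approx(4.92, rel=0.005)

    def test_unit_median_without_offset(self):
        for s in (0.1, 0.5, 2.0):
            _, med, _ = offset_lognormal_quantiles(0.0, s, 0.0)
            assert med == pytest.approx(1.0, rel=1e-9)

    def test_quantiles_match_sampling_oracle(self):
        rng = np.random.default_rng(8)
        draws = 2.65 + np.exp(rng.normal(0.82, 0.33, size=10**6))
        lo, med, hi = offset_lognormal_quantiles(0.82, 0.33, 2.65)
        emp = np.quantile(draws, [0.025, 0.5, 0.975])
        np.testing.assert_allclose([lo, med, hi], emp, rtol=0.005)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            offset_lognormal_quantiles(0.82, 0.0, 2.65)


class TestDiscreteDistributions:
    def test_quantile_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        grid = np.sort(rng.uniform(0, 100, 50))
        probs = rng.dirichlet(np.ones(50))
        d = DateDistribution(grid, probs)
        qs = d.quantile(np.linspace(0, 1, 33))
        assert np.all(np.diff(qs) >= 0)
        med, lo, hi = d.summary()
        assert lo <= med <= hi

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            DateDistribution([1.0, 2.0], [1.5, -0.5])

    def test_rate_distribution_requires_positive_rates(self):
        with pytest.raises(ValueError):
            RateDistribution([0.0, 1.0], [0.5, 0.5])

    def test_hpd_narrower_than_equal_tail_for_skewed_mass(self):
        grid = np.linspace(1, 100, 200)
        probs = np.exp(-grid / 10.0)
        d = DateDistribution(grid, probs / probs.sum())
        lo, hi = d.hpd(0.95)
        _, eq_lo, eq_hi = d.summary()
        assert (hi - lo) <= (eq_hi - eq_lo) + 1e-9


class TestRateDistribution:
    CAL = fit_skew_normal(4.92e6, 3.86e6, 6.92e6)

    def test_degenerate_limit_concentrates_at_ratio(self):
        cal = fit_skew_normal(4.92e6, 4.9199e6, 4.9201e6)
        rd = rate_distribution(0.05, 1e-9, cal, GridSpec(50, 50, 500))
        med = rd.quantile(0.5)
        assert med == pytest.approx(0.05 / 4.92e6, rel=1e-3)
        lo, hi = rd.quantile(0.001), rd.quantile(0.999)
        assert (hi - lo) / med < 5e-3

    def test_scaling_calibration_halves_rates(self):
        rd1 = rate_distribution(0.05, 0.003, self.CAL)
        cal2 = fit_skew_normal(2 * 4.92e6, 2 * 3.86e6, 2 * 6.92e6)
        rd2 = rate_distribution(0.05, 0.003, cal2)
        for q in (0.025, 0.5, 0.975):
            assert rd2.quantile(q) == pytest.approx(rd1.quantile(q) / 2,
                                                    rel=0.01)

    def test_quantiles_match_monte_carlo_oracle(self):
        h, se = 0.055, 0.0035
        rd = rate_distribution(h, se, self.CAL)
        rng = np.random.default_rng(42)
        n = 10**6
        hs = rng.normal(h, se, n)
        ds = skewnorm.rvs(self.CAL.shape, loc=self.CAL.location,
                          scale=self.CAL.scale, size=n, random_state=rng)
        keep = (hs > h - 5 * se) & (ds > self.CAL.ppf(0.001)) \
            & (ds < self.CAL.ppf(0.999))
        mus = hs[keep] / ds[keep]
        for q in (0.025, 0.5, 0.975):
            assert rd.quantile(q) == pytest.approx(np.quantile(mus, q),
                                                   rel=0.01)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            rate_distribution(0.05, 0.003, self.CAL, GridSpec(1, 50, 100))
        with pytest.raises(ValueError):
            rate_distribution(-0.05, 0.003, self.CAL)


class TestNodeDates:
    CAL = fit_skew_normal(4.92e6, 3.86e6, 6.92e6)

    def test_zero_height_is_point_mass_at_zero(self):
        rd = rate_distribution(0.05, 0.003, self.CAL)
        dd = node_date_distribution(0.0, rd)
        assert dd.quantile(0.5) == 0.0 and dd.quantile(0.999) == 0.0

    def test_point_mass_rate(self):
        rd = RateDistribution([1e-8], [1.0])
        dd = node_date_distribution(7.2e-4, rd)
        assert dd.quantile(0.5) == pytest.approx(7.2e4)

    def test_two_point_rate_gives_two_point_ages(self):
        rd = RateDistribution([1e-8, 2e-8], [0.5, 0.5])
        dd = node_date_distribution(1e-3, rd)
        np.testing.assert_allclose(sorted(dd.grid), [5e4, 1e5])
        np.testing.assert_allclose(dd.probabilities, [0.5, 0.5])

    def test_ages_match_monte_carlo_oracle(self):
        h, se, node_h = 0.055, 0.0035, 8e-4
        rd = rate_distribution(h, se, self.CAL)
        dd = node_date_distribution(node_h, rd)
        rng = np.random.default_rng(4)
        n = 10**6
        hs = rng.normal(h, se, n)
        ds = skewnorm.rvs(self.CAL.shape, loc=self.CAL.location,
                          scale=self.CAL.scale, size=n, random_state=rng)
        keep = (hs > h - 5 * se) & (ds > self.CAL.ppf(0.001)) \
            & (ds < self.CAL.ppf(0.999))
        ages = node_h * ds[keep] / hs[keep]
        for q in (0.025, 0.5, 0.975):
            assert dd.quantile(q) == pytest.approx(np.quantile(ages, q),
                                                   rel=0.01)


class TestCombineTopologies:
    def test_single_topology_identity(self):
        d = DateDistribution([1.0, 2.0, 3.0], [0.2, 0.5, 0.3])
        mix = combine_topologies([d], [1.0])
        np.testing.assert_allclose(mix.grid, d.grid)
        np.testing.assert_allclose(mix.probabilities, d.probabilities)

    def test_identical_distributions_unchanged(self):
        d = DateDistribution([1.0, 2.0], [0.4, 0.6])
        mix = combine_topologies([d, d], [0.3, 0.7])
        for q in (0.1, 0.5, 0.9):
            assert mix.quantile(q) == d.quantile(q)

    def test_point_mass_mixture_quantiles(self):
        d1 = DateDistribution([70e3], [1.0])
        d2 = DateDistribution([140e3], [1.0])
        mix = combine_topologies([d1, d2], [0.8, 0.2])
        med, _, hi = mix.summary()
        assert med == pytest.approx(70e3)
        assert hi == pytest.approx(140e3)

    def test_weights_renormalised(self):
        d1 = DateDistribution([1.0], [1.0])
        d2 = DateDistribution([2.0], [1.0])
        mix = combine_topologies([d1, d2], [2.0, 2.0])
        assert mix.probabilities.sum() == pytest.approx(1.0)

    def test_mismatched_weights_rejected(self):
        d = DateDistribution([1.0], [1.0])
        with pytest.raises(ValueError):
            combine_topologies([d], [0.5, 0.5])
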