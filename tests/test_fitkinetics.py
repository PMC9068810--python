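"""Dwell-time statistics: mixture fits, model selection, analytic checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfqcompete import (
    ConfigurationError,
    DataError,
    FitError,
    access_time_bound,
    bootstrap_errors,
    density_histogram,
    empirical_cdf,
    fit_cdf_exponentials,
    fit_mle_mixture,
    ks_two_sample,
    mean_lifetime,
    select_model,
)


class TestECDF:
    def test_step_values(self):
        F = empirical_cdf([1.0, 2.0, 3.0])
        assert F(2.0) == pytest.approx(2 / 3)
        assert F(0.5) == 0.0
        assert F(3.0) == 1.0

    def test_single_observation_jump(self):
        F = empirical_cdf([5.0])
        assert F(4.999) == 0.0 and F(5.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            empirical_cdf([])


class TestCdfFit:
    def test_single_exponential_recovery(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5.0, 5000)
        fit = fit_cdf_exponentials(t, k=1)
        assert abs(fit.lifetimes[0] - 5.0) < 3 * 5.0 / math.sqrt(5000)

    def test_overfitting_single_exponential_is_harmless(self):
        """k=2 on single-exponential data degenerates: one component vanishes
        or the lifetimes coincide, and the fit barely improves."""
        rng = np.random.default_rng(12)
        t = rng.exponential(5.0, 3000)
        f1 = fit_cdf_exponentials(t, k=1)
        f2 = fit_cdf_exponentials(t, k=2)
        a = min(f2.fractions)
        tau_ratio = f2.lifetimes[1] / max(f2.lifetimes[0], 1e-9)
        assert a < 0.1 or tau_ratio < 1.5
        # the fitted CDF curves are essentially the same function
        grid = np.linspace(0.0, 30.0, 200)

        def cdf(fit):
            return sum(
                frac * (1.0 - np.exp(-grid / max(tau, 1e-9)))
                for frac, tau in zip(fit.fractions, fit.lifetimes)
            )

        assert np.max(np.abs(cdf(f2) - cdf(f1))) < 0.02

    def test_identical_times_degenerate(self):
        with pytest.raises(FitError):
            fit_cdf_exponentials(np.full(50, 2.0), k=1)

    def test_too_few_observations(self):
        with pytest.raises(DataError):
            fit_cdf_exponentials([1.0] * 9, k=1)


class TestMleMixture:
    def test_censored_flags_none_equals_all_false(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(8.0, 500)
        a = fit_mle_mixture(t, None, k=2, resolution=0.0, seed=1)
        b = fit_mle_mixture(t, np.zeros(500, bool), k=2, resolution=0.0, seed=1)
        assert a.loglik == pytest.approx(b.loglik)
        assert a.lifetimes == pytest.approx(b.lifetimes)

    def test_censoring_aware_fit_is_unbiased(self):
        """Truncating at a 300 s window biases the naive mean low; the
        survival-term MLE recovers the true lifetime."""
        rng = np.random.default_rng(14)
        t = rng.exponential(133.0, 4000)
        cens = t > 300.0
        obs = np.minimum(t, 300.0)
        fit = fit_mle_mixture(obs, cens, k=1, resolution=0.0)
        naive = obs.mean()
        se = 133.0 / math.sqrt((~cens).sum())
        assert abs(fit.lifetimes[0] - 133.0) < 3 * se
        assert naive < 120.0  # the uncorrected estimate is clearly biased

    def test_cdf_and_mle_agree_on_large_samples(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(20.0, 5000)
        mle = fit_mle_mixture(t, None, k=1, resolution=0.0)
        cdf = fit_cdf_exponentials(t, k=1)
        assert abs(mle.lifetimes[0] - cdf.lifetimes[0]) / mle.lifetimes[0] < 0.02

    def test_sub_resolution_component_reported_as_zero(self):
        """40% of dwells below the 0.2 s resolution: the fit reports a
        zero-lifetime class whose weight matches that fraction."""
        rng = np.random.default_rng(16)
        n = 4000
        comp = rng.random(n) < 0.4
        t = np.where(comp, rng.exponential(0.02, n), rng.exponential(20.0, n))
        fit = fit_mle_mixture(t, None, k=2, resolution=0.2, seed=2)
        assert fit.lifetimes[0] == 0.0
        se = math.sqrt(0.4 * 0.6 / n)
        assert abs(fit.fractions[0] - 0.4) < 3 * se

    def test_loglik_monotone_in_components(self):
        rng = np.random.default_rng(17)
        comp = rng.random(2000) < 0.5
        t = np.where(comp, rng.exponential(2.0, 2000), rng.exponential(40.0, 2000))
        fits = [fit_mle_mixture(t, None, k=k, resolution=0.0, seed=3) for k in (1, 2, 3)]
        assert fits[0].loglik <= fits[1].loglik + 1e-6
        assert fits[1].loglik <= fits[2].loglik + 1e-6

    def test_fraction_normalisation(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(5.0, 300)
        for k in (1, 2, 3):
            fit = fit_mle_mixture(t, None, k=k, resolution=0.0, seed=4)
            assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-6)


class TestModelSelection:
    def test_single_exponential_data_selects_one(self):
        rng = np.random.default_rng(19)
        t = rng.exponential(10.0, 2000)
        fits = [fit_mle_mixture(t, None, k=k, resolution=0.0, seed=5) for k in (1, 2, 3)]
        assert select_model(fits).chosen_k == 1

    def test_three_well_separated_components_selected(self):
        rng = np.random.default_rng(20)
        n = 10000
        comp = rng.choice(3, n, p=[0.4, 0.4, 0.2])
        taus = np.array([0.5, 13.0, 133.0])
        t = rng.exponential(taus[comp])
        fits = [fit_mle_mixture(t, None, k=k, resolution=0.0, seed=6) for k in (1, 2, 3)]
        assert select_model(fits).chosen_k == 3

    def test_small_samples_lack_power_for_close_lifetimes(self):
        rng = np.random.default_rng(22)
        comp = rng.random(30) < 0.5
        t = np.where(comp, rng.exponential(10.0, 30), rng.exponential(15.0, 30))
        fits = [fit_mle_mixture(t, None, k=k, resolution=0.0, seed=7) for k in (1, 2)]
        assert select_model(fits).chosen_k == 1

    def test_non_nested_inputs_rejected(self):
        rng = np.random.default_rng(22)
        t = rng.exponential(5.0, 100)
        f1 = fit_mle_mixture(t, None, k=1, resolution=0.0)
        f3 = fit_mle_mixture(t, None, k=3, resolution=0.0)
        with pytest.raises(ConfigurationError):
            select_model([f1, f3])


class TestBootstrap:
    def test_same_seed_reproduces_intervals(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(10.0, 400)
        fit = fit_mle_mixture(t, None, k=1, resolution=0.0)
        a = bootstrap_errors(t, None, fit, n_boot=200, seed=9)
        b = bootstrap_errors(t, None, fit, n_boot=200, seed=9)
        assert a.ci_lower == b.ci_lower and a.ci_upper == b.ci_upper

    def test_zero_replicates_rejected(self):
        rng = np.random.default_rng(24)
        t = rng.exponential(10.0, 50)
        fit = fit_mle_mixture(t, None, k=1, resolution=0.0)
        with pytest.raises(ConfigurationError):
            bootstrap_errors(t, None, fit, n_boot=0)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(25)
        t = rng.exponential(10.0, 400)
        fit = fit_mle_mixture(t, None, k=1, resolution=0.0)
        fit = bootstrap_errors(t, None, fit, n_boot=500, seed=10)
        assert fit.ci_lower[0] <= fit.lifetimes[0] <= fit.ci_upper[0]
        assert fit.ci68_lower[0] >= fit.ci_lower[0]
        assert fit.ci68_upper[0] <= fit.ci_upper[0]


class TestDescriptive:
    def test_density_histogram_closed_form(self):
        t = np.concatenate([np.full(50, 0.5), np.full(50, 1.5)])
        density, err = density_histogram(t[:100], [0.0, 1.0])
        # one bin holding half the data: density 0.5, error sqrt(.25/100)
        assert density[0] == pytest.approx(0.5)
        assert err[0] == pytest.approx(0.05)

    def test_density_histogram_normalised(self):
        rng = np.random.default_rng(26)
        t = rng.exponential(3.0, 1000)
        edges = np.linspace(0.0, t.max() + 1e-9, 20)
        density, err = density_histogram(t, edges)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)
        assert np.all(err >= 0)

    def test_density_histogram_empty_bin(self):
        density, err = density_histogram([0.5], [0.0, 1.0, 2.0])
        assert density[1] == 0.0 and err[1] == 0.0

    def test_density_histogram_bad_edges(self):
        with pytest.raises(DataError):
            density_histogram([1.0], [0.0, 0.0, 1.0])

    def test_ks_identical_and_disjoint(self):
        x = np.arange(1.0, 50.0)
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)
        d, _ = ks_two_sample(x, x + 1000.0)
        assert d == 1.0

    def test_ks_matches_brute_force_ecdf(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]
        # brute-force sup over the pooled support
        grid = sorted(set(x) | set(y))
        sup = max(
            abs(sum(v <= g for v in x) / len(x) - sum(v <= g for v in y) / len(y)) for g in grid
        )
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(sup)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1e3), min_size=1, max_size=40),
        st.lists(st.floats(0.01, 1e3), min_size=1, max_size=40),
    )
    def test_ks_statistic_bounded(self, x, y):
        d, p = ks_two_sample(x, y)
        assert 0.0 <= d <= 1.0
        assert 0.0 <= p <= 1.0


class TestAnalytic:
    def test_cell_concentration_endpoints(self):
        bound = access_time_bound(copies=(10, 60), volume_um3=0.5, k_on=2e5)
        assert bound.concentration_low_nM == pytest.approx(33.2, abs=0.05)
        assert bound.concentration_high_nM == pytest.approx(199.3, abs=0.1)

    def test_access_time_endpoints(self):
        bound = access_time_bound(copies=(10, 60), volume_um3=0.5, k_on=2e5)
        assert bound.access_time_min_s == pytest.approx(25.1, abs=0.05)
        assert bound.access_time_max_s == pytest.approx(150.6, abs=0.1)

    def test_kon_scaling(self):
        a = access_time_bound(k_on=2e5)
        b = access_time_bound(k_on=4e5)
        assert b.access_time_min_s == pytest.approx(a.access_time_min_s / 2)
        assert b.concentration_low_nM == a.concentration_low_nM

    def test_mean_lifetime_reciprocal(self):
        assert mean_lifetime(0.06) == pytest.approx(16.7, abs=0.05)
        with pytest.raises(ConfigurationError):
            mean_lifetime(0.0)
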