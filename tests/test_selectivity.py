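"""Gaussian tuning, omega-squared selectivity and intrinsic timescales."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from pfcdev.selectivity import (fit_tuning, intrinsic_timescale, omega_pev,
                                permutation_selectivity_test)
from pfcdev.synthetic import ou_modulated_counts

LOCS = np.arange(8) * 45.0


def _gauss_rates(b1, b2, b3, b4, locs=LOCS):
    d = (locs - b3 + 180) % 360 - 180
    return b1 + b2 * np.exp(-0.5 * (d / b4) ** 2)


def brute_force_omega2(groups):
    """Independent ANOVA oracle: explicit sums over observations."""
    all_x = [x for g in groups for x in g]
    n = len(all_x)
    grand = sum(all_x) / n
    ss_total = sum((x - grand) ** 2 for x in all_x)
    ss_between = 0.0
    for g in groups:
        gm = sum(g) / len(g)
        ss_between += len(g) * (gm - grand) ** 2
    dfb = len(groups) - 1
    mse = (ss_total - ss_between) / (n - len(groups))
    return (ss_between - dfb * mse) / (ss_total + mse)


class TestTuning:
    def test_exact_recovery_noiseless(self):
        rates = _gauss_rates(1.0, 5.0, 180.0, 40.0)
        fit = fit_tuning(LOCS, rates)
        assert fit.baseline_hz == pytest.approx(1.0, abs=1e-6)
        assert fit.amplitude_hz == pytest.approx(5.0, abs=1e-6)
        assert fit.preferred_deg == pytest.approx(180.0, abs=1e-4)
        assert fit.width_deg == pytest.approx(40.0, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_rates_give_zero_amplitude(self):
        fit = fit_tuning(LOCS, np.full(8, 7.0))
        assert fit.amplitude_hz == pytest.approx(0.0, abs=1e-3)

    def test_circular_peak_near_wraparound(self):
        rates = _gauss_rates(2.0, 6.0, 350.0, 30.0)
        fit = fit_tuning(LOCS, rates)
        d = (fit.preferred_deg - 350.0 + 180) % 360 - 180
        assert abs(d) < 2.0

    def test_width_recovery_under_noise(self, rng):
        recovered = []
        for _ in range(200):
            rates = _gauss_rates(2.0, 8.0, 90.0, 40.0) + rng.normal(0, 0.5, 8)
            fit = fit_tuning(LOCS, rates)
            if fit.converged:
                recovered.append(fit.width_deg)
        assert np.mean(recovered) == pytest.approx(40.0, rel=0.10)

    def test_residual_shrinks_with_noise(self, rng):
        errs = []
        for sigma in (1.0, 0.5, 0.1, 0.0):
            rates = _gauss_rates(1.0, 5.0, 135.0, 35.0) + rng.normal(0, sigma, 8)
            fit = fit_tuning(LOCS, rates)
            pred = _gauss_rates(fit.baseline_hz, fit.amplitude_hz,
                                fit.preferred_deg, fit.width_deg)
            errs.append(np.sum((rates - pred) ** 2))
        assert errs == sorted(errs, reverse=True) or errs[-1] < errs[0]

    def test_quality_filter(self):
        fit = fit_tuning(LOCS, _gauss_rates(0.2, 5.0, 90.0, 40.0))
        assert not fit.passes_quality()       # baseline <= 0.5 Hz


class TestOmegaPev:
    def test_hand_computed_example(self):
        res = omega_pev([np.array([1.0, 2, 3]), np.array([5.0, 6, 7])])
        assert res.omega2 == pytest.approx(23.0 / 29.0, abs=1e-12)
        assert res.ss_between == pytest.approx(24.0)
        assert res.ss_total == pytest.approx(28.0)
        assert res.mse == pytest.approx(1.0)
        assert res.df_between == 1

    def test_constant_data_zero(self):
        with pytest.warns(UserWarning):
            res = omega_pev([np.full(3, 2.0), np.full(3, 2.0)])
        assert res.omega2 == 0.0

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=1000, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        groups = [rng.normal(rng.uniform(0, 5), 1.0, rng.integers(2, 8))
                  for _ in range(k)]
        assert omega_pev(groups).omega2 == pytest.approx(
            brute_force_omega2(groups), abs=1e-10)

    def test_bias_correction_null_mean_near_zero(self, rng):
        vals = []
        for _ in range(1000):
            groups = [rng.normal(5, 1, 6) for _ in range(8)]
            vals.append(omega_pev(groups).omega2)
        assert abs(np.mean(vals)) < 0.01


class TestPermutationSelectivity:
    def test_selective_neuron_small_p(self, rng):
        groups = [rng.normal(5 + 3 * (i == 2), 1.0, 10) for i in range(8)]
        _, p = permutation_selectivity_test(groups, n_perm=500, rng=rng)
        assert p <= 0.01

    def test_constant_data_p_one(self, rng):
        groups = [np.full(5, 3.0) for _ in range(4)]
        _, p = permutation_selectivity_test(groups, n_perm=200, rng=rng)
        assert p == 1.0

    def test_null_p_uniform(self):
        ps = []
        for r in range(200):
            rs = np.random.default_rng(4000 + r)
            groups = [rs.normal(10, 2, 8) for _ in range(8)]
            _, p = permutation_selectivity_test(groups, n_perm=200, rng=rs)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.05

    def test_single_group_raises(self, rng):
        with pytest.raises(ValueError):
            permutation_selectivity_test([rng.normal(0, 1, 10)], n_perm=100,
                                         rng=rng)


class TestIntrinsicTimescale:
    def test_white_noise_no_structure(self, rng):
        counts = rng.poisson(0.4, size=(400, 20))
        fit = intrinsic_timescale(counts)
        assert (not fit.included) or fit.amplitude < 0.05

    def test_planted_ou_timescale_recovered(self):
        taus = []
        for rep in range(15):
            counts = ou_modulated_counts(
                0.5, 0.15, 500, 20, np.random.default_rng(600 + rep), depth=0.7)
            fit = intrinsic_timescale(counts)
            if fit.included:
                taus.append(fit.tau_s)
        assert np.median(taus) == pytest.approx(0.15, abs=0.05)

    def test_low_rate_excluded(self, rng):
        counts = rng.poisson(0.025, size=(100, 20))   # 0.5 spikes/s
        fit = intrinsic_timescale(counts)
        assert not fit.included and fit.reason == "low_rate"

    def test_empty_bin_excluded(self, rng):
        counts = rng.poisson(1.0, size=(50, 20))
        counts[:, 7] = 0
        fit = intrinsic_timescale(counts)
        assert not fit.included and fit.reason == "empty_bin"

    def test_slow_timescale_excluded(self):
        counts = ou_modulated_counts(
            0.5, 5.0, 400, 20, np.random.default_rng(9), depth=0.8)
        fit = intrinsic_timescale(counts)
        if not fit.included:
            assert fit.reason in ("slow_timescale", "fit_failure")
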