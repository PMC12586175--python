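"""Penalized-spline mixed trajectory model and derivative inference."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pfcdev.synthetic import logistic
from pfcdev.trajectory import (MaturationTimeline, TrajectoryModel,
                               fdr_correct, fit_trajectory, to_relative_age)


def _cohort_xy(rng, truth_fn, sigma=0.5, n_subj=8, offsets_sd=0.0):
    ages = np.tile(np.arange(-28, 8, 3.0), n_subj)
    subj = np.repeat([f"s{i}" for i in range(n_subj)], 12)
    offs = rng.normal(0, offsets_sd, n_subj) if offsets_sd else np.zeros(n_subj)
    offs -= offs.mean()
    y = truth_fn(ages) + np.repeat(offs, 12) + rng.normal(0, sigma, len(ages))
    return ages, subj, y, offs


class TestRelativeAge:
    def test_anchor_maps_to_zero(self):
        tl = MaturationTimeline({"m1": 57.9})
        assert to_relative_age(57.9, tl, "m1") == 0.0

    @pytest.mark.parametrize("chron,mid,expected", [
        (40.0, 60.0, -20.0), (70.0, 58.0, 12.0)])
    def test_arithmetic(self, chron, mid, expected):
        tl = MaturationTimeline({"m": mid})
        assert to_relative_age(chron, tl, "m") == expected

    def test_unknown_subject(self):
        with pytest.raises(KeyError):
            to_relative_age(40.0, MaturationTimeline({}), "nope")


class TestFdr:
    def test_hand_computed_bh(self):
        adj = fdr_correct([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_correct([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestGaussianFit:
    def test_constant_truth_no_intervals(self, rng):
        ages, subj, y, _ = _cohort_xy(rng, lambda t: np.full_like(t, 3.0),
                                      sigma=0.3)
        m = TrajectoryModel(seed=0, n_draws=4000).fit(ages, y, subject=subj)
        assert np.all(np.abs(m.fitted_ - 3.0) < 0.3)
        assert m.significant_intervals_ == []

    def test_logistic_recovery(self, rng):
        truth = lambda t: logistic(t, 5, 15, -10, 5)
        ages, subj, y, _ = _cohort_xy(rng, truth, sigma=0.5, offsets_sd=1.0)
        m = TrajectoryModel(seed=1).fit(ages, y, subject=subj)
        rmse = np.sqrt(np.mean((m.fitted_ - truth(m.grid_)) ** 2))
        assert rmse < 0.5
        los = [iv[0] for iv in m.significant_intervals_]
        his = [iv[1] for iv in m.significant_intervals_]
        assert min(los) <= -18 and max(his) >= -2

    def test_random_intercept_recovery(self, rng):
        truth = lambda t: 0.1 * t
        ages, subj, y, offs = _cohort_xy(rng, truth, sigma=0.3, offsets_sd=2.0)
        m = TrajectoryModel(seed=2).fit(ages, y, subject=subj)
        est = np.array([m.random_intercepts_[f"s{i}"] for i in range(8)])
        assert np.corrcoef(est, offs)[0, 1] > 0.9

    def test_linear_truth_derivative(self, rng):
        ages, subj, y, _ = _cohort_xy(rng, lambda t: 1.0 * t, sigma=0.3)
        m = TrajectoryModel(seed=3).fit(ages, y, subject=subj)
        # boundary bins wiggle (spline edge effect); check the interior
        interior = slice(len(m.grid_) // 20, -len(m.grid_) // 20)
        assert np.allclose(m.derivative_[interior], 1.0, atol=0.15)
        covered = sum(hi - lo for lo, hi in m.significant_intervals_)
        assert covered > 0.8 * (m.grid_[-1] - m.grid_[0])

    def test_inverted_u_extremum(self, rng):
        truth = lambda t: -0.02 * t ** 2
        ages, subj, y, _ = _cohort_xy(rng, truth, sigma=0.3)
        m = TrajectoryModel(seed=4).fit(ages, y, subject=subj)
        # symmetric peak at 0 recovered up to noise-driven jitter
        assert abs(m.extremum_age_) < 3.0

    def test_row_order_and_relabel_invariance(self, rng):
        truth = lambda t: logistic(t, 0, 4, -8, 4)
        ages, subj, y, _ = _cohort_xy(rng, truth, sigma=0.4, offsets_sd=1.0)
        m1 = TrajectoryModel(seed=5).fit(ages, y, subject=subj)
        perm = rng.permutation(len(ages))
        relabel = {f"s{i}": f"x{7 - i}" for i in range(8)}
        m2 = TrajectoryModel(seed=5).fit(
            ages[perm], y[perm], subject=[relabel[s] for s in subj[perm]])
        assert np.allclose(m1.fitted_, m2.fitted_, atol=1e-6)

    def test_single_subject_reduces_to_penalized_spline(self, rng):
        x = np.linspace(-20, 10, 60)
        y = np.sin(x / 6) + rng.normal(0, 0.2, 60)
        m1 = TrajectoryModel(seed=6, random_effects=False).fit(x, y)
        m2 = TrajectoryModel(seed=6, random_effects=True).fit(
            x, y, subject=["only"] * 60)
        assert np.allclose(m1.fitted_, m2.fitted_, atol=1e-6)

    def test_too_few_ages_raises(self):
        with pytest.raises(ValueError):
            TrajectoryModel().fit([0.0, 1.0], [1.0, 2.0])

    def test_get_set_params_roundtrip(self):
        m = TrajectoryModel(k=8)
        m.set_params(**m.get_params())
        assert m.get_params()["k"] == 8


class TestProportionFamily:
    def test_planted_logit_curve(self, rng):
        ages = np.tile(np.arange(-28, 8, 3.0), 8)
        subj = np.repeat([f"s{i}" for i in range(8)], 12)
        p = logistic(ages, 0.7, 0.88, -10, 6)
        y = rng.binomial(60, p) / 60.0
        m = TrajectoryModel(family="proportion", seed=7).fit(
            ages, y, subject=subj, trials=np.full(len(ages), 60.0))
        truth = logistic(m.grid_, 0.7, 0.88, -10, 6)
        assert np.sqrt(np.mean((m.fitted_ - truth) ** 2)) < 0.03
        assert np.all((m.fitted_ > 0) & (m.fitted_ < 1))

    def test_requires_trials(self):
        with pytest.raises(ValueError, match="trials"):
            TrajectoryModel(family="proportion").fit(
                [0.0, 1, 2, 3], [0.5, 0.5, 0.6, 0.7])


class TestDerivativeCalibration:
    def test_null_false_positive_rate(self):
        """Simultaneous derivative bands: FPR under constant truth."""
        n_sims, fp = 200, 0
        ages = np.tile(np.arange(-28, 8, 3.0), 8)
        subj = np.repeat([f"s{i}" for i in range(8)], 12)
        for r in range(n_sims):
            rs = np.random.default_rng(5000 + r)
            y = rs.normal(0, 1, len(ages))
            m = TrajectoryModel(seed=r, n_draws=3000).fit(ages, y, subject=subj)
            fp += len(m.significant_intervals_) > 0
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert fp / n_sims <= 0.05 + 2 * se

    def test_leave_one_subject_out_sign_stable(self, rng):
        truth = lambda t: logistic(t, 2, 10, -10, 5)
        ages, subj, y, _ = _cohort_xy(rng, truth, sigma=0.5, offsets_sd=1.0)
        for drop in range(8):
            keep = subj != f"s{drop}"
            m = TrajectoryModel(seed=drop, n_draws=3000).fit(
                ages[keep], y[keep], subject=subj[keep])
            assert m.significant_intervals_, "planted effect lost"
            lo, hi = m.significant_intervals_[0]
            mask = (m.grid_ >= lo) & (m.grid_ <= hi)
            assert m.derivative_[mask].mean() > 0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_against_mgcv_reference(rng):
    """Cross-check the penalized-spline fit against R mgcv on one dataset.

    The bases differ (P-spline vs thin plate), so agreement is judged on the
    fitted curve, not coefficients.
    """
    x = np.round(np.linspace(-25, 12, 80), 4)
    y = np.round(logistic(x, 3, 9, -8, 5) + rng.normal(0, 0.4, 80), 4)
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        pd.DataFrame({"x": x, "y": y}).to_csv(td / "d.csv", index=False)
        script = td / "fit.R"
        script.write_text(
            'library(mgcv)\n'
            'd <- read.csv(commandArgs(TRUE)[1])\n'
            'g <- gam(y ~ s(x, k=10), data=d, method="REML")\n'
            'p <- predict(g, newdata=data.frame(x=seq(min(d$x), max(d$x), '
            'length.out=200)))\n'
            'write.csv(data.frame(fit=p), commandArgs(TRUE)[2], '
            'row.names=FALSE)\n')
        out = td / "fit.csv"
        subprocess.run(["Rscript", str(script), str(td / "d.csv"), str(out)],
                       check=True, capture_output=True)
        ref = pd.read_csv(out)["fit"].to_numpy()
    m = TrajectoryModel(seed=0, random_effects=False, n_draws=1000).fit(x, y)
    rmse = np.sqrt(np.mean((m.fitted_ - ref) ** 2))
    assert rmse < 0.15 * np.std(y)
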