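"""Participation-ratio dimensionality and subspace rotation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pfcdev.geometry import (PseudoPopulation, _rotation_one,
                             build_pseudopopulations, fit_plane_normal,
                             full_space_dimensionality, participation_ratio,
                             rotation_angle_deg, subspace_rotation,
                             temporal_dimensionality)
from pfcdev.synthetic import (generate_latent_population,
                              generate_rotated_population)


def iterative_plane_normal(points):
    """Independent oracle: direct distance minimization over normal angles."""
    p = np.asarray(points, dtype=float)
    pc = p - p.mean(axis=0)

    def cost(angles):
        th, ph = angles
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                      np.cos(th)])
        return float(np.sum((pc @ n) ** 2))

    best = None
    for th0 in (0.3, 1.0, 1.8, 2.6):
        for ph0 in (0.0, 1.5, 3.0, 4.5):
            res = minimize(cost, [th0, ph0], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-15,
                                    "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
    th, ph = best.x
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                     np.cos(th)])


class TestParticipationRatio:
    def test_hand_computed(self):
        assert participation_ratio([3.0, 1.0, 0.0]) == pytest.approx(1.6)

    def test_equal_eigenvalues_give_count(self):
        assert participation_ratio([2.0] * 5) == pytest.approx(5.0)

    def test_matches_dense_covariance_oracle(self):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(rng.integers(5, 12), rng.integers(3, 9)))
            res = temporal_dimensionality(x)
            lam = np.linalg.eigvalsh(np.cov(x.T, ddof=1))
            direct = participation_ratio(np.clip(lam, 0, None))
            assert res.n_eff == pytest.approx(direct, abs=1e-8)

    def test_orthogonal_rotation_invariance(self, rng):
        x = rng.normal(size=(20, 10))
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        a = temporal_dimensionality(x).n_eff
        b = temporal_dimensionality(x @ q).n_eff
        assert b == pytest.approx(a, abs=1e-6)

    def test_rank_one_matrix(self, rng):
        profile = rng.normal(size=10)
        x = np.outer(rng.uniform(1, 3, 8), profile)
        assert temporal_dimensionality(x).n_eff == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_warns(self):
        with pytest.warns(UserWarning):
            res = temporal_dimensionality(np.full((8, 10), 3.0))
        assert np.isnan(res.n_eff)


class TestPseudoPopulations:
    def test_partition_covers_all_neurons(self, rng):
        ages = rng.uniform(-30, 20, 200)
        resp = rng.normal(size=(10, 200))
        pops = build_pseudopopulations(ages, resp, n_intervals=20,
                                       min_neurons=5)
        assert sum(p.n_neurons for p in pops) == 200
        for p in pops:
            if p.n_neurons:
                a = ages[[i for i in range(200)
                          if i in set(p.neuron_ids)]]
                assert a.min() >= p.lo_months - 1e-9
                assert a.max() <= p.hi_months + 1e-9

    def test_single_age_degenerate(self):
        pops = build_pseudopopulations(np.zeros(40), np.ones((5, 40)),
                                       n_intervals=20, min_neurons=30)
        eligible = [p for p in pops if p.eligible]
        assert len(eligible) == 1 and eligible[0].n_neurons == 40

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_pseudopopulations([], np.empty((5, 0)))

    def test_cohort_interval_bookkeeping(self, small_cohort):
        neurons = small_cohort["neurons"]
        resp = np.zeros((4, len(neurons)))
        pops = build_pseudopopulations(
            neurons["rel_age_months"].to_numpy(), resp, n_intervals=4,
            min_neurons=1)
        counts = neurons.groupby("rel_age_months").size()
        assert sum(p.n_neurons for p in pops) == counts.sum()


class TestFullSpaceDimensionality:
    def test_rank_one_population_unit_dim(self, rng):
        pattern = rng.normal(size=112)
        resp = np.outer(pattern, rng.uniform(0.5, 2.0, 50))
        pop = PseudoPopulation(0, 0, 1, 0, list(range(50)), resp)
        vals = full_space_dimensionality(pop, n_sub=30, n_boot=50, rng=rng)
        assert np.allclose(vals, 1.0, atol=1e-8)

    def test_planted_dimensionality_recovered(self, rng):
        resp = generate_latent_population(150, 5, noise_sd=0.02, rng=rng)
        pop = PseudoPopulation(0, 0, 1, 0, list(range(150)), resp)
        vals = full_space_dimensionality(pop, n_sub=30, n_boot=500, rng=rng)
        assert abs(np.median(vals) - 5) <= 1.0

    def test_boot_count(self, rng):
        resp = rng.normal(size=(112, 40))
        pop = PseudoPopulation(0, 0, 1, 0, list(range(40)), resp)
        assert len(full_space_dimensionality(pop, 30, 500, rng)) == 500

    def test_ineligible_skipped(self, rng):
        pop = PseudoPopulation(0, 0, 1, 0, list(range(10)),
                               rng.normal(size=(112, 10)), eligible=False)
        with pytest.warns(UserWarning):
            vals = full_space_dimensionality(pop, n_sub=30, n_boot=10, rng=rng)
        assert len(vals) == 0


class TestPlaneFit:
    def test_matches_iterative_minimization(self):
        for seed in range(60):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(rng.integers(4, 8), 3))
            n1 = fit_plane_normal(pts)
            n2 = iterative_plane_normal(pts)
            angle = np.arccos(min(abs(float(n1 @ n2)), 1.0))
            assert angle < 1e-4

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_plane_normal(pts)

    def test_angle_range(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            phi = rotation_angle_deg(a, b)
            assert 0.0 <= phi <= 90.0


class TestSubspaceRotation:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0])
    def test_planted_angle_recovered_noiseless(self, angle, rng):
        mat = generate_rotated_population(30, angle, 0.0, rng)
        phi, _ = _rotation_one(mat)
        assert phi == pytest.approx(angle, abs=1.0)

    def test_identical_epochs_zero_angle(self, rng):
        half = rng.normal(5, 1, size=(4, 30))
        mat = np.vstack([half, half]) + rng.normal(0, 1e-9, size=(8, 30))
        phi, _ = _rotation_one(mat)
        assert phi < 1.0

    def test_bootstrap_recovery_with_noise(self, rng):
        mat = generate_rotated_population(120, 45.0, 0.3, rng)
        pop = PseudoPopulation(0, 0, 1, 0, list(range(120)), mat)
        df = subspace_rotation(pop, n_sub=30, n_boot=500, rng=rng)
        assert np.median(df["phi_deg"]) == pytest.approx(45.0, abs=3.0)

    def test_epoch_symmetry_and_relabeling(self, rng):
        mat = generate_rotated_population(30, 30.0, 0.1, rng)
        phi1, _ = _rotation_one(mat)
        swapped = np.vstack([mat[4:], mat[:4]])
        phi2, _ = _rotation_one(swapped)
        perm = [2, 0, 3, 1]
        relabeled = np.vstack([mat[:4][perm], mat[4:][perm]])
        phi3, _ = _rotation_one(relabeled)
        assert phi2 == pytest.approx(phi1, abs=1e-8)
        assert phi3 == pytest.approx(phi1, abs=1e-8)
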