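"""Nonlinear developmental trajectories with subject-level random effects.

The model is an additive mixed smoother in the GAMM family:

    y_ij = f(age_ij) + a_i + b_i * age_ij + e_ij

where `f` is a low-rank penalized cubic B-spline (P-spline: second-order
difference penalty, a smoothness class equivalent to the usual thin-plate
regression spline for one covariate), and a_i, b_i are per-subject random
intercepts and slopes estimated as ridge-penalized effects.  All smoothing
parameters are chosen by a REML criterion.  Continuous outcomes use a
Gaussian identity link; proportion outcomes (successes out of trials) use a
logit link with a free (quasi-binomial) dispersion estimated from Pearson
residuals.

Inference on the fitted curve follows the simulation approach used for
penalized-spline posteriors: coefficient draws from the approximate Gaussian
posterior give simultaneous 95% bands for the curve and for its
finite-difference derivative; intervals where the simultaneous derivative
band excludes zero are reported as significant developmental change, along
with the age of peak change velocity (max |derivative|) and the age of the
fitted extremum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "MaturationTimeline", "to_relative_age", "TrajectoryModel",
    "TrajectoryFit", "fit_trajectory", "fdr_correct",
]


# ---------------------------------------------------------------------------
# mid-adolescence age alignment
# ---------------------------------------------------------------------------

@dataclass
class MaturationTimeline:
    """Per-subject chronological age (months) at the mid-adolescence anchor
    (distal tibial epiphyseal closure)."""
    mid_adolescence_age_months: dict

    def relative(self, subject, chronological_months: float) -> float:
        if subject not in self.mid_adolescence_age_months:
            raise KeyError(f"unknown subject {subject!r}")
        return float(chronological_months) - float(
            self.mid_adolescence_age_months[subject])


def to_relative_age(chronological_months, timeline: MaturationTimeline, subject):
    """Relative (mid-adolescence-anchored) age in months; anchor maps to 0."""
    return timeline.relative(subject, chronological_months)


def fdr_correct(p_values):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    """Fitted trajectory of one measure vs. relative age."""
    grid: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray            # pointwise 95%
    band_upper: np.ndarray
    sim_lower: np.ndarray             # simultaneous 95%
    sim_upper: np.ndarray
    derivative: np.ndarray
    significant_intervals: list       # [(lo, hi) months] where deriv band != 0
    monotonic_intervals: list         # significant and single-signed
    peak_velocity_age: float
    extremum_age: float
    smooth_f: float
    smooth_p: float
    family: str
    edf: float
    random_intercepts: dict = field(default_factory=dict)
    random_slopes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "fitted": self.fitted.tolist(),
            "band_lower": self.band_lower.tolist(),
            "band_upper": self.band_upper.tolist(),
            "sim_lower": self.sim_lower.tolist(),
            "sim_upper": self.sim_upper.tolist(),
            "derivative": self.derivative.tolist(),
            "significant_intervals": [list(iv) for iv in self.significant_intervals],
            "monotonic_intervals": [list(iv) for iv in self.monotonic_intervals],
            "peak_velocity_age": self.peak_velocity_age,
            "extremum_age": self.extremum_age,
            "smooth_f": self.smooth_f,
            "smooth_p": self.smooth_p,
            "family": self.family,
            "edf": self.edf,
        }


class TrajectoryModel:
    """Penalized-spline mixed-effects trajectory smoother (fit/predict).

    Parameters
    ----------
    k : spline basis dimension (default 10; reduced automatically when the
        data have fewer distinct ages).
    grid_size : prediction-grid resolution over the observed age range.
    random_effects : include per-subject random intercepts and slopes.
    family : "gaussian" or "proportion" (logit link, quasi dispersion).
    n_draws : posterior coefficient draws for simultaneous bands.
    deriv_step_frac : finite-difference step as a fraction of grid spacing.
    """

    def __init__(self, k: int = 10, grid_size: int = 200,
                 random_effects: bool = True, family: str = "gaussian",
                 n_draws: int = 10000, deriv_step_frac: float = 0.1,
                 seed: int = 0):
        if family not in ("gaussian", "proportion"):
            raise ValueError("family must be 'gaussian' or 'proportion'")
        self.k = k
        self.grid_size = grid_size
        self.random_effects = random_effects
        self.family = family
        self.n_draws = n_draws
        self.deriv_step_frac = deriv_step_frac
        self.seed = seed

    # -- sklearn-style param plumbing ------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in
                ("k", "grid_size", "random_effects", "family", "n_draws",
                 "deriv_step_frac", "seed")}

    def set_params(self, **params):
        for name, value in params.items():
            if not hasattr(self, name):
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    # -- basis ------------------------------------------------------------
    def _spline_design(self, x: np.ndarray) -> np.ndarray:
        """Constrained spline design: raw B-spline columns projected onto the
        complement of the constant coefficient direction (B-splines sum to 1
        row-wise, so the unconstrained block would be confounded with the
        intercept)."""
        b = BSpline.design_matrix(
            np.clip(x, self._xlo, self._xhi), self._knots, 3).toarray()
        return b @ self._Z

    def _design(self, x: np.ndarray, subjects=None) -> np.ndarray:
        b = self._spline_design(x) - self._b_means
        cols = [np.ones((len(x), 1)), b]
        if self._m > 0:
            zi = np.zeros((len(x), self._m))
            zs = np.zeros((len(x), self._m))
            if subjects is not None:
                idx = np.array([self._subj_index[s] for s in subjects])
                rows = np.arange(len(x))
                zi[rows, idx] = 1.0
                zs[rows, idx] = (x - self._x_center) / self._x_scale
            cols.extend([zi, zs])
        return np.hstack(cols)

    # -- penalized weighted least squares --------------------------------
    def _fit_plws(self, z, w, lam) -> tuple:
        s_diag = np.zeros(self._p)
        sl = slice(1, 1 + self._kk)
        S = np.zeros((self._p, self._p))
        S[sl, sl] = lam[0] * self._S_spline
        if self._m > 0:
            S[np.arange(1 + self._kk, 1 + self._kk + self._m),
              np.arange(1 + self._kk, 1 + self._kk + self._m)] = lam[1]
            S[np.arange(1 + self._kk + self._m, self._p),
              np.arange(1 + self._kk + self._m, self._p)] = lam[2]
        XtW = self._X.T * w
        A = XtW @ self._X + S
        A.flat[:: self._p + 1] += 1e-10
        beta = np.linalg.solve(A, XtW @ z)
        return beta, A, S

    def _reml(self, rho, z, w) -> float:
        lam = np.exp(np.clip(rho, -20, 25))
        if self._m == 0:
            lam = np.array([lam[0], 0.0, 0.0])
        beta, A, S = self._fit_plws(z, w, lam)
        resid = z - self._X @ beta
        P = float(resid @ (w * resid) + beta @ S @ beta)
        n, mp = len(z), self._null_dim
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        logdet_s = (self._rank_spline * math.log(lam[0]) + self._logdet_spline)
        if self._m > 0:
            logdet_s += self._m * (math.log(lam[1]) + math.log(lam[2]))
        return (n - mp) * math.log(max(P, 1e-300)) + logdet_a - logdet_s

    def _optimize_lambda(self, z, w, rho0) -> np.ndarray:
        ndim = 1 if self._m == 0 else 3
        res = minimize(lambda r: self._reml(np.resize(r, 3), z, w),
                       rho0[:ndim], method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-4})
        return np.resize(res.x, 3)

    # -- fitting ----------------------------------------------------------
    def fit(self, rel_age, y, subject=None, trials=None):
        x = np.asarray(rel_age, dtype=float)
        yv = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(yv))
        if trials is not None:
            trials = np.asarray(trials, dtype=float)
            ok &= ~np.isnan(trials) & (trials > 0)
            trials = trials[ok]
        x, yv = x[ok], yv[ok]
        subjects = None
        if subject is not None:
            subjects = np.asarray(subject, dtype=object)[ok]
        n = len(x)
        distinct = np.unique(x)
        if len(distinct) < 3:
            raise ValueError("need >= 3 distinct relative ages")
        kk = self.k
        if len(distinct) < kk:
            kk = max(4, len(distinct))
            warnings.warn(f"basis dimension reduced to k={kk} "
                          f"({len(distinct)} distinct ages)")
        self._xlo, self._xhi = float(x.min()), float(x.max())
        interior = np.linspace(self._xlo, self._xhi, kk - 2)[1:-1]
        self._knots = np.concatenate([[self._xlo] * 4, interior, [self._xhi] * 4])
        # orthonormal complement of the all-ones coefficient direction
        _, _, vt = np.linalg.svd(np.ones((1, kk)))
        self._Z = vt[1:].T                       # (kk, kk - 1)
        self._kk = kk - 1                        # constrained block size
        self._b_means = 0.0
        self._b_means = self._spline_design(x).mean(axis=0)

        d2 = np.diff(np.eye(kk), n=2, axis=0)
        self._S_spline = self._Z.T @ (d2.T @ d2) @ self._Z
        ev = np.linalg.eigvalsh(self._S_spline)
        pos = ev[ev > 1e-10 * ev.max()]
        self._rank_spline = len(pos)
        self._logdet_spline = float(np.sum(np.log(pos)))

        use_re = self.random_effects and subjects is not None
        if use_re:
            self._subj_levels = list(pd.unique(subjects))
            if len(self._subj_levels) < 2:
                use_re = False
        if use_re:
            self._subj_index = {s: i for i, s in enumerate(self._subj_levels)}
            self._m = len(self._subj_levels)
            self._x_center = float(x.mean())
            self._x_scale = float(x.std()) or 1.0
        else:
            self._m = 0
            self._x_center, self._x_scale = 0.0, 1.0
            self._subj_levels, self._subj_index = [], {}
        # unpenalized null space: intercept + linear trend
        self._null_dim = 2
        self._X = self._design(x, subjects if use_re else None)
        self._p = self._X.shape[1]

        if self.family == "gaussian":
            w = np.ones(n)
            rho = self._optimize_lambda(yv, w, np.zeros(3))
            lam = np.exp(np.clip(rho, -20, 25))
            if self._m == 0:
                lam = np.array([lam[0], 0.0, 0.0])
            beta, A, S = self._fit_plws(yv, w, lam)
            resid = yv - self._X @ beta
            P = float(resid @ resid + beta @ S @ beta)
            self.sigma2_ = P / (n - self._null_dim)
            self.dispersion_ = self.sigma2_
            self._w = w
        else:
            if trials is None:
                raise ValueError("family='proportion' requires trials counts")
            p_obs = np.clip(yv, 1e-4, 1 - 1e-4)
            eta = logit(p_obs)
            rho = np.zeros(3)
            beta = None
            for _ in range(60):
                mu = expit(np.clip(eta, -30, 30))
                var = mu * (1 - mu)
                w = trials * var
                z = eta + (yv - mu) / var
                rho = self._optimize_lambda(z, w, rho)
                lam = np.exp(np.clip(rho, -20, 25))
                if self._m == 0:
                    lam = np.array([lam[0], 0.0, 0.0])
                beta_new, A, S = self._fit_plws(z, w, lam)
                eta_new = self._X @ beta_new
                done = beta is not None and np.max(np.abs(eta_new - eta)) < 1e-8
                beta, eta = beta_new, eta_new
                if done:
                    break
            mu = expit(np.clip(eta, -30, 30))
            pear2 = trials * (yv - mu) ** 2 / (mu * (1 - mu))
            self._w = w
            Ainv = np.linalg.inv(A)
            edf = float(np.trace(Ainv @ (self._X.T * w) @ self._X))
            self.dispersion_ = float(np.sum(pear2) / max(n - edf, 1.0))
            self.sigma2_ = self.dispersion_

        self.lambda_ = lam
        self.coef_ = beta
        Ainv = np.linalg.inv(A)
        self._Vb = self.sigma2_ * Ainv
        self.edf_ = float(np.trace(Ainv @ (self._X.T * self._w) @ self._X))
        self._n = n
        if self._m > 0:
            bi = beta[1 + self._kk: 1 + self._kk + self._m]
            bsl = beta[1 + self._kk + self._m:]
            self.random_intercepts_ = dict(zip(self._subj_levels, bi))
            self.random_slopes_ = dict(
                zip(self._subj_levels, bsl / self._x_scale))
        else:
            self.random_intercepts_, self.random_slopes_ = {}, {}
        self._infer()
        return self

    # -- posterior inference on the population curve ----------------------
    def _infer(self):
        kk = self._kk
        grid = np.linspace(self._xlo, self._xhi, self.grid_size)
        nf = 1 + kk                       # intercept + spline block
        Xg = np.hstack([np.ones((len(grid), 1)),
                        self._spline_design(grid) - self._b_means])
        h = (grid[1] - grid[0]) * self.deriv_step_frac
        Bd = (self._spline_design(grid + h)
              - self._spline_design(grid - h)) / (2 * h)
        Xd = np.hstack([np.zeros((len(grid), 1)), Bd])

        beta_f = self.coef_[:nf]
        Vf = self._Vb[:nf, :nf]
        eta = Xg @ beta_f
        d_eta = Xd @ beta_f
        se = np.sqrt(np.maximum(np.sum(Xg @ Vf * Xg, axis=1), 0.0))
        se_d = np.sqrt(np.maximum(np.sum(Xd @ Vf * Xd, axis=1), 0.0))

        rng = substream(self.seed, "trajectory_posterior")
        ev, U = np.linalg.eigh((Vf + Vf.T) / 2)
        L = U * np.sqrt(np.clip(ev, 0.0, None))
        draws = L @ rng.standard_normal((nf, self.n_draws))   # (nf, n_draws)
        dev_f = Xg @ draws
        dev_d = Xd @ draws
        with np.errstate(invalid="ignore", divide="ignore"):
            t_f = np.nanmax(np.abs(dev_f) / np.where(se > 0, se, np.nan)[:, None],
                            axis=0)
            t_d = np.nanmax(np.abs(dev_d) / np.where(se_d > 0, se_d, np.nan)[:, None],
                            axis=0)
        crit_f = float(np.nanquantile(t_f, 0.95))
        crit_d = float(np.nanquantile(t_d, 0.95))

        if self.family == "proportion":
            mean = expit(eta)
            band = (expit(eta - 1.96 * se), expit(eta + 1.96 * se))
            sim = (expit(eta - crit_f * se), expit(eta + crit_f * se))
            deriv = d_eta * mean * (1 - mean)   # chain rule on response scale
        else:
            mean = eta
            band = (eta - 1.96 * se, eta + 1.96 * se)
            sim = (eta - crit_f * se, eta + crit_f * se)
            deriv = d_eta

        d_lo = d_eta - crit_d * se_d
        d_hi = d_eta + crit_d * se_d
        sig_mask = (d_lo > 0) | (d_hi < 0)
        intervals, monotone = [], []
        i = 0
        while i < len(grid):
            if not sig_mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grid) and sig_mask[j + 1]:
                j += 1
            intervals.append((float(grid[i]), float(grid[j])))
            signs = np.sign(d_eta[i:j + 1])
            if np.all(signs > 0) or np.all(signs < 0):
                monotone.append((float(grid[i]), float(grid[j])))
            i = j + 1

        self.grid_ = grid
        self.fitted_ = mean
        self.se_ = se
        self.band_lower_, self.band_upper_ = band
        self.sim_lower_, self.sim_upper_ = sim
        self.derivative_ = deriv
        self.derivative_se_ = se_d
        self.derivative_sim_crit_ = crit_d
        self.significant_intervals_ = intervals
        self.monotonic_intervals_ = monotone
        self.peak_velocity_age_ = float(grid[np.argmax(np.abs(deriv))])
        self.extremum_age_ = float(grid[np.argmax(mean)])

        # approximate Wald test of the smooth term (spline block)
        beta_s = self.coef_[1:1 + self._kk]
        Vs = self._Vb[1:1 + self._kk, 1:1 + self._kk]
        evs = np.linalg.eigvalsh((Vs + Vs.T) / 2)
        r = int(np.sum(evs > 1e-8 * max(evs.max(), 1e-300)))
        r = max(r, 1)
        stat = float(beta_s @ np.linalg.pinv(Vs, rcond=1e-8) @ beta_s)
        self.smooth_f_ = stat / r
        df2 = max(self._n - self.edf_, 1.0)
        self.smooth_p_ = float(f_dist.sf(self.smooth_f_, r, df2))

    def predict(self, rel_age, subject=None) -> np.ndarray:
        """Population-curve prediction (random effects at zero unless
        `subject` supplies known levels)."""
        x = np.asarray(rel_age, dtype=float)
        subj = None
        if subject is not None and self._m > 0:
            subj = np.asarray(subject, dtype=object)
        X = self._design(x, subj)
        eta = X @ self.coef_
        return expit(eta) if self.family == "proportion" else eta

    def result(self) -> TrajectoryFit:
        return TrajectoryFit(
            grid=self.grid_, fitted=self.fitted_,
            band_lower=self.band_lower_, band_upper=self.band_upper_,
            sim_lower=self.sim_lower_, sim_upper=self.sim_upper_,
            derivative=self.derivative_,
            significant_intervals=self.significant_intervals_,
            monotonic_intervals=self.monotonic_intervals_,
            peak_velocity_age=self.peak_velocity_age_,
            extremum_age=self.extremum_age_,
            smooth_f=self.smooth_f_, smooth_p=self.smooth_p_,
            family=self.family, edf=self.edf_,
            random_intercepts=self.random_intercepts_,
            random_slopes=self.random_slopes_)


def fit_trajectory(points: pd.DataFrame, family: str = "gaussian",
                   k: int = 10, grid_size: int = 200, n_draws: int = 10000,
                   random_effects: bool = True, seed: int = 0) -> TrajectoryFit:
    """Fit one measure's developmental trajectory from a long-format table.

    `points` needs columns subject, rel_age_months, value (and n_trials for
    proportion outcomes).
    """
    model = TrajectoryModel(k=k, grid_size=grid_size, family=family,
                            random_effects=random_effects, n_draws=n_draws,
                            seed=seed)
    trials = points["n_trials"] if (family == "proportion"
                                    and "n_trials" in points) else None
    model.fit(points["rel_age_months"], points["value"],
              subject=points["subject"] if "subject" in points else None,
              trials=trials)
    return model.result()
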