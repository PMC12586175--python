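"""Single-neuron selectivity and intrinsic-timescale estimation.

* Gaussian tuning of firing rate over the eight cue locations,
  f(loc) = b1 + b2 * exp(-0.5 ((loc - b3) / b4)^2), fitted by nonlinear
  least squares after re-centering the circle on the empirical peak.
* Bias-corrected omega-squared percent explained variance (wPEV),
  w2 = (SS_between - df_between * MSE) / (SS_total + MSE),
  with a label-shuffling permutation test.
* Intrinsic timescale from the across-trial autocorrelation of baseline
  spike counts (50-ms bins over the 1-s pre-cue fixation), fitted with
  R(lag) = A * exp(-lag / tau) + B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._rng import substream

__all__ = [
    "TuningFit", "OmegaPEVResult", "TimescaleFit",
    "fit_tuning", "omega_pev", "permutation_selectivity_test",
    "intrinsic_timescale", "neuron_selectivity_table",
]


# ---------------------------------------------------------------------------
# Gaussian tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningFit:
    baseline_hz: float        # b1
    amplitude_hz: float       # b2
    preferred_deg: float      # b3, in original circle coordinates [0, 360)
    width_deg: float          # b4 (> 0)
    r_squared: float
    converged: bool

    def passes_quality(self, r2_min: float = 0.5, baseline_min_hz: float = 0.5) -> bool:
        """Downstream inclusion rule: drop low-rate or poorly fitted neurons."""
        return (self.converged and self.r_squared >= r2_min
                and self.baseline_hz > baseline_min_hz)


def _gauss(loc, b1, b2, b3, b4):
    return b1 + b2 * np.exp(-0.5 * ((loc - b3) / b4) ** 2)


def fit_tuning(locations_deg, rates_hz) -> TuningFit:
    """Fit a Gaussian tuning curve to per-location mean rates.

    Locations are circular; the data are re-centered so the max-rate location
    sits at 0 and the remaining locations are unwrapped into (-180, 180]
    before fitting the (non-periodic) Gaussian.
    """
    loc = np.asarray(locations_deg, dtype=float)
    r = np.asarray(rates_hz, dtype=float)
    if len(loc) != len(r) or len(loc) < 5:
        raise ValueError("need matched locations and rates (>= 5 points)")
    peak = loc[np.argmax(r)]
    x = (loc - peak + 180.0) % 360.0 - 180.0   # peak at 0, range (-180, 180]
    rng_amp = float(r.max() - r.min())
    p0 = (float(r.min()), max(rng_amp, 1e-3), 0.0, 45.0)
    bounds = ([-np.inf, 0.0, -180.0, 5.0], [np.inf, np.inf, 180.0, 180.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, _ = curve_fit(_gauss, x, r, p0=p0, bounds=bounds, maxfev=5000)
        converged = True
    except (RuntimeError, ValueError):
        return TuningFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    resid = r - _gauss(x, *beta)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    preferred = (beta[2] + peak) % 360.0
    return TuningFit(float(beta[0]), float(beta[1]), float(preferred),
                     float(beta[3]), r2, converged)


# ---------------------------------------------------------------------------
# omega-squared percent explained variance
# ---------------------------------------------------------------------------

@dataclass
class OmegaPEVResult:
    omega2: float
    ss_between: float
    ss_total: float
    mse: float
    df_between: int


def omega_pev(groups: Sequence[np.ndarray]) -> OmegaPEVResult:
    """Bias-corrected omega-squared from observations grouped by condition.

    One-way ANOVA decomposition; the bias correction subtracts the expected
    between-group sum of squares under the null, so the statistic averages
    to ~0 for unselective data (and may be negative).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_x = np.concatenate(groups)
    n_total = len(all_x)
    grand = all_x.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_total = float(np.sum((all_x - grand) ** 2))
    ss_within = ss_total - ss_between
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    mse = ss_within / df_within
    if ss_total == 0:
        warnings.warn("zero total variance; omega2 set to 0")
        return OmegaPEVResult(0.0, ss_between, ss_total, mse, df_between)
    omega2 = (ss_between - df_between * mse) / (ss_total + mse)
    return OmegaPEVResult(float(omega2), ss_between, ss_total, mse, df_between)


def _omega2_from_values(values: np.ndarray, group_idx: list) -> float:
    """omega2 for fixed group membership positions, vectorized over rows.

    `values` is (n_perm, N); `group_idx` lists the column indices of each
    group.  Returns an (n_perm,) array.
    """
    n_total = values.shape[1]
    k = len(group_idx)
    grand = values.mean(axis=1)
    ss_total = ((values - grand[:, None]) ** 2).sum(axis=1)
    ss_between = np.zeros(values.shape[0])
    for idx in group_idx:
        gm = values[:, idx].mean(axis=1)
        ss_between += len(idx) * (gm - grand) ** 2
    mse = (ss_total - ss_between) / (n_total - k)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ss_between - (k - 1) * mse) / (ss_total + mse)
    return np.where(ss_total > 0, out, 0.0)


def permutation_selectivity_test(
    groups: Sequence[np.ndarray],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple:
    """Permutation p-value for omega2 selectivity (labels shuffled within neuron).

    p = (1 + #{shuffled w2 >= observed}) / (1 + n_perm).
    Returns (observed omega2, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = omega_pev(groups).omega2
    groups = [np.asarray(g, dtype=float) for g in groups]
    values = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    edges = np.cumsum([0] + sizes)
    group_idx = [np.arange(edges[i], edges[i + 1]) for i in range(len(sizes))]
    if rng is None:
        rng = substream(seed, "permutation_selectivity")
    perm_vals = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    null = _omega2_from_values(perm_vals, group_idx)
    p = (1 + int(np.count_nonzero(null >= obs))) / (1 + n_perm)
    return obs, float(p)


# ---------------------------------------------------------------------------
# intrinsic timescale
# ---------------------------------------------------------------------------

@dataclass
class TimescaleFit:
    amplitude: float
    tau_s: float
    offset: float
    included: bool
    reason: str            # "" when included; machine-readable code otherwise
    lags_s: Optional[np.ndarray] = None
    autocorr: Optional[np.ndarray] = None


def _exp_decay(x, a, tau, b):
    return a * np.exp(-x / tau) + b


def intrinsic_timescale(
    counts: np.ndarray,
    bin_s: float = 0.05,
    min_rate_hz: float = 1.0,
    tau_max_s: float = 0.5,
) -> TimescaleFit:
    """Intrinsic timescale from baseline spike counts (trials x bins).

    The across-trial covariance between every pair of bins is averaged per
    lag and normalized by the total count variance; an exponential decay is
    fitted over lags >= 1 bin.  Exclusion rules: mean rate below
    `min_rate_hz`, any bin empty across all trials, non-convergent fit, or
    fitted tau above `tau_max_s`.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be (trials, bins)")
    n_trials, n_bins = x.shape
    rate = x.sum() / (n_trials * n_bins * bin_s)
    if rate < min_rate_hz:
        return TimescaleFit(np.nan, np.nan, np.nan, False, "low_rate")
    if np.any(x.sum(axis=0) == 0):
        return TimescaleFit(np.nan, np.nan, np.nan, False, "empty_bin")
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (n_trials - 1)          # (bins, bins) across-trial covariance
    total_var = float(np.mean(np.diag(cov)))
    if total_var <= 0:
        return TimescaleFit(np.nan, np.nan, np.nan, False, "zero_variance")
    lags = np.arange(1, n_bins)
    r = np.array([np.mean(np.diag(cov, k=int(l))) for l in lags]) / total_var
    xlag = lags * bin_s
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p0 = (max(r[0], 0.05), 0.1, float(np.mean(r[-5:])))
            beta, _ = curve_fit(
                _exp_decay, xlag, r, p0=p0,
                bounds=([0.0, 1e-3, -1.0], [5.0, 5.0, 1.0]), maxfev=5000)
    except (RuntimeError, ValueError):
        return TimescaleFit(np.nan, np.nan, np.nan, False, "fit_failure",
                            lags_s=xlag, autocorr=r)
    a, tau, b = (float(v) for v in beta)
    if tau > tau_max_s:
        return TimescaleFit(a, tau, b, False, "slow_timescale",
                            lags_s=xlag, autocorr=r)
    return TimescaleFit(a, tau, b, True, "", lags_s=xlag, autocorr=r)


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def neuron_selectivity_table(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    baseline_s: float = 1.0,
    timescale_bin_s: float = 0.05,
) -> pd.DataFrame:
    """Tuning, wPEV (cue and delay), permutation p and timescale per neuron."""
    tr = trials[trials["outcome"] == "correct"]
    key = ["subject", "session", "trial"]
    merged = spikes.merge(
        tr[key + ["t_cue_on", "t_cue_off", "t_fix_off", "condition"]],
        on=key, how="inner")
    rng = substream(seed, "selectivity_table")
    rows = []
    for (subj, sess, neuron), g in merged.groupby(
            ["subject", "session", "neuron"], sort=True):
        trials_here = tr[(tr["subject"] == subj) & (tr["session"] == sess)]
        spikes_by_trial = {t: gg["spike_time_s"].to_numpy()
                           for t, gg in g.groupby("trial")}
        cue_counts: dict = {}
        delay_counts: dict = {}
        base_binned = []
        n_bins = int(round(baseline_s / timescale_bin_s))
        for _, trow in trials_here.iterrows():
            st = spikes_by_trial.get(trow["trial"], np.empty(0))
            c0, c1 = trow["t_cue_on"], trow["t_cue_off"]
            d1 = trow["t_fix_off"]
            cond = trow["condition"]
            cue_counts.setdefault(cond, []).append(
                np.count_nonzero((st >= c0) & (st < c1)))
            delay_counts.setdefault(cond, []).append(
                np.count_nonzero((st >= c1) & (st < d1)))
            b0 = c0 - baseline_s
            edges = b0 + np.arange(n_bins + 1) * timescale_bin_s
            base_binned.append(np.histogram(st, bins=edges)[0])
        locs = sorted(cue_counts)
        cue_dur = float(np.median(trials_here["t_cue_off"] - trials_here["t_cue_on"]))
        mean_rates = [np.mean(cue_counts[c]) / cue_dur for c in locs]
        row = {"subject": subj, "session": sess, "neuron": neuron}
        if len(locs) >= 5:
            tune = fit_tuning(np.asarray(locs, dtype=float), mean_rates)
            row.update(beta1=tune.baseline_hz, beta2=tune.amplitude_hz,
                       beta3=tune.preferred_deg, beta4=tune.width_deg,
                       r2=tune.r_squared, tuning_ok=tune.passes_quality())
        else:
            row.update(beta1=np.nan, beta2=np.nan, beta3=np.nan, beta4=np.nan,
                       r2=np.nan, tuning_ok=False)
        for name, counts in (("cue", cue_counts), ("delay", delay_counts)):
            groups = [np.asarray(counts[c], dtype=float) for c in locs]
            try:
                w2, p = permutation_selectivity_test(groups, n_perm=n_perm, rng=rng)
            except ValueError:
                w2, p = np.nan, np.nan
            row[f"omega2_{name}"] = w2
            row[f"p_perm_{name}"] = p
        ts = intrinsic_timescale(np.asarray(base_binned), bin_s=timescale_bin_s)
        row.update(tau_s=ts.tau_s, tau_included=ts.included, tau_reason=ts.reason)
        rows.append(row)
    return pd.DataFrame(rows)
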