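"""Per-neuron firing metrics: epoch rates and variability statistics.

Variability is summarized three ways, all from correct trials:

* CV_ISI = sd(ISI) / mean(ISI), inter-spike intervals pooled across the
  baseline (pre-cue fixation) epochs of all trials; intervals never span
  trial boundaries.
* CV_rate = sd / mean of the per-trial baseline firing rate.
* Fano factor = slope of the across-trial spike-count variance vs. mean
  regression, one point per stimulus condition, fitted through the origin.

Spike-window convention is half-open [start, end) everywhere, so adjacent
epochs never double-count a boundary spike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "epoch_rate",
    "epoch_count",
    "cv_isi",
    "cv_rate",
    "fano_slope",
    "lognormal_mean_rate",
    "neuron_metrics_table",
    "session_metrics_table",
]


def epoch_count(spike_times, start: float, end: float) -> int:
    """Spike count in the half-open window [start, end)."""
    t = np.asarray(spike_times, dtype=float)
    return int(np.count_nonzero((t >= start) & (t < end)))


def epoch_rate(spike_times, start: float, end: float) -> float:
    """Firing rate (Hz) in [start, end)."""
    if end <= start:
        raise ValueError("zero- or negative-length window")
    return epoch_count(spike_times, start, end) / (end - start)


def _isis(trains) -> np.ndarray:
    """Within-trial ISIs pooled across a list of spike-time arrays."""
    out = []
    for t in trains:
        t = np.asarray(t, dtype=float)
        if len(t) >= 2:
            out.append(np.diff(t))
    return np.concatenate(out) if out else np.empty(0)


def cv_isi(trains, min_isis: int = 3) -> float:
    """CV of within-trial inter-spike intervals pooled across trials.

    Returns NaN when fewer than `min_isis` intervals are available.
    Uses the sample (n-1) standard deviation.
    """
    isis = _isis(trains)
    if len(isis) < min_isis:
        return float("nan")
    mu = isis.mean()
    if mu == 0:
        return float("nan")
    return float(isis.std(ddof=1) / mu)


def cv_rate(rates, min_trials: int = 3) -> float:
    """CV of the per-trial baseline firing rate across trials."""
    r = np.asarray(rates, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) < min_trials:
        return float("nan")
    mu = r.mean()
    if mu == 0:
        return float("nan")
    return float(r.std(ddof=1) / mu)


def fano_slope(
    mean_counts,
    var_counts,
    min_conditions: int = 3,
    through_origin: bool = True,
) -> float:
    """Fano factor as the variance-vs-mean regression slope across conditions.

    Each point is one stimulus condition: (across-trial mean count,
    across-trial count variance).  The regression is constrained through the
    origin by default (variance = F * mean); `through_origin=False` adds an
    intercept.
    """
    m = np.asarray(mean_counts, dtype=float)
    v = np.asarray(var_counts, dtype=float)
    ok = ~(np.isnan(m) | np.isnan(v))
    m, v = m[ok], v[ok]
    if len(m) < min_conditions or np.all(m == 0):
        return float("nan")
    if through_origin:
        denom = float(m @ m)
        if denom == 0:
            return float("nan")
        return float((m @ v) / denom)
    X = np.column_stack([np.ones_like(m), m])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return float(coef[1])


def lognormal_mean_rate(rates, floor_hz: float = 0.1) -> float:
    """Log-normal (geometric-mean) average of rates across neurons.

    Rates are floored at `floor_hz` before taking logs so silent neurons do
    not send the average to zero.
    """
    r = np.maximum(np.asarray(rates, dtype=float), floor_hz)
    r = r[~np.isnan(r)]
    if len(r) == 0:
        return float("nan")
    return float(np.exp(np.mean(np.log(r))))


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def _trial_epochs(trial_row, baseline_s: float = 1.0):
    """(start, end) of baseline, cue and delay epochs for one trial row."""
    t_cue_on = trial_row["t_cue_on"]
    t_cue_off = trial_row["t_cue_off"]
    t_fix_off = trial_row["t_fix_off"]
    return {
        "baseline": (t_cue_on - baseline_s, t_cue_on),
        "cue": (t_cue_on, t_cue_off),
        "delay": (t_cue_off, t_fix_off),
    }


def neuron_metrics_table(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    baseline_s: float = 1.0,
    min_trials_per_condition: int = 4,
) -> pd.DataFrame:
    """Per-neuron firing metrics from long-format spike and trial tables.

    Uses correct trials only.  Columns produced: baseline/cue/delay rate,
    CV_ISI, CV_rate, Fano slope, n_trials.
    """
    tr = trials[trials["outcome"] == "correct"].copy()
    key = ["subject", "session", "trial"]
    merged = spikes.merge(tr[key + ["t_cue_on", "t_cue_off", "t_fix_off",
                                    "condition"]], on=key, how="inner")
    rows = []
    for (subj, sess, neuron), g in merged.groupby(
            ["subject", "session", "neuron"], sort=True):
        trials_here = tr[(tr["subject"] == subj) & (tr["session"] == sess)]
        n_trials = len(trials_here)
        if n_trials == 0:
            continue
        spikes_by_trial = {t: gg["spike_time_s"].to_numpy()
                           for t, gg in g.groupby("trial")}
        base_trains, base_rates = [], []
        counts_by_cond: dict = {}
        rates = {"baseline": [], "cue": [], "delay": []}
        for _, trow in trials_here.iterrows():
            st = spikes_by_trial.get(trow["trial"], np.empty(0))
            ep = _trial_epochs(trow, baseline_s)
            for name, (a, b) in ep.items():
                rates[name].append(epoch_rate(st, a, b))
            a, b = ep["baseline"]
            tb = st[(st >= a) & (st < b)]
            base_trains.append(tb)
            base_rates.append(len(tb) / (b - a))
            ca, cb = ep["cue"]
            counts_by_cond.setdefault(trow["condition"], []).append(
                epoch_count(st, ca, cb))
        mean_c, var_c = [], []
        for cond, cc in sorted(counts_by_cond.items()):
            if len(cc) >= min_trials_per_condition:
                cc = np.asarray(cc, dtype=float)
                mean_c.append(cc.mean())
                var_c.append(cc.var(ddof=1))
        rows.append({
            "subject": subj, "session": sess, "neuron": neuron,
            "rate_baseline": float(np.mean(rates["baseline"])),
            "rate_cue": float(np.mean(rates["cue"])),
            "rate_delay": float(np.mean(rates["delay"])),
            "cv_isi": cv_isi(base_trains),
            "cv_rate": cv_rate(base_rates),
            "fano": fano_slope(mean_c, var_c),
            "n_trials": n_trials,
        })
    return pd.DataFrame(rows)


def session_metrics_table(
    neuron_metrics: pd.DataFrame,
    neurons: pd.DataFrame,
) -> pd.DataFrame:
    """Session averages of per-neuron metrics.

    Rates use the log-normal average across neurons; variability metrics use
    plain means.  `neurons` supplies rel_age_months per (subject, session).
    """
    age = neurons.groupby(["subject", "session"])["rel_age_months"].first()
    rows = []
    for (subj, sess), g in neuron_metrics.groupby(["subject", "session"]):
        rows.append({
            "subject": subj, "session": sess,
            "rel_age_months": float(age.loc[(subj, sess)]),
            "rate_baseline": lognormal_mean_rate(g["rate_baseline"]),
            "rate_cue": lognormal_mean_rate(g["rate_cue"]),
            "rate_delay": lognormal_mean_rate(g["rate_delay"]),
            "cv_isi": float(np.nanmean(g["cv_isi"])) if g["cv_isi"].notna().any() else np.nan,
            "cv_rate": float(np.nanmean(g["cv_rate"])) if g["cv_rate"].notna().any() else np.nan,
            "fano": float(np.nanmean(g["fano"])) if g["fano"].notna().any() else np.nan,
            "n_neurons": int(len(g)),
        })
    return pd.DataFrame(rows)
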