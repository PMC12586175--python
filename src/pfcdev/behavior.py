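"""Session-level behavioral outcomes for oculomotor delayed-response tasks.

Three measures summarize a session:

* the saccade dispersion index (DI) — the area of the one-standard-deviation
  covariance ellipse of saccade endpoints around the mean landing position of
  each target, averaged over targets (deg^2; lower = more precise),
* reaction time (RT) — fixation-offset to saccade-onset latency (s),
* percent correct, excluding trials aborted before the end of the delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InsufficientTrialsError",
    "compute_di",
    "compute_rt",
    "compute_performance",
    "session_behavior_table",
]

#: seconds; saccades launched at or below this latency are flagged anticipatory
ANTICIPATORY_S = 0.08

#: outcome labels understood by this module
OUTCOMES = ("correct", "error", "aborted_early", "aborted_other")


class InsufficientTrialsError(ValueError):
    """No target condition has enough trials for a covariance estimate."""


def _ellipse_area(points: np.ndarray, circular: bool = False) -> float:
    """Area of the 1-s.d. region of a 2-D endpoint scatter.

    Default: area of the 1-s.d. covariance ellipse, pi * sqrt(det(Sigma))
    with the unbiased (n-1) sample covariance.  `circular=True` uses the
    isotropic alternative pi * (mean radial s.d.)^2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("endpoints must be an (n, 2) array")
    cov = np.cov(pts.T, ddof=1)
    if circular:
        return float(np.pi * 0.5 * np.trace(cov))
    det = float(np.linalg.det(cov))
    if det < 0:
        det = 0.0
    if det == 0.0:
        warnings.warn("singular endpoint covariance (collinear endpoints); DI set to 0")
        return 0.0
    return float(np.pi * np.sqrt(det))


def compute_di(
    endpoints_by_target: dict,
    min_trials: int = 4,
    circular: bool = False,
) -> "DispersionResult":
    """Dispersion index from saccade endpoints grouped by target.

    Parameters
    ----------
    endpoints_by_target
        Mapping target id -> (n, 2) array of endpoint coordinates (deg).
    min_trials
        Minimum endpoints per target for that target to be included.
    circular
        Use the circular (isotropic) area definition instead of the
        covariance-ellipse area.

    Returns
    -------
    DispersionResult with the unweighted mean over included targets and the
    per-target areas.
    """
    per_target: dict = {}
    for target, pts in endpoints_by_target.items():
        pts = np.asarray(pts, dtype=float)
        if len(pts) >= min_trials:
            per_target[target] = _ellipse_area(pts, circular=circular)
    if not per_target:
        raise InsufficientTrialsError(
            f"no target has >= {min_trials} trials with endpoints"
        )
    session = float(np.mean(list(per_target.values())))
    return DispersionResult(di_session=session, di_per_target=per_target)


@dataclass
class DispersionResult:
    di_session: float
    di_per_target: dict = field(default_factory=dict)


def compute_rt(onset_s, fixation_off_s, response_window_s: float = 0.6):
    """Reaction time(s) with anticipatory/late flags.

    RT = saccade onset - fixation offset.  Flags: "anticipatory" if
    RT <= 0.08 s, "late" if RT > response window, else "ok".  Missing onsets
    (NaN) yield NaN RT and flag "missing".
    """
    onset = np.asarray(onset_s, dtype=float)
    fix_off = np.asarray(fixation_off_s, dtype=float)
    rt = onset - fix_off
    flags = np.where(
        np.isnan(rt),
        "missing",
        np.where(rt <= ANTICIPATORY_S, "anticipatory",
                 np.where(rt > response_window_s, "late", "ok")),
    )
    if rt.ndim == 0:
        return float(rt), str(flags)
    return rt, flags


def compute_performance(outcomes) -> float:
    """Percent correct, excluding trials aborted before the end of the delay.

    The denominator is correct + error trials; `aborted_early` (fixation
    break before delay end) never counts against performance, while
    `aborted_other` (e.g. broke fixation during the response) counts as an
    eligible failed trial.
    """
    s = pd.Series(outcomes, dtype="object")
    n_correct = int((s == "correct").sum())
    n_eligible = int(s.isin(["correct", "error", "aborted_other"]).sum())
    if n_eligible == 0:
        raise ValueError("no eligible trials (all aborted before delay end)")
    return 100.0 * n_correct / n_eligible


def session_behavior_table(
    trials: pd.DataFrame,
    min_trials: int = 4,
    response_window_s: float = 0.6,
    circular: bool = False,
) -> pd.DataFrame:
    """Per-session behavior summary from a long-format trial table.

    Expects columns: subject, session, rel_age_months, condition, outcome,
    t_fix_off, sacc_onset_s, endpoint_x_deg, endpoint_y_deg.  DI uses
    endpoints from correct trials only; RT uses non-aborted trials with a
    recorded onset.
    """
    rows = []
    for (subj, sess), g in trials.groupby(["subject", "session"], sort=True):
        correct = g[g["outcome"] == "correct"]
        groups = {
            cond: gc[["endpoint_x_deg", "endpoint_y_deg"]].to_numpy()
            for cond, gc in correct.groupby("condition")
        }
        try:
            di = compute_di(groups, min_trials=min_trials, circular=circular).di_session
        except InsufficientTrialsError:
            di = np.nan
        resp = g[g["outcome"].isin(["correct", "error"])]
        rt, flags = compute_rt(
            resp["sacc_onset_s"].to_numpy(),
            resp["t_fix_off"].to_numpy(),
            response_window_s,
        )
        rt_ok = rt[(flags == "ok")]
        rt_mean = float(np.mean(rt_ok)) if len(rt_ok) else np.nan
        try:
            pct = compute_performance(g["outcome"])
        except ValueError:
            pct = np.nan
        rows.append({
            "subject": subj,
            "session": sess,
            "rel_age_months": float(g["rel_age_months"].iloc[0]),
            "DI": di,
            "RT_mean": rt_mean,
            "percent_correct": pct,
            "n_correct": int((g["outcome"] == "correct").sum()),
            "n_trials": int(len(g)),
        })
    return pd.DataFrame(rows)
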