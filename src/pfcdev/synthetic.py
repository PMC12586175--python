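"""Synthetic longitudinal cohort with planted developmental structure.

Generates subjects tracked across ages performing oculomotor
delayed-response (ODR) trials — with and without a mid-delay distractor —
together with per-neuron spike trains, saccade endpoints, reaction times and
auxiliary longitudinal measures.  Every age-dependent property is a planted,
user-controlled curve of mid-adolescence-relative age, and the generator
returns those curves evaluated at each session ("truth") so each downstream
estimator has a parameter-recovery test.

Planted structure
-----------------
* Spike trains are time-rescaled gamma-renewal processes with shape
  1 / CV^2, so the ISI coefficient of variation is directly controlled.
* Trial-to-trial count over-dispersion (Fano factor > CV^2) comes from a
  per-trial lognormal rate gain.
* Baseline counts carry a slow Ornstein-Uhlenbeck rate modulation with a
  planted intrinsic timescale.
* Delay-period condition x time profiles are combinations of a fixed set of
  orthonormal patterns; the number of active patterns plants the population
  dimensionality.
* For distractor-task sessions, each neuron's cue-epoch and distractor-epoch
  condition means are drawn from a construction whose cue and distractor
  planes subtend a planted angle after the z-score + 3-PC analysis.
* Saccade endpoints are isotropic bivariate Gaussian around the target;
  reaction times are truncated lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "TaskConfig", "NeuronPopulationSpec", "BehaviorSpec", "CohortSpec",
    "logistic", "generate_spike_train", "generate_rotated_population",
    "generate_latent_population", "ou_modulated_counts", "generate_cohort",
]


def logistic(t, young: float, adult: float, midpoint: float, scale: float):
    """Sigmoid developmental curve: `young` value far before `midpoint`,
    `adult` value far after, transition width `scale` (months)."""
    t = np.asarray(t, dtype=float)
    return young + (adult - young) / (1.0 + np.exp(-(t - midpoint) / scale))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Geometry and timing of the ODR task variants (times in s, angles deg)."""
    n_locations: int = 8
    eccentricity_deg: float = 10.0
    fixation_s: float = 1.0
    cue_s: float = 0.5
    delay_s: float = 1.5
    distractor_onset_after_cue_s: float = 1.25
    distractor_s: float = 0.5
    response_window_s: float = 0.6
    endpoint_window_deg: float = 6.0
    hold_s: float = 0.1
    distractor_offsets_deg: tuple = (180, 90, 45, 0, None)

    def validate(self):
        if self.n_locations not in (4, 8):
            raise ValueError("TaskConfig.n_locations must be 4 or 8")
        for name in ("fixation_s", "cue_s", "delay_s", "distractor_s",
                     "response_window_s", "hold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TaskConfig.{name} must be > 0")

    @property
    def locations_deg(self) -> np.ndarray:
        step = 360.0 / self.n_locations
        return np.arange(self.n_locations) * step


@dataclass
class NeuronPopulationSpec:
    n_neurons_per_session: int = 30
    baseline_rate_curve: Callable = lambda t: logistic(t, 4.0, 8.0, -10.0, 8.0)
    cv_curve: Callable = lambda t: logistic(t, 1.25, 0.95, -10.0, 8.0)
    fano_curve: Callable = lambda t: logistic(t, 1.8, 1.2, -8.0, 8.0)
    tuning_amplitude_hz: float = 6.0
    tuning_width_deg: float = 40.0
    latent_dim_curve: Callable = lambda t: logistic(t, 2.0, 6.0, -10.0, 7.0)
    rotation_curve: Callable = lambda t: logistic(t, 10.0, 45.0, -12.0, 6.0)
    timescale_s: float = 0.15
    ou_depth: float = 0.5
    pattern_scale_hz: float = 4.0
    n_patterns: int = 8

    def validate(self):
        if self.n_neurons_per_session < 1:
            raise ValueError("NeuronPopulationSpec.n_neurons_per_session must be >= 1")
        if self.timescale_s <= 0:
            raise ValueError("NeuronPopulationSpec.timescale_s must be > 0")


@dataclass
class BehaviorSpec:
    dispersion_curve: Callable = lambda t: logistic(t, 2.2, 1.55, -10.0, 8.0)
    rt_curve: Callable = lambda t: logistic(t, 0.25, 0.19, -10.0, 8.0)
    rt_sigma: float = 0.15
    correct_rate_curve: Callable = lambda t: logistic(t, 0.72, 0.85, -10.0, 8.0)
    aborted_early_rate: float = 0.08

    def validate(self):
        if not (0.0 <= self.aborted_early_rate < 1.0):
            raise ValueError("BehaviorSpec.aborted_early_rate must be in [0, 1)")


@dataclass
class CohortSpec:
    n_subjects: int = 8
    ages_months: Sequence = field(
        default_factory=lambda: [list(range(40, 74, 3))] * 8)
    mid_adolescence_month: Sequence = field(
        default_factory=lambda: [53.0, 54.5, 56.0, 57.0, 58.5, 60.0, 61.5, 63.0])
    seed: int = 0
    trials_per_session: int = 64
    n_distractor_subjects: int = 4
    task: TaskConfig = field(default_factory=TaskConfig)
    neuron_spec: NeuronPopulationSpec = field(default_factory=NeuronPopulationSpec)
    behavior_spec: BehaviorSpec = field(default_factory=BehaviorSpec)

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("CohortSpec.n_subjects must be >= 1")
        if len(self.ages_months) != self.n_subjects:
            raise ValueError("CohortSpec.ages_months must have one list per subject")
        if len(self.mid_adolescence_month) != self.n_subjects:
            raise ValueError(
                "CohortSpec.mid_adolescence_month must have one value per subject")
        for ages in self.ages_months:
            a = np.asarray(ages, dtype=float)
            if len(a) == 0 or np.any(np.diff(a) <= 0):
                raise ValueError("CohortSpec.ages_months must be strictly increasing")
        if self.trials_per_session < 1:
            raise ValueError("CohortSpec.trials_per_session must be >= 1")
        if not (0 <= self.n_distractor_subjects <= self.n_subjects):
            raise ValueError("CohortSpec.n_distractor_subjects out of range")
        self.task.validate()
        self.neuron_spec.validate()
        self.behavior_spec.validate()


# ---------------------------------------------------------------------------
# spike-train primitive
# ---------------------------------------------------------------------------

def generate_spike_train(
    rate_profile,
    target_cv: float,
    trial_duration_s: float,
    rng: np.random.Generator,
    bin_edges: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gamma-renewal spike train, rate-modulated by time rescaling.

    ISIs in operational time are gamma with shape k = 1 / target_cv^2 and
    unit mean; real-time spikes are obtained by inverting the cumulative
    intensity of the piecewise-constant `rate_profile` (Hz per bin over
    `bin_edges`; a scalar profile means a constant rate).  A warm-up of five
    mean intervals before t = 0 approximates a stationary (equilibrium)
    renewal process.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be > 0")
    if trial_duration_s <= 0:
        return np.empty(0)
    rates = np.atleast_1d(np.asarray(rate_profile, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, trial_duration_s, len(rates) + 1)
    edges = np.asarray(bin_edges, dtype=float)
    lam_edges = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
    lam_tot = lam_edges[-1]
    if lam_tot <= 0:
        return np.empty(0)
    k = 1.0 / target_cv ** 2
    warmup = 5.0
    ops = []
    t_op, budget = -warmup, lam_tot + warmup
    while t_op < lam_tot:
        n_draw = int(budget + 6 * math.sqrt(budget + 1) + 10)
        incr = rng.gamma(k, 1.0 / k, size=n_draw)
        cum = t_op + np.cumsum(incr)
        ops.append(cum)
        t_op = cum[-1]
        budget = lam_tot - t_op
    op_times = np.concatenate(ops)
    op_times = op_times[(op_times > 0) & (op_times <= lam_tot)]
    return np.interp(op_times, lam_edges, edges)


def ou_modulated_counts(
    mean_count_per_bin: float,
    tau_s: float,
    n_trials: int,
    n_bins: int,
    rng: np.random.Generator,
    bin_s: float = 0.05,
    depth: float = 0.5,
) -> np.ndarray:
    """Doubly stochastic Poisson counts with an OU-rate planted timescale.

    The per-bin rate is mu * (1 + depth * z) clipped at 0, where z is a
    stationary AR(1) (discretized Ornstein-Uhlenbeck) process with lag-1
    correlation exp(-bin_s / tau_s).  Returns (n_trials, n_bins) counts.
    """
    rho = math.exp(-bin_s / tau_s)
    z = np.empty((n_trials, n_bins))
    z[:, 0] = rng.standard_normal(n_trials)
    innov = rng.standard_normal((n_trials, n_bins)) * math.sqrt(1 - rho ** 2)
    for b in range(1, n_bins):
        z[:, b] = rho * z[:, b - 1] + innov[:, b]
    lam = np.clip(mean_count_per_bin * (1.0 + depth * z), 0.0, None)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# planted-geometry constructions
# ---------------------------------------------------------------------------

def _tight_frame(n_neurons: int, rng: np.random.Generator) -> np.ndarray:
    """3 x n matrix with unit-norm columns; for n a multiple of 3 the rows
    are orthogonal with equal norm (a tight frame), so embedding through it
    is a scaled isometry."""
    blocks = []
    for _ in range(math.ceil(n_neurons / 3)):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        blocks.append(q)
    return np.hstack(blocks)[:, :n_neurons]


def generate_rotated_population(
    n_neurons: int,
    angle_deg: float,
    noise_sd: float,
    rng: np.random.Generator,
    mean_rate_hz: float = 8.0,
    latent_scale_hz: float = 3.0,
) -> np.ndarray:
    """8 x n_neurons rate matrix with a planted cue/distractor plane angle.

    Rows 0-3 are cue-epoch condition means for four locations, rows 4-7 the
    distractor-epoch means.  The latent 3-D configuration is built so that
    (a) its total covariance is isotropic — hence per-neuron z-scoring
    rescales all latent directions equally — and (b) the two best-fit plane
    normals subtend `angle_deg`.  The embedding uses unit-norm columns from
    stacked random rotations, so the downstream z-score + 3-PC + plane-fit
    pipeline recovers the planted angle (exactly for noiseless input when
    n_neurons is a multiple of 3).
    """
    if not (0.0 <= angle_deg <= 90.0):
        raise ValueError("angle_deg must be in [0, 90]")
    if n_neurons < 4:
        raise ValueError("n_neurons must be >= 4 (plane undetermined)")
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    f2 = np.array([0.0, c, s])
    a = math.sqrt((1 + c) / 2.0)
    d = math.sqrt(2.0 * c)
    if angle_deg == 0.0:
        u = np.array([0.0, 0.0, 1.0])     # parallel planes offset along normal
    else:
        u = np.array([0.0, 1.0 - c, -s])
        u /= np.linalg.norm(u)
    c_cue, c_dis = -(d / 2.0) * u, (d / 2.0) * u
    cue = np.stack([c_cue + a * e1, c_cue - a * e1, c_cue + e2, c_cue - e2])
    dis = np.stack([c_dis + a * e1, c_dis - a * e1, c_dis + f2, c_dis - f2])
    latent = np.vstack([cue, dis])                      # (8, 3)
    frame = _tight_frame(n_neurons, rng)                # (3, n)
    base = mean_rate_hz * np.exp(rng.normal(0.0, 0.25, size=n_neurons))
    mat = base[None, :] + latent_scale_hz * (latent @ frame)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return mat


def generate_latent_population(
    n_neurons: int,
    latent_dim: int,
    n_rows: int = 112,
    noise_sd: float = 0.05,
    weight_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """(n_rows, n_neurons) response matrix with a planted dimensionality.

    Each neuron's condition x time profile is a random combination of
    `latent_dim` shared orthonormal patterns with i.i.d. weights, plus
    entry-wise noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if latent_dim < 1 or latent_dim > n_rows:
        raise ValueError("latent_dim must be in [1, n_rows]")
    q, _ = np.linalg.qr(rng.standard_normal((n_rows, latent_dim)))
    w = rng.normal(0.0, weight_sd, size=(n_neurons, latent_dim))
    x = q @ w.T
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return x


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_rt(rng, mean_s: float, sigma: float, window_s: float) -> float:
    """Lognormal RT with the given mean, truncated into (0.08, window]."""
    mu = math.log(mean_s) - sigma ** 2 / 2.0
    for _ in range(100):
        rt = rng.lognormal(mu, sigma)
        if 0.08 < rt <= window_s:
            return rt
    return min(max(mean_s, 0.09), window_s)


def _ar1(rng, n: int, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for i in range(1, n):
        z[i] = rho * z[i - 1] + math.sqrt(1 - rho ** 2) * rng.standard_normal()
    return z


def _circ_gauss(delta_deg, width_deg):
    d = (np.asarray(delta_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.exp(-0.5 * (d / width_deg) ** 2)


def generate_cohort(spec: CohortSpec) -> dict:
    """Generate the full synthetic cohort.

    Returns a dict with `trials`, `spikes`, `neurons`, `measures` DataFrames
    and `truth` (planted curve values per subject-session plus global
    parameters).  Output is a deterministic function of `spec` (including
    its seed).
    """
    spec.validate()
    rng = substream(spec.seed, "cohort")
    task = spec.task
    ns = spec.neuron_spec
    bs = spec.behavior_spec
    locs = task.locations_deg
    dis_locs = np.arange(4) * 90.0

    # shared orthonormal delay patterns over (8 conditions x 15 delay bins)
    n_delay_bins = int(round(task.delay_s / 0.1))
    pat_rng = substream(spec.seed, "patterns")
    n_pat_rows = task.n_locations * n_delay_bins
    pat_q, _ = np.linalg.qr(
        pat_rng.standard_normal((n_pat_rows, ns.n_patterns)))
    # scale to unit per-entry variance so pattern_scale_hz is a per-bin rate sd
    patterns = (pat_q * math.sqrt(n_pat_rows)).T.reshape(
        ns.n_patterns, task.n_locations, n_delay_bins)

    trial_rows, spike_rows, neuron_rows, truth_rows = [], [], [], []
    measure_rows = []

    n_fix_bins = int(round(task.fixation_s / 0.05))
    rho_fix = math.exp(-0.05 / ns.timescale_s)

    for si in range(spec.n_subjects):
        subject = f"m{si + 1:02d}"
        mid = float(spec.mid_adolescence_month[si])
        has_distractor = si < spec.n_distractor_subjects
        for age_i, age in enumerate(spec.ages_months[si]):
            session = f"{subject}_s{age_i + 1:02d}"
            t_rel = float(age) - mid
            base_t = float(ns.baseline_rate_curve(t_rel))
            cv_t = float(ns.cv_curve(t_rel))
            fano_t = float(ns.fano_curve(t_rel))
            disp_t = float(bs.dispersion_curve(t_rel))
            rt_t = float(bs.rt_curve(t_rel))
            pcorr_t = float(bs.correct_rate_curve(t_rel))
            kdim_t = int(round(float(ns.latent_dim_curve(t_rel))))
            kdim_t = max(1, min(kdim_t, ns.n_patterns))
            angle_t = float(ns.rotation_curve(t_rel))
            truth_rows.append({
                "subject": subject, "session": session, "age_months": float(age),
                "rel_age_months": t_rel, "baseline_rate_hz": base_t,
                "cv_isi": cv_t, "fano": fano_t, "dispersion_sd_deg": disp_t,
                "rt_mean_s": rt_t, "correct_rate": pcorr_t,
                "latent_dim": kdim_t, "rotation_deg": angle_t,
                "timescale_s": ns.timescale_s,
            })

            # --- per-neuron parameters -------------------------------------
            nn = ns.n_neurons_per_session
            base_i = base_t * np.exp(rng.normal(0.0, 0.3, size=nn))
            amp_i = ns.tuning_amplitude_hz * np.exp(rng.normal(0.0, 0.4, size=nn))
            pref_i = rng.choice(locs, size=nn)
            wts_i = rng.normal(0.0, 1.0, size=(nn, ns.n_patterns))
            wts_i[:, kdim_t:] = 0.0
            # lognormal gain sd chosen to lift count Fano above CV^2
            mu_count = np.maximum(base_i * task.cue_s, 0.2)
            excess = np.maximum(fano_t - cv_t ** 2, 0.0)
            sig2_gain = np.log1p(excess / mu_count)
            sig_gain = np.sqrt(sig2_gain)
            if has_distractor:
                rot_mat = generate_rotated_population(
                    nn, angle_t, noise_sd=0.0, rng=rng,
                    mean_rate_hz=base_t, latent_scale_hz=3.0)
                rot_mat = np.clip(rot_mat, 0.1, None)
            for j in range(nn):
                neuron_rows.append({
                    "subject": subject, "session": session, "neuron": j,
                    "rel_age_months": t_rel,
                })

            # precomputed per-(neuron, condition) rate profiles (ODR)
            # bins: fixation 50-ms bins | cue | delay 100-ms bins | response
            t_cue_on = task.fixation_s
            t_cue_off = t_cue_on + task.cue_s
            t_fix_off = t_cue_off + task.delay_s
            t_end = t_fix_off + task.response_window_s
            edges = np.concatenate([
                np.arange(n_fix_bins + 1) * 0.05,
                [t_cue_off],
                t_cue_off + np.arange(1, n_delay_bins + 1) * 0.1,
                [t_end],
            ])
            cue_rate = (base_i[:, None]
                        + amp_i[:, None] * _circ_gauss(locs[None, :] - pref_i[:, None],
                                                       ns.tuning_width_deg))
            delay_tuned = base_i[:, None] + 0.3 * amp_i[:, None] * _circ_gauss(
                locs[None, :] - pref_i[:, None], ns.tuning_width_deg)
            # (neuron, condition, delay bin)
            delay_rate = (delay_tuned[:, :, None]
                          + ns.pattern_scale_hz
                          * np.einsum("np,pcb->ncb", wts_i, patterns))
            delay_rate = np.clip(delay_rate, 0.1, None)

            # --- trials ----------------------------------------------------
            def run_trials(task_name, cue_locations, n_trials, delay_total,
                           dis_offsets=None, trial0=0):
                """Emit n_trials trials; returns next trial index."""
                t_fix_off_loc = t_cue_off + delay_total
                t_end_loc = t_fix_off_loc + task.response_window_s
                if task_name == "odr":
                    edges_loc, cue_r, delay_r = edges, cue_rate, delay_rate
                else:
                    t_dis_on = t_cue_on + task.distractor_onset_after_cue_s
                    t_dis_off = t_dis_on + task.distractor_s
                    edges_loc = np.concatenate([
                        np.arange(n_fix_bins + 1) * 0.05,
                        [t_cue_off, t_dis_on, t_dis_off, t_fix_off_loc, t_end_loc],
                    ])
                for ti in range(n_trials):
                    trial = trial0 + ti
                    ci = ti % len(cue_locations)
                    cue_deg = float(cue_locations[ci])
                    if dis_offsets is not None:
                        off = dis_offsets[(ti // len(cue_locations)) % len(dis_offsets)]
                        dis_cond = "none" if off is None else str(int(off))
                        t_dis_on = t_cue_on + task.distractor_onset_after_cue_s
                        t_dis_off = t_dis_on + task.distractor_s
                    else:
                        dis_cond, t_dis_on, t_dis_off = "", np.nan, np.nan
                    u = rng.uniform()
                    if u < bs.aborted_early_rate:
                        outcome = "aborted_early"
                    elif rng.uniform() < pcorr_t:
                        outcome = "correct"
                    else:
                        outcome = "error"
                    # saccade
                    if outcome == "correct":
                        tgt = task.eccentricity_deg * np.array(
                            [math.cos(math.radians(cue_deg)),
                             math.sin(math.radians(cue_deg))])
                        ep = tgt + disp_t * rng.standard_normal(2)
                        rt = _draw_rt(rng, rt_t, bs.rt_sigma, task.response_window_s)
                        onset = t_fix_off_loc + rt
                    elif outcome == "error":
                        wrong = float(rng.choice(cue_locations))
                        tgt = task.eccentricity_deg * np.array(
                            [math.cos(math.radians(wrong)),
                             math.sin(math.radians(wrong))])
                        ep = tgt + disp_t * rng.standard_normal(2)
                        rt = _draw_rt(rng, rt_t * 1.1, bs.rt_sigma,
                                      task.response_window_s)
                        onset = t_fix_off_loc + rt
                    else:
                        ep = (np.nan, np.nan)
                        onset = np.nan
                    trial_rows.append({
                        "subject": subject, "session": session,
                        "age_months": float(age), "rel_age_months": t_rel,
                        "trial": trial, "task": task_name,
                        "condition": cue_deg, "distractor_condition": dis_cond,
                        "outcome": outcome, "t_fix_on": 0.0,
                        "t_cue_on": t_cue_on, "t_cue_off": t_cue_off,
                        "t_dis_on": t_dis_on, "t_dis_off": t_dis_off,
                        "t_fix_off": t_fix_off_loc,
                        "sacc_onset_s": onset,
                        "endpoint_x_deg": float(ep[0]), "endpoint_y_deg": float(ep[1]),
                    })
                    if outcome == "aborted_early":
                        continue          # no spikes recorded for aborted trials
                    gains = np.exp(rng.normal(-sig2_gain / 2.0, sig_gain))
                    ou = 1.0 + ns.ou_depth * _ar1(rng, n_fix_bins, rho_fix)
                    ou = np.clip(ou, 0.05, None)
                    for j in range(nn):
                        if task_name == "odr":
                            li = int(np.argmin(np.abs(locs - cue_deg)))
                            prof = np.concatenate([
                                base_i[j] * ou,
                                [cue_rate[j, li]],
                                delay_rate[j, li],
                                [base_i[j]],
                            ])
                        else:
                            li = int(np.argmin(np.abs(dis_locs - cue_deg)))
                            prof = np.concatenate([
                                base_i[j] * ou,
                                [rot_mat[li, j]],          # cue epoch
                                [base_i[j]],               # delay 1
                                [rot_mat[4 + li, j]],      # distractor epoch
                                [base_i[j]],               # delay 2
                                [base_i[j]],               # response
                            ])
                        st = generate_spike_train(
                            prof * gains[j], cv_t, float(edges_loc[-1]),
                            rng, bin_edges=edges_loc)
                        if len(st):
                            spike_rows.append((subject, session, j, trial, st))
                return trial0 + n_trials

            nxt = run_trials("odr", locs, spec.trials_per_session, task.delay_s)
            if has_distractor:
                dis_delay = (task.distractor_onset_after_cue_s - task.cue_s
                             + task.distractor_s
                             + task.distractor_onset_after_cue_s)
                run_trials("odr_distractor", dis_locs, spec.trials_per_session,
                           dis_delay, dis_offsets=task.distractor_offsets_deg,
                           trial0=nxt)

        # auxiliary longitudinal measures (one value per subject-age)
        for age in spec.ages_months[si]:
            t_rel = float(age) - mid
            fa = float(logistic(t_rel, 0.42, 0.50, -12.0, 7.0)) \
                + rng.normal(0.0, 0.004)
            gm = 100.0 * (1.0 - ((t_rel - 5.0) / 60.0) ** 2) + rng.normal(0.0, 0.3)
            measure_rows.extend([
                {"subject": subject, "age_months": float(age),
                 "rel_age_months": t_rel, "measure_name": "fa_frontal_tract",
                 "value": fa},
                {"subject": subject, "age_months": float(age),
                 "rel_age_months": t_rel, "measure_name": "gm_volume",
                 "value": gm},
            ])

    trials = pd.DataFrame(trial_rows)
    if spike_rows:
        counts = np.array([len(r[4]) for r in spike_rows])
        spikes = pd.DataFrame({
            "subject": np.repeat([r[0] for r in spike_rows], counts),
            "session": np.repeat([r[1] for r in spike_rows], counts),
            "neuron": np.repeat([r[2] for r in spike_rows], counts),
            "trial": np.repeat([r[3] for r in spike_rows], counts),
            "spike_time_s": np.concatenate([r[4] for r in spike_rows]),
        })
    else:
        spikes = pd.DataFrame(
            columns=["subject", "session", "neuron", "trial", "spike_time_s"])
    neurons = pd.DataFrame(neuron_rows)
    measures = pd.DataFrame(measure_rows)
    truth = {
        "per_session": pd.DataFrame(truth_rows),
        "params": {
            "timescale_s": ns.timescale_s,
            "n_patterns": ns.n_patterns,
            "seed": spec.seed,
        },
    }
    return {"trials": trials, "spikes": spikes, "neurons": neurons,
            "measures": measures, "truth": truth}
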