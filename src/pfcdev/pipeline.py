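"""End-to-end orchestration: simulate -> behavior -> spike metrics ->
selectivity -> population geometry -> trajectories -> comparisons.

Every stage reads/writes plain CSV (plus one JSON file of fitted
trajectories and a JSON manifest), so any stage can also be run on
user-supplied tables with the same schemas.  Units: times in seconds, ages
in months, angles in degrees, rates in Hz.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as _behavior
from . import compare as _compare
from . import geometry as _geometry
from . import selectivity as _selectivity
from . import spikes as _spikes
from . import synthetic as _synthetic
from . import trajectory as _trajectory
from ._rng import substream

log = logging.getLogger("pfcdev")

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ["simulate", "behavior", "spikes", "selectivity", "geometry",
          "trajectory", "compare"]


@dataclass
class PipelineConfig:
    """All pipeline constants in one serializable record."""
    seed: int = 0
    out_dir: str = "pfcdev_out"
    # cohort scale
    n_subjects: int = 8
    n_sessions: int = 12
    first_age_months: int = 40
    session_step_months: int = 3
    n_neurons_per_session: int = 30
    trials_per_session: int = 64
    n_distractor_subjects: int = 4
    # thresholds
    min_trials_per_target: int = 4
    min_neurons_per_interval: int = 30
    r2_cutoff: float = 0.5
    rate_cutoff_hz: float = 0.5
    timescale_cutoff_s: float = 0.5
    # analysis sizes
    n_bootstrap: int = 500
    n_permutations: int = 1000
    n_intervals_full_space: int = 20
    n_intervals_rotation: int = 15
    n_subsample: int = 30
    grid_size: int = 200
    compare_points: int = 100
    n_posterior_draws: int = 10000

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cohort_spec(self) -> _synthetic.CohortSpec:
        ages = [list(range(self.first_age_months,
                           self.first_age_months
                           + self.n_sessions * self.session_step_months,
                           self.session_step_months))] * self.n_subjects
        mids = list(np.linspace(53.0, 63.0, self.n_subjects))
        spec = _synthetic.CohortSpec(
            n_subjects=self.n_subjects, ages_months=ages,
            mid_adolescence_month=mids, seed=self.seed,
            trials_per_session=self.trials_per_session,
            n_distractor_subjects=min(self.n_distractor_subjects,
                                      self.n_subjects))
        spec.neuron_spec.n_neurons_per_session = self.n_neurons_per_session
        return spec


# ---------------------------------------------------------------------------
# geometry helpers operating on the long tables
# ---------------------------------------------------------------------------

def _binned_condition_means(spikes, trials, t0_col, n_bins, bin_s,
                            task="odr"):
    """Per (subject, session, neuron, condition): mean rate per bin.

    Bins are `n_bins` consecutive windows of `bin_s` starting at the trial
    column `t0_col`.  Returns a DataFrame indexed by neuron key with one
    rate column per (condition, bin).
    """
    tr = trials[(trials["outcome"] == "correct") & (trials["task"] == task)]
    key = ["subject", "session", "trial"]
    m = spikes.merge(tr[key + [t0_col, "condition"]], on=key, how="inner")
    rel = m["spike_time_s"] - m[t0_col]
    b = np.floor(rel / bin_s).astype(int)
    m = m.assign(bin=b)
    m = m[(m["bin"] >= 0) & (m["bin"] < n_bins)]
    counts = (m.groupby(["subject", "session", "neuron", "condition", "bin"])
              .size().rename("count").reset_index())
    ntr = (tr.groupby(["subject", "session", "condition"])
           .size().rename("n_trials").reset_index())
    counts = counts.merge(ntr, on=["subject", "session", "condition"])
    counts["rate"] = counts["count"] / (counts["n_trials"] * bin_s)
    wide = counts.pivot_table(index=["subject", "session", "neuron"],
                              columns=["condition", "bin"], values="rate",
                              fill_value=0.0)
    # ensure a complete (condition, bin) column grid
    conds = sorted(tr["condition"].unique())
    full = pd.MultiIndex.from_product([conds, range(n_bins)])
    wide = wide.reindex(columns=full, fill_value=0.0)
    return wide, conds


def _epoch_condition_means(spikes, trials, start_col, end_col, task):
    """Per (neuron, condition) mean rate in [start_col, end_col)."""
    tr = trials[(trials["outcome"] == "correct") & (trials["task"] == task)]
    key = ["subject", "session", "trial"]
    m = spikes.merge(tr[key + [start_col, end_col, "condition"]],
                     on=key, how="inner")
    dur = m[end_col] - m[start_col]
    inwin = (m["spike_time_s"] >= m[start_col]) & (m["spike_time_s"] < m[end_col])
    m = m[inwin]
    counts = (m.groupby(["subject", "session", "neuron", "condition"])
              .size().rename("count").reset_index())
    tr_dur = tr.assign(dur=tr[end_col] - tr[start_col])
    ntr = (tr_dur.groupby(["subject", "session", "condition"])
           .agg(n_trials=("trial", "size"), dur=("dur", "median")).reset_index())
    counts = counts.merge(ntr, on=["subject", "session", "condition"])
    counts["rate"] = counts["count"] / (counts["n_trials"] * counts["dur"])
    wide = counts.pivot_table(index=["subject", "session", "neuron"],
                              columns="condition", values="rate", fill_value=0.0)
    conds = sorted(tr["condition"].unique())
    wide = wide.reindex(columns=conds, fill_value=0.0)
    return wide


def temporal_dimensionality_table(spikes, trials, cue_bins=10,
                                  cue_bin_s=0.05) -> pd.DataFrame:
    """Per-neuron temporal-coding N_eff over the cue period."""
    wide, conds = _binned_condition_means(spikes, trials, "t_cue_on",
                                          cue_bins, cue_bin_s)
    rows = []
    for key, row in wide.iterrows():
        mat = row.to_numpy().reshape(len(conds), cue_bins)
        res = _geometry.temporal_dimensionality(mat)
        rows.append({"subject": key[0], "session": key[1], "neuron": key[2],
                     "n_eff_temporal": res.n_eff})
    return pd.DataFrame(rows)


def full_space_stage(spikes, trials, neurons, cfg, rng) -> pd.DataFrame:
    """Bootstrap full-space dimensionality per maturation interval."""
    delay_sub_bins = 15
    wide, conds = _binned_condition_means(spikes, trials, "t_cue_off",
                                          delay_sub_bins, 0.1)
    n_cond = len(conds)
    raw = wide.to_numpy().reshape(len(wide), n_cond, delay_sub_bins)
    # 200-ms windows stepped by 100 ms over the 1.5-s delay -> 14 windows
    resp = (raw[:, :, :-1] + raw[:, :, 1:]) / 2.0
    resp = resp.reshape(len(wide), -1).T          # (rows, neurons)
    key = pd.DataFrame(wide.index.tolist(),
                       columns=["subject", "session", "neuron"])
    ages = key.merge(neurons, on=["subject", "session", "neuron"])
    pops = _geometry.build_pseudopopulations(
        ages["rel_age_months"].to_numpy(), resp,
        n_intervals=cfg.n_intervals_full_space,
        min_neurons=cfg.min_neurons_per_interval)
    rows = []
    for pop in pops:
        vals = _geometry.full_space_dimensionality(
            pop, n_sub=cfg.n_subsample, n_boot=cfg.n_bootstrap, rng=rng)
        for rep, v in enumerate(vals):
            rows.append({"interval": pop.interval_index,
                         "rel_age_months": pop.rel_age_months,
                         "replicate": rep, "n_eff": v})
    return pd.DataFrame(rows)


def rotation_stage(spikes, trials, neurons, cfg, rng) -> pd.DataFrame:
    """Bootstrap cue/distractor subspace rotation per maturation interval."""
    task = "odr_distractor"
    if not (trials["task"] == task).any():
        return pd.DataFrame(columns=["interval", "rel_age_months",
                                     "replicate", "phi_deg",
                                     "var_explained_3pc"])
    cue = _epoch_condition_means(spikes, trials, "t_cue_on", "t_cue_off", task)
    dis = _epoch_condition_means(spikes, trials, "t_dis_on", "t_dis_off", task)
    both = cue.join(dis, lsuffix="_cue", rsuffix="_dis", how="inner")
    resp = both.to_numpy().T                       # (8, neurons)
    key = pd.DataFrame(both.index.tolist(),
                       columns=["subject", "session", "neuron"])
    ages = key.merge(neurons, on=["subject", "session", "neuron"])
    pops = _geometry.build_pseudopopulations(
        ages["rel_age_months"].to_numpy(), resp,
        n_intervals=cfg.n_intervals_rotation,
        min_neurons=cfg.min_neurons_per_interval)
    rows = []
    for pop in pops:
        df = _geometry.subspace_rotation(pop, n_sub=cfg.n_subsample,
                                         n_boot=cfg.n_bootstrap, rng=rng)
        for _, r in df.iterrows():
            rows.append({"interval": pop.interval_index,
                         "rel_age_months": pop.rel_age_months,
                         "replicate": int(r["replicate"]),
                         "phi_deg": r["phi_deg"],
                         "var_explained_3pc": r["var_explained_3pc"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _session_measures(behavior_df, session_df, neff_session) -> list:
    """(name, points-frame, family) triples for the trajectory stage."""
    out = []
    b = behavior_df.rename(columns={"DI": "DI"})
    for name in ("DI", "RT_mean"):
        pts = b[["subject", "rel_age_months", name]].rename(
            columns={name: "value"}).dropna()
        out.append((name, pts, "gaussian"))
    pc = b.dropna(subset=["percent_correct"]).assign(
        value=lambda d: d["percent_correct"] / 100.0,
        n_trials=lambda d: d["n_eligible"])
    out.append(("percent_correct",
                pc[["subject", "rel_age_months", "value", "n_trials"]],
                "proportion"))
    for name in ("rate_baseline", "rate_cue", "rate_delay",
                 "cv_isi", "cv_rate", "fano"):
        pts = session_df[["subject", "rel_age_months", name]].rename(
            columns={name: "value"}).dropna()
        out.append((name, pts, "gaussian"))
    if neff_session is not None and len(neff_session):
        out.append(("n_eff_temporal", neff_session, "gaussian"))
    return out


def run_pipeline(cfg: PipelineConfig, odr_only: bool = False) -> dict:
    """Run all stages on a synthetic cohort; returns the manifest dict."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "stages": {}}

    def record(stage, **info):
        manifest["stages"][stage] = info
        log.info("stage %-12s %s", stage, info)

    try:
        # 1. simulate ------------------------------------------------------
        spec = cfg.cohort_spec()
        if odr_only:
            spec.n_distractor_subjects = 0
        cohort = _synthetic.generate_cohort(spec)
        trials, spikes = cohort["trials"], cohort["spikes"]
        neurons, measures = cohort["neurons"], cohort["measures"]
        for name, df in (("trials", trials), ("spikes", spikes),
                         ("neurons", neurons), ("measures", measures)):
            df.to_csv(out / f"{name}.csv", index=False)
        cohort["truth"]["per_session"].to_csv(out / "truth.csv", index=False)
        record("simulate", n_trials=len(trials), n_spikes=len(spikes),
               n_neurons=len(neurons))

        # 2. behavior ------------------------------------------------------
        odr_trials = trials[trials["task"] == "odr"]
        beh = _behavior.session_behavior_table(
            odr_trials, min_trials=cfg.min_trials_per_target)
        beh["n_eligible"] = beh["n_trials"] - (
            odr_trials.groupby(["subject", "session"])["outcome"]
            .apply(lambda s: int((s == "aborted_early").sum()))
            .reindex(pd.MultiIndex.from_frame(beh[["subject", "session"]]))
            .to_numpy())
        beh.to_csv(out / "behavior_sessions.csv", index=False)
        record("behavior", n_sessions=len(beh))

        # 3. spike metrics -------------------------------------------------
        nm = _spikes.neuron_metrics_table(spikes, odr_trials)
        sm = _spikes.session_metrics_table(nm, neurons)
        nm.to_csv(out / "neuron_metrics.csv", index=False)
        sm.to_csv(out / "session_metrics.csv", index=False)
        record("spikes", n_neurons=len(nm), n_sessions=len(sm))

        # 4. selectivity ---------------------------------------------------
        sel = _selectivity.neuron_selectivity_table(
            spikes, odr_trials, n_perm=cfg.n_permutations, seed=cfg.seed)
        sel.to_csv(out / "neuron_selectivity.csv", index=False)
        n_exc = int((~sel["tau_included"]).sum())
        record("selectivity", n_neurons=len(sel), n_tau_excluded=n_exc)
        for _, r in sel[~sel["tau_included"]].iterrows():
            log.debug("excluded neuron %s/%s/%s from timescale: %s",
                      r["subject"], r["session"], r["neuron"], r["tau_reason"])

        # 5. geometry ------------------------------------------------------
        rng = substream(cfg.seed, "geometry_bootstrap")
        neff = temporal_dimensionality_table(spikes, trials)
        neff.to_csv(out / "neuron_dimensionality.csv", index=False)
        dim = full_space_stage(spikes, trials, neurons, cfg, rng)
        dim.to_csv(out / "dimensionality.csv", index=False)
        rot = rotation_stage(spikes, trials, neurons, cfg, rng)
        rot.to_csv(out / "rotation.csv", index=False)
        record("geometry", n_neff_boot=len(dim), n_rotation_boot=len(rot),
               n_eligible_intervals=int(dim["interval"].nunique())
               if len(dim) else 0)

        # 6. trajectories --------------------------------------------------
        neff_sess = (neff.merge(neurons, on=["subject", "session", "neuron"])
                     .groupby(["subject", "session", "rel_age_months"])
                     ["n_eff_temporal"].mean().reset_index()
                     .rename(columns={"n_eff_temporal": "value"})
                     [["subject", "rel_age_months", "value"]])
        measure_list = _session_measures(beh, sm, neff_sess)
        for mname, g in measures.groupby("measure_name"):
            pts = g[["subject", "rel_age_months", "value"]]
            measure_list.append((mname, pts, "gaussian"))
        # bootstrap replicates within an interval share neurons; an
        # interval-level random intercept absorbs that dependence
        if len(dim):
            measure_list.append((
                "n_eff_full_space",
                dim.assign(subject=dim["interval"].map("iv{}".format))
                .rename(columns={"n_eff": "value"})
                [["subject", "rel_age_months", "value"]], "gaussian"))
        if len(rot):
            measure_list.append((
                "rotation_phi",
                rot.assign(subject=rot["interval"].map("iv{}".format))
                .rename(columns={"phi_deg": "value"})
                [["subject", "rel_age_months", "value"]], "gaussian"))
        fits, rows = {}, []
        for name, pts, family in measure_list:
            has_subj = "subject" in pts.columns
            try:
                fit = _trajectory.fit_trajectory(
                    pts, family=family, grid_size=cfg.grid_size,
                    n_draws=cfg.n_posterior_draws,
                    random_effects=has_subj, seed=cfg.seed)
            except ValueError as exc:
                log.warning("trajectory fit skipped for %s: %s", name, exc)
                continue
            fits[name] = fit
            rows.append({"measure": name, "family": family,
                         "smooth_f": fit.smooth_f, "smooth_p": fit.smooth_p,
                         "edf": fit.edf,
                         "peak_velocity_age": fit.peak_velocity_age,
                         "extremum_age": fit.extremum_age,
                         "n_signif_intervals": len(fit.significant_intervals)})
        traj = pd.DataFrame(rows)
        traj["p_adjusted"] = _trajectory.fdr_correct(traj["smooth_p"])
        traj.to_csv(out / "trajectories.csv", index=False)
        (out / "trajectories.json").write_text(json.dumps(
            {name: fit.to_dict() for name, fit in fits.items()}, indent=1))
        record("trajectory", n_measures=len(fits))

        # 7. comparisons ---------------------------------------------------
        pairs = [("DI", "rate_baseline"), ("RT_mean", "rate_baseline"),
                 ("DI", "fa_frontal_tract"), ("RT_mean", "fa_frontal_tract"),
                 ("DI", "gm_volume"), ("DI", "cv_isi")]
        pairs = [(a, b) for a, b in pairs if a in fits and b in fits]
        prepared, meta = [], []
        for a, b in pairs:
            fa, fb = fits[a], fits[b]
            try:
                x, y, _ = _compare.resample_and_normalize(
                    fa.grid, fa.fitted, fb.grid, fb.fitted,
                    n_points=cfg.compare_points)
            except ValueError as exc:
                log.warning("comparison skipped for (%s, %s): %s", a, b, exc)
                continue
            prepared.append((x, y))
            meta.append((a, b, x, y))
        comp_rows = []
        if prepared:
            results = _compare.maxt_correlation_test(
                prepared, n_perm=cfg.n_permutations,
                rng=substream(cfg.seed, "maxt"))
            for (a, b, x, y), (r, p) in zip(meta, results):
                comp_rows.append({
                    "measureA": a, "measureB": b, "r": r,
                    "RMSE": _compare.curve_rmse(x, y), "p_maxT": p,
                    "n_perm": cfg.n_permutations, "seed": cfg.seed})
        comp = pd.DataFrame(comp_rows)
        comp.to_csv(out / "comparisons.csv", index=False)
        record("compare", n_pairs=len(comp))
    except Exception as exc:
        stage = STAGES[len(manifest["stages"])] if \
            len(manifest["stages"]) < len(STAGES) else "unknown"
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    manifest["seed"] = cfg.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
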