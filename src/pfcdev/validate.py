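"""Schema and referential-integrity checks for the pipeline's CSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["validate_tables", "TABLE_SCHEMAS"]

TABLE_SCHEMAS = {
    "trials": ["subject", "session", "age_months", "rel_age_months", "trial",
               "condition", "distractor_condition", "outcome", "t_fix_on",
               "t_cue_on", "t_cue_off", "t_fix_off", "sacc_onset_s",
               "endpoint_x_deg", "endpoint_y_deg"],
    "spikes": ["subject", "session", "neuron", "trial", "spike_time_s"],
    "neurons": ["subject", "session", "neuron", "rel_age_months"],
    "measures": ["subject", "age_months", "rel_age_months", "measure_name",
                 "value"],
}

_NUMERIC = {"age_months", "rel_age_months", "t_fix_on", "t_cue_on",
            "t_cue_off", "t_fix_off", "sacc_onset_s", "endpoint_x_deg",
            "endpoint_y_deg", "spike_time_s", "value"}


def validate_tables(tables: dict) -> list:
    """Validate a set of tables; returns a list of violation strings.

    `tables` maps table name -> DataFrame or CSV path.  Checks: required
    columns present, numeric columns numeric, spikes reference existing
    trials, trials reference sessions listed in `neurons` (when both
    present), and spike times sorted within each (neuron, trial).
    """
    loaded = {}
    violations = []
    for name, t in tables.items():
        if isinstance(t, (str, Path)):
            try:
                t = pd.read_csv(t)
            except OSError as exc:
                raise OSError(f"cannot read table {name!r}: {exc}") from exc
        loaded[name] = t
        schema = TABLE_SCHEMAS.get(name)
        if schema:
            missing = [c for c in schema if c not in t.columns]
            for c in missing:
                violations.append(f"{name}: missing column '{c}'")
            for c in set(schema) & _NUMERIC & set(t.columns):
                if not pd.api.types.is_numeric_dtype(t[c]):
                    violations.append(f"{name}: column '{c}' not numeric")

    if "spikes" in loaded and "trials" in loaded:
        sp, tr = loaded["spikes"], loaded["trials"]
        key = ["subject", "session", "trial"]
        if all(c in sp.columns for c in key) and all(c in tr.columns for c in key):
            trial_keys = set(map(tuple, tr[key].itertuples(index=False)))
            spike_keys = set(map(tuple, sp[key].drop_duplicates()
                                 .itertuples(index=False)))
            for k in sorted(spike_keys - trial_keys):
                violations.append(f"spikes: reference to missing trial {k}")
            unsorted = (sp.groupby(["subject", "session", "neuron", "trial"])
                        ["spike_time_s"]
                        .apply(lambda s: bool((s.diff().dropna() < 0).any())))
            for k in unsorted[unsorted].index:
                violations.append(f"spikes: unsorted spike times in {tuple(k)}")

    if "trials" in loaded and "neurons" in loaded:
        tr, ne = loaded["trials"], loaded["neurons"]
        skey = ["subject", "session"]
        if all(c in tr.columns for c in skey) and all(c in ne.columns for c in skey):
            sess_tr = set(map(tuple, tr[skey].drop_duplicates()
                              .itertuples(index=False)))
            sess_ne = set(map(tuple, ne[skey].drop_duplicates()
                              .itertuples(index=False)))
            for k in sorted(sess_ne - sess_tr):
                violations.append(f"neurons: session {k} has no trials")
    return violations
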