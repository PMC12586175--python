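"""PCA-based population geometry: effective dimensionality and subspace rotation.

Effective dimensionality is the participation ratio of a PCA eigenspectrum,
N_eff = (sum lambda)^2 / sum lambda^2, which counts eigenvalues weighted so
that many small (noise) components contribute little.  It is computed

* per neuron, over the 8 condition-mean temporal profiles in ten 50-ms cue
  bins (temporal coding dimensionality), and
* per maturation interval, over pseudo-populations of neurons pooled across
  subjects, with condition x delay-time rows and bootstrap resampling of
  neurons.

Subspace rotation quantifies how differently the same four stimulus
locations are represented in the cue vs. distractor epochs: condition means
are z-scored per neuron, projected onto the first three principal
components, a plane is fitted to each epoch's four points by total least
squares, and the rotation is the acute angle between the plane normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "participation_ratio", "temporal_dimensionality",
    "PseudoPopulation", "build_pseudopopulations",
    "full_space_dimensionality", "fit_plane_normal", "subspace_rotation",
    "rotation_angle_deg", "DimensionalityResult",
]


def participation_ratio(eigenvalues) -> float:
    """(sum lambda)^2 / sum lambda^2 over non-negative eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return float("nan")
    return float(lam.sum() ** 2 / np.sum(lam ** 2))


def _eig_from_rows(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues of the covariance of the rows after centering columns."""
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    # singular values give eigenvalues of X'X/(n-1) without forming it
    s = np.linalg.svd(xc, compute_uv=False)
    lam = s ** 2 / max(n - 1, 1)
    return lam


@dataclass
class DimensionalityResult:
    n_eff: float
    spectrum: np.ndarray


def temporal_dimensionality(condition_means: np.ndarray) -> DimensionalityResult:
    """N_eff of one neuron's condition x time-bin mean-rate matrix.

    `condition_means` is (8 conditions, 10 bins): per-condition mean firing
    rate in ten consecutive 50-ms bins of the cue period.  Columns are
    centered; eigenvalues come from the covariance over the condition rows.
    """
    x = np.asarray(condition_means, dtype=float)
    lam = _eig_from_rows(x)
    if np.all(lam <= 1e-300):
        import warnings
        warnings.warn("constant condition x time matrix; N_eff undefined")
        return DimensionalityResult(float("nan"), lam)
    return DimensionalityResult(participation_ratio(lam), lam)


# ---------------------------------------------------------------------------
# pseudo-populations
# ---------------------------------------------------------------------------

@dataclass
class PseudoPopulation:
    """Neurons pooled into one maturation interval.

    `responses` is (n_rows, n_neurons): each column is one neuron's
    condition(-by-time) mean-rate vector; rows are condition (x time bin)
    entries in a fixed order shared by all neurons in all intervals.
    """
    interval_index: int
    lo_months: float
    hi_months: float
    rel_age_months: float          # mean rel age of member neurons
    neuron_ids: list
    responses: np.ndarray
    eligible: bool = True

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]


def build_pseudopopulations(
    rel_ages,
    responses: np.ndarray,
    neuron_ids: Optional[Sequence] = None,
    n_intervals: int = 20,
    min_neurons: int = 30,
) -> list:
    """Partition neurons into even maturation intervals by relative age.

    The span [min age, max age] is cut into `n_intervals` equal intervals;
    a neuron on an interior boundary goes to the interval on its right
    (left-closed convention); the last interval is closed on both sides.
    Intervals with fewer than `min_neurons` members are flagged ineligible.
    """
    ages = np.asarray(rel_ages, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if ages.size == 0:
        raise ValueError("no neurons supplied")
    if resp.shape[1] != ages.size:
        raise ValueError("responses must have one column per neuron")
    if neuron_ids is None:
        neuron_ids = list(range(ages.size))
    lo, hi = float(ages.min()), float(ages.max())
    edges = np.linspace(lo, hi, n_intervals + 1)
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                  0, n_intervals - 1)
    pops = []
    for i in range(n_intervals):
        members = np.flatnonzero(idx == i)
        if members.size == 0:
            pops.append(PseudoPopulation(
                i, float(edges[i]), float(edges[i + 1]), np.nan, [],
                np.empty((resp.shape[0], 0)), eligible=False))
            continue
        pops.append(PseudoPopulation(
            i, float(edges[i]), float(edges[i + 1]),
            float(ages[members].mean()),
            [neuron_ids[j] for j in members],
            resp[:, members],
            eligible=members.size >= min_neurons))
    return pops


def full_space_dimensionality(
    pop: PseudoPopulation,
    n_sub: int = 30,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Bootstrap N_eff values for one pseudo-population.

    Per replicate: sample `n_sub` neurons with replacement, center each
    neuron column over the condition x time rows, and take the participation
    ratio of the PCA eigenspectrum.  Returns an (n_boot,) array.
    """
    if not pop.eligible or pop.n_neurons < n_sub:
        import warnings
        warnings.warn(f"interval {pop.interval_index} ineligible "
                      f"({pop.n_neurons} < {n_sub} neurons); skipped")
        return np.empty(0)
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.integers(0, pop.n_neurons, size=n_sub)
        out[b] = participation_ratio(_eig_from_rows(pop.responses[:, cols]))
    return out


# ---------------------------------------------------------------------------
# subspace rotation
# ---------------------------------------------------------------------------

def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through >= 4 3-D points.

    The normal is the eigenvector of the centered point covariance with the
    smallest eigenvalue — the closed form of minimizing the summed squared
    point-to-plane distances.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 4 or p.shape[1] != 3:
        raise ValueError("need >= 4 points in 3-D")
    pc = p - p.mean(axis=0, keepdims=True)
    # collinear points leave the plane undetermined
    s = np.linalg.svd(pc, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) points; plane undetermined")
    cov = pc.T @ pc
    w, v = np.linalg.eigh(cov)
    return v[:, 0] / np.linalg.norm(v[:, 0])


def rotation_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, in degrees."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def _rotation_one(matrix: np.ndarray) -> tuple:
    """Rotation angle for one 8 x N condition-mean matrix.

    Rows 0-3 are cue-epoch condition means, rows 4-7 distractor-epoch means.
    z-scores each neuron column, projects the 8 points onto the first three
    principal components, fits one plane per epoch and returns
    (angle_deg, fraction of variance explained by the 3 PCs).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] != 8:
        raise ValueError("matrix must have 8 rows (4 locations x 2 epochs)")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 non-constant neurons")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :3] * s[:3]
    var_frac = float(np.sum(s[:3] ** 2) / np.sum(s ** 2))
    n_cue = fit_plane_normal(scores[:4])
    n_dis = fit_plane_normal(scores[4:])
    return rotation_angle_deg(n_cue, n_dis), var_frac


def subspace_rotation(
    pop: PseudoPopulation,
    n_sub: int = 30,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Bootstrap distribution of the cue/distractor rotation angle.

    `pop.responses` must be the 8 x N matrix of 4 cue-epoch + 4
    distractor-epoch condition means per neuron.  Per replicate, `n_sub`
    neurons are resampled with replacement and the angle recomputed; the 3-PC
    projection is refit within each replicate.  Degenerate replicates are
    dropped (their count is in `attrs["n_discarded"]`).
    """
    if not pop.eligible or pop.n_neurons < n_sub:
        import warnings
        warnings.warn(f"interval {pop.interval_index} ineligible for rotation; skipped")
        return pd.DataFrame(columns=["replicate", "phi_deg", "var_explained_3pc"])
    if rng is None:
        rng = np.random.default_rng(0)
    rows, discarded = [], 0
    for b in range(n_boot):
        cols = rng.integers(0, pop.n_neurons, size=n_sub)
        try:
            phi, var3 = _rotation_one(pop.responses[:, cols])
        except ValueError:
            discarded += 1
            continue
        rows.append({"replicate": b, "phi_deg": phi, "var_explained_3pc": var3})
    out = pd.DataFrame(rows)
    out.attrs["n_discarded"] = discarded
    return out
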