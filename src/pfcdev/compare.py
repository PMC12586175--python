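"""Similarity between two fitted developmental trajectories.

Both curves are evaluated at 100 evenly spaced relative ages over their
overlapping range and z-scored.  Two statistics are reported:

* Pearson r between the z-scored curves,
* a shape-distance RMSE computed after shifting each z-scored curve so its
  first sample is zero and taking absolute values (so positively and
  negatively correlated pairs are directly comparable),
  RMSE = sqrt(mean((|X_i| - |Y_i|)^2)).

Significance uses a maxT permutation test: per permutation the sample order
of X and of Y is independently shuffled, |r| is recomputed for every pair in
the tested family, and the familywise null statistic is the maximum |r|
across the family.  Note that smooth curves are strongly autocorrelated, so
permuting samples independently is anti-conservative; a block permutation
mode is available for more honest inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "ComparisonResult", "resample_and_normalize", "curve_rmse",
    "maxt_correlation_test", "compare_trajectories",
]

N_POINTS = 100


@dataclass
class ComparisonResult:
    r: float
    rmse: float
    p_maxt: float
    n_points: int
    x: np.ndarray
    y: np.ndarray


def resample_and_normalize(grid_a, curve_a, grid_b, curve_b,
                           n_points: int = N_POINTS) -> tuple:
    """Evaluate two fitted curves on a common grid and z-score each.

    The common grid has `n_points` evenly spaced points over the overlap of
    the two age ranges.  Raises if the ranges do not overlap or either curve
    is constant over the overlap.
    """
    ga = np.asarray(grid_a, dtype=float)
    gb = np.asarray(grid_b, dtype=float)
    lo, hi = max(ga.min(), gb.min()), min(ga.max(), gb.max())
    if hi <= lo:
        raise ValueError("age ranges do not overlap")
    grid = np.linspace(lo, hi, n_points)
    x = np.interp(grid, ga, np.asarray(curve_a, dtype=float))
    y = np.interp(grid, gb, np.asarray(curve_b, dtype=float))
    for name, v in (("first", x), ("second", v2 := y)):
        if np.std(v) == 0:
            raise ValueError(f"{name} curve has zero variance over the overlap")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    return x, y, grid


def curve_rmse(x, y) -> float:
    """Shifted-absolute RMSE between two equally sampled (z-scored) curves."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("curves must have equal length >= 2")
    xs = np.abs(x - x[0])
    ys = np.abs(y - y[0])
    return float(np.sqrt(np.mean((xs - ys) ** 2)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def maxt_correlation_test(
    pairs: Sequence[tuple],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    block: Optional[int] = None,
) -> list:
    """Single-step maxT permutation test over a family of curve pairs.

    `pairs` is a sequence of (X, Y) sample arrays (already resampled and
    normalized).  Per permutation, the sample order of X and Y is shuffled
    independently in every pair; the null statistic is max |r| over the
    family.  With `block` set, contiguous blocks of that length are permuted
    instead of single samples (less anti-conservative for smooth curves).

    Returns a list of (r_obs, p_maxt), one per pair, where every p uses the
    familywise max distribution (two-sided on |r|, add-one convention).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = substream(seed, "maxt_correlation")
    prepared = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("constant input curve")
        prepared.append((x, y))
    r_obs = [_pearson(x, y) for x, y in prepared]

    def _perm_index(n: int) -> np.ndarray:
        if block is None or block <= 1:
            return rng.permutation(n)
        n_blocks = int(np.ceil(n / block))
        order = rng.permutation(n_blocks)
        idx = np.concatenate([np.arange(b * block, min((b + 1) * block, n))
                              for b in order])
        return idx

    max_null = np.empty(n_perm)
    for i in range(n_perm):
        best = 0.0
        for x, y in prepared:
            xp = x[_perm_index(len(x))]
            yp = y[_perm_index(len(y))]
            best = max(best, abs(_pearson(xp, yp)))
        max_null[i] = best
    out = []
    for r in r_obs:
        p = (1 + int(np.count_nonzero(max_null >= abs(r)))) / (1 + n_perm)
        out.append((r, float(p)))
    return out


def compare_trajectories(
    grid_a, curve_a, grid_b, curve_b,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    block: Optional[int] = None,
) -> ComparisonResult:
    """Full two-curve comparison: resample, z-score, r, RMSE and maxT p."""
    x, y, _ = resample_and_normalize(grid_a, curve_a, grid_b, curve_b)
    (r, p), = maxt_correlation_test([(x, y)], n_perm=n_perm, rng=rng,
                                    seed=seed, block=block)
    return ComparisonResult(r=r, rmse=curve_rmse(x, y), p_maxt=p,
                            n_points=len(x), x=x, y=y)
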