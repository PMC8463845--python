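"""Histogram and point-cloud utilities shared by the collapse functionals.

Collapsed distributions are compared as point clouds in log–log(–log)
space.  Binning uses a fixed number of log-spaced bins spanning the
pooled rescaled range of all member distributions, so every member is
histogrammed on a common grid at each candidate exponent.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "log_edges",
    "standardize_clouds",
    "pairwise_nn_distance",
]

DEFAULT_BINS = 30


def log_edges(pooled: np.ndarray, n_bins: int) -> np.ndarray:
    """Log-spaced bin edges spanning the pooled positive sample range."""
    lo = float(pooled.min())
    hi = float(pooled.max())
    if not lo > 0:
        raise ValueError("samples must be strictly positive for log binning")
    if lo == hi:
        raise ValueError("degenerate (all-equal) samples cannot be binned")
    return np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)


def standardize_clouds(clouds: list[np.ndarray]) -> list[np.ndarray]:
    """Scale each axis by the pooled range so distances are unit-free."""
    allpts = np.vstack(clouds)
    lo = allpts.min(axis=0)
    span = allpts.max(axis=0) - lo
    span[span == 0] = 1.0
    return [(c - lo) / span for c in clouds]


def pairwise_nn_distance(clouds: list[np.ndarray]) -> float:
    """Sum over ordered pairs of the mean squared nearest-neighbor distance.

    For each ordered pair (k, l), every point of cloud k is matched to
    its nearest neighbor in cloud l; the squared Euclidean distances are
    averaged over cloud k's points.  Summing over ordered pairs makes
    the functional symmetric under relabeling.
    """
    std = standardize_clouds(clouds)
    trees = [cKDTree(c) for c in std]
    total = 0.0
    for k, ck in enumerate(std):
        for l, tree in enumerate(trees):
            if k == l:
                continue
            d, _ = tree.query(ck, k=1)
            total += float(np.mean(d**2))
    return total
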