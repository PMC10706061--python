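"""Maturity-stage assignment by spectral clustering of the chemistry indicators.

Ground-truth stages are not measured directly; they are constructed by
clustering the four quality indicators (SSC, TA, TP, TN) into five groups
and ordering the groups by mean sugar content.  The clustering is the
Ng-Jordan-Weiss normalised variant: Gaussian affinity on z-scored
indicators (median-heuristic bandwidth), normalised symmetric Laplacian,
row-normalised eigenvector embedding, k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .containers import INDICATOR_COLUMNS, stage_name

__all__ = ["SclConfig", "build_affinity", "spectral_cluster", "stage_summary"]


class ClusteringError(RuntimeError):
    pass


@dataclass
class SclConfig:
    """Spectral-clustering settings: 5 stages, median-heuristic bandwidth."""

    k: int = 5
    affinity_sigma: float | str = "median-heuristic"
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _indicator_matrix(chem: pd.DataFrame) -> np.ndarray:
    z = chem[list(INDICATOR_COLUMNS)].to_numpy(dtype=float)
    sd = z.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = INDICATOR_COLUMNS[int(np.flatnonzero(sd == 0)[0])]
        raise ClusteringError(f"indicator {bad!r} has zero variance")
    return (z - z.mean(axis=0)) / sd


def build_affinity(chem: pd.DataFrame, config: SclConfig) -> np.ndarray:
    """Gaussian affinity exp(-d^2 / 2 sigma^2) on z-scored indicators.

    sigma is the median pairwise Euclidean distance when the config says
    "median-heuristic".  Fully connected; diagonal zeroed.
    """
    z = _indicator_matrix(chem)
    n = z.shape[0]
    if n < 2:
        raise ClusteringError("need at least two samples")
    if config.k > n - 1:
        # k == n is the trivial one-sample-per-cluster case, still allowed
        if config.k > n:
            raise ClusteringError("k exceeds sample count")
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    if config.affinity_sigma == "median-heuristic":
        iu = np.triu_indices(n, k=1)
        sigma = float(np.median(np.sqrt(d2[iu])))
        if sigma == 0:
            sigma = 1.0  # all points coincide; affinity all ones
    else:
        sigma = float(config.affinity_sigma)
    w = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w


def spectral_cluster(
    affinity: np.ndarray, config: SclConfig, chem: pd.DataFrame | None = None
) -> np.ndarray:
    """NJW spectral clustering; stages ordered by ascending cluster-mean SSC.

    Returns 0-based stage indices.  When ``chem`` is omitted the raw
    k-means labels are returned unordered (useful for tests on point
    clouds without chemistry).
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n) or not np.allclose(w, w.T, atol=1e-10):
        raise ClusteringError("affinity must be a symmetric square matrix")
    k = config.k
    if k == n:
        return np.arange(n)
    deg = w.sum(axis=1)
    if np.any(deg == 0):
        raise ClusteringError("isolated vertex in affinity graph")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    # k eigenvectors of the k smallest eigenvalues
    _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    km = KMeans(
        n_clusters=k,
        n_init=config.kmeans_restarts,
        random_state=config.seed,
    ).fit(emb)
    raw = km.labels_
    if chem is None:
        return raw
    # relabel so stage order follows ascending cluster-mean SSC
    ssc = chem["ssc_brix"].to_numpy(dtype=float)
    means = [ssc[raw == c].mean() for c in range(k)]
    order = np.argsort(means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def stage_summary(chem: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-stage indicator means/SDs and counts, for comparison tables."""
    df = chem.copy()
    df["_stage"] = [stage_name(s) for s in labels]
    agg = df.groupby("_stage")[list(INDICATOR_COLUMNS) + ["ssc_ta_ratio"]].agg(
        ["mean", "std", "count"]
    )
    return agg
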