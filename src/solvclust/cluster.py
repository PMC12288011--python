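"""Hierarchical clustering of the RMSD matrix and quality metrics.

Agglomerative linkage, dendrogram cutting, the four cluster-quality
scores (silhouette, Calinski–Harabasz, Davies–Bouldin, cophenetic
correlation) and silhouette-driven automatic threshold selection.

The silhouette score is evaluated directly on the precomputed RMSD
matrix.  Calinski–Harabasz and Davies–Bouldin are centroid-based and need
point coordinates; by convention each frame is represented by its row of
the full (squareform) RMSD matrix as a feature vector — the standard
device for precomputed-distance workflows.  The cophenetic correlation is
the Pearson correlation between the original condensed distances and the
tree-implied (cophenetic) distances.

Ward, centroid and median linkage formally assume Euclidean distances;
applying them to a generic RMSD matrix is a common heuristic and is
allowed here with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .pairdist import CondensedRMSDMatrix

__all__ = [
    "LINKAGE_METHODS",
    "ClusterResult",
    "linkage",
    "cut",
    "silhouette",
    "scores",
    "auto_threshold",
]

logger = logging.getLogger(__name__)

LINKAGE_METHODS = (
    "single", "complete", "average", "weighted", "centroid", "median", "ward",
)
_EUCLIDEAN_ONLY = ("centroid", "median", "ward")


@dataclass
class ClusterResult:
    """Flat clustering of the M frames.

    ``labels`` are 1-based cluster ids assigned by order of first
    appearance along the trajectory (frame 1 always belongs to cluster 1),
    so repeated runs and plots are deterministic.
    """

    labels: np.ndarray
    threshold: float
    n_clusters: int
    scores: dict[str, float] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() != self.n_clusters:
            raise ValueError("labels must be 1..n_clusters")


def linkage(m: CondensedRMSDMatrix, method: str = "ward") -> np.ndarray:
    """Agglomerative linkage of the condensed RMSD matrix.

    Returns the SciPy linkage matrix: M-1 rows of
    (left, right, height, size).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(
            f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}"
        )
    if method in _EUCLIDEAN_ONLY:
        logger.warning(
            "%s linkage formally assumes Euclidean distances; using it on a "
            "generic RMSD matrix is heuristic", method,
        )
    return sch.linkage(m.d, method=method)


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    """Renumber labels so ids follow order of first appearance (1-based)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cut(tree: np.ndarray, threshold: float) -> ClusterResult:
    """Flat clusters from cutting the dendrogram at ``threshold`` (Å).

    Leaves whose merge heights are all ≤ threshold end up in one cluster.
    Monotone: raising the threshold never increases the cluster count.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    raw = sch.fcluster(tree, t=threshold, criterion="distance")
    labels = _relabel_first_appearance(raw)
    return ClusterResult(labels, float(threshold), int(labels.max()))


def silhouette(m: CondensedRMSDMatrix, labels: np.ndarray) -> float:
    """Mean silhouette coefficient from the precomputed RMSD matrix.

    Requires 2 ≤ n_clusters ≤ M-1; undefined otherwise.
    """
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if not 2 <= k <= m.M - 1:
        raise ValueError("silhouette needs 2 <= n_clusters <= M-1")
    return float(silhouette_score(m.squareform(), labels, metric="precomputed"))


def cophenetic_correlation(m: CondensedRMSDMatrix, tree: np.ndarray) -> float:
    """Pearson correlation between original and cophenetic distances."""
    c, _ = sch.cophenet(tree, m.d)
    return float(c)


def scores(
    m: CondensedRMSDMatrix, labels: np.ndarray, tree: np.ndarray
) -> dict[str, float]:
    """All four quality metrics: ss, ch, db, cpcc.

    Raises on degenerate partitions for which a metric is undefined
    (e.g. Davies–Bouldin with coincident singleton clusters).
    """
    labels = np.asarray(labels)
    if np.all(m.d == 0):
        raise ValueError(
            "all pairwise distances are zero: cluster metrics undefined"
        )
    ss = silhouette(m, labels)
    X = m.squareform()  # frame i featurised as its distance-matrix row
    ch = float(calinski_harabasz_score(X, labels))
    with np.errstate(divide="ignore", invalid="ignore"):
        db = float(davies_bouldin_score(X, labels))
    with np.errstate(divide="ignore", invalid="ignore"):
        cpcc = cophenetic_correlation(m, tree)
    out = {"ss": ss, "ch": ch, "db": db, "cpcc": cpcc}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"undefined for this partition: {', '.join(bad)}")
    return out


def _candidate_thresholds(tree: np.ndarray) -> np.ndarray:
    """Scan grid: midpoints between consecutive distinct merge heights,
    plus each height ± a small relative epsilon."""
    heights = np.unique(tree[:, 2])
    eps = 1e-9 * np.maximum(np.abs(heights), 1.0)
    cands = [heights - eps, heights + eps]
    if len(heights) > 1:
        cands.append((heights[:-1] + heights[1:]) / 2.0)
    grid = np.unique(np.concatenate(cands))
    return grid[grid > 0]


def _labels_after_merges(tree: np.ndarray, n_merges: int) -> np.ndarray:
    """Partition after performing the first ``n_merges`` linkage rows.

    Equivalent to a distance cut for untied trees; with tied merge
    heights it breaks the tie deterministically by merge order, reaching
    partitions no distance threshold can express.
    """
    M = tree.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(M)}
    for k, row in enumerate(tree[:n_merges]):
        a, b = int(row[0]), int(row[1])
        members[M + k] = members.pop(a) + members.pop(b)
    raw = np.empty(M, dtype=int)
    for cid, mem in enumerate(members.values(), start=1):
        for i in mem:
            raw[i] = cid
    return _relabel_first_appearance(raw)


def auto_threshold(
    m: CondensedRMSDMatrix, tree: np.ndarray
) -> tuple[float, ClusterResult]:
    """Pick the cut threshold maximizing the silhouette score.

    Every distinct merge height (± epsilon, plus midpoints between
    consecutive heights) is tried; cuts producing fewer than 2 or more
    than M-1 clusters are skipped.  When tied merge heights make a
    cluster count unreachable by any distance threshold, the tie is
    broken by merge order and the cut is reported just below the tied
    height.  Ties in silhouette are resolved in favour of the smallest
    threshold.  The returned result carries all four quality scores.
    """
    if m.M < 3:
        raise ValueError("automatic threshold needs at least 3 frames")
    # candidate partitions, each with the smallest threshold producing it
    cands: dict[tuple, float] = {}
    for t in _candidate_thresholds(tree):  # ascending
        res = cut(tree, t)
        if 2 <= res.n_clusters <= m.M - 1:
            cands.setdefault(tuple(res.labels), float(t))
    for j in range(1, m.M):  # tie-broken prefixes of the merge sequence
        k = m.M - j
        if not 2 <= k <= m.M - 1:
            continue
        labels = _labels_after_merges(tree, j)
        h = float(tree[j - 1, 2])
        t = h - 1e-9 * max(abs(h), 1.0)
        if t > 0:
            cands.setdefault(tuple(labels), t)
    if not cands:
        raise ValueError("no cut produces between 2 and M-1 clusters")
    evaluated = [
        (silhouette(m, np.array(key)), t, key) for key, t in cands.items()
    ]
    best_ss = max(e[0] for e in evaluated)
    ties = [e for e in evaluated if e[0] >= best_ss - 1e-15]
    best_ss, t, labels_key = min(ties, key=lambda e: e[1])
    labels = np.array(labels_key)
    res = ClusterResult(labels, t, int(labels.max()))
    try:
        res.scores = scores(m, labels, tree)
    except ValueError as exc:  # degenerate matrix: keep what is defined
        logger.warning("some quality scores undefined: %s", exc)
        res.scores = {"ss": float(best_ss)}
    return t, res
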