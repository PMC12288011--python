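"""Cluster reporting: medoids, per-cluster trajectories, plots, summaries.

The medoid of a cluster is the member with the smallest sum of RMSDs to
all other members — the cluster's representative configuration (e.g. for
picking frames for follow-up quantum-chemistry calculations).  Ties go to
the lowest frame index.

Numeric inputs of every plot (linkage merge table, labels, projection
coordinates) are also written as plain text so downstream analysis never
has to parse images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .cluster import ClusterResult
from .pairdist import CondensedRMSDMatrix, PairOptions, pair_min_rmsd
from .traj_io import Snapshot, Trajectory, write_trajectory

__all__ = [
    "ClusterSummary",
    "find_medoid",
    "cluster_summaries",
    "write_assignments",
    "write_cluster_trajectories",
    "summary_stats",
    "classical_mds",
    "dendrogram_data",
    "plot_dendrogram",
    "plot_projection",
]


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    member_frames: tuple[int, ...]
    medoid_frame: int
    population: int
    mean_intra_rmsd: float


def find_medoid(m: CondensedRMSDMatrix, members: Sequence[int]) -> int:
    """Member with the smallest sum of RMSDs to the other members.

    ``members`` are 0-based frame indices; ties are broken by the lowest
    frame index.  A singleton cluster's medoid is its single member.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    sub = m.squareform()[np.ix_(members, members)]
    return members[int(np.argmin(sub.sum(axis=1)))]


def cluster_summaries(
    m: CondensedRMSDMatrix, result: ClusterResult
) -> list[ClusterSummary]:
    """Per-cluster membership, medoid and mean intra-cluster RMSD."""
    out = []
    sq = m.squareform()
    for cid in range(1, result.n_clusters + 1):
        members = np.flatnonzero(result.labels == cid)
        sub = sq[np.ix_(members, members)]
        k = len(members)
        mean_intra = float(sub.sum() / (k * (k - 1))) if k > 1 else 0.0
        out.append(
            ClusterSummary(
                cluster_id=cid,
                member_frames=tuple(int(i) for i in members),
                medoid_frame=find_medoid(m, members),
                population=k,
                mean_intra_rmsd=mean_intra,
            )
        )
    return out


def write_assignments(result: ClusterResult, path: str | Path) -> None:
    """Two-column text file: frame index (1-based), cluster id."""
    with open(path, "w") as fh:
        fh.write("# frame  cluster\n")
        for i, lab in enumerate(result.labels, start=1):
            fh.write(f"{i} {lab}\n")


def write_cluster_trajectories(
    traj: Trajectory,
    result: ClusterResult,
    m: CondensedRMSDMatrix,
    opts: PairOptions,
    outdir: str | Path,
    fmt: str = "xyz",
) -> list[Path]:
    """One multi-frame file per cluster, members superposed on the medoid.

    The medoid is written first; every other member is relabeled and
    aligned onto it with the same pairwise procedure used for the matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for summ in cluster_summaries(m, result):
        med = traj[summ.medoid_frame]
        frames = [med]
        for fidx in summ.member_frames:
            if fidx == summ.medoid_frame:
                continue
            _, aligned = pair_min_rmsd(
                med, traj[fidx], opts, return_aligned=True
            )
            frames.append(Snapshot(med.elements, aligned, fidx))
        path = outdir / f"cluster_{summ.cluster_id}.{fmt}"
        write_trajectory(frames, path, fmt=fmt)
        paths.append(path)
    return paths


def summary_stats(
    rows: pd.DataFrame | Sequence[dict],
    x: str | None = None,
    y: str | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Tabulate per-run clustering results; optionally correlate two columns.

    Each row describes one clustering run (e.g. n_clusters, threshold,
    silhouette score, RMSD matrix sum).  When ``x`` and ``y`` name two
    columns, the Pearson correlation coefficient between them is returned
    alongside the table; a zero-variance column makes the correlation
    undefined and raises.
    """
    table = pd.DataFrame(rows)
    r = None
    if x is not None or y is not None:
        if x is None or y is None:
            raise ValueError("need both x and y to correlate")
        if len(table) < 2:
            raise ValueError("Pearson correlation needs >= 2 observations")
        xs = table[x].to_numpy(dtype=float)
        ys = table[y].to_numpy(dtype=float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise ValueError("Pearson correlation undefined: zero variance")
        r = float(pearsonr(xs, ys).statistic)
    return table, r


def classical_mds(m: CondensedRMSDMatrix, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS embedding of the RMSD matrix.

    Double-centers the squared distances and keeps the leading
    non-negative eigenpairs.  Component signs are fixed so the entry of
    largest magnitude in each column is positive (deterministic output).
    """
    D2 = m.squareform() ** 2
    n = m.M
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(vals)
    for k in range(X.shape[1]):
        if np.abs(X[:, k]).max() > 0 and X[np.argmax(np.abs(X[:, k])), k] < 0:
            X[:, k] *= -1
    return X


def dendrogram_data(tree: np.ndarray) -> dict:
    """Dendrogram geometry as plain data (no plotting)."""
    import scipy.cluster.hierarchy as sch

    dd = sch.dendrogram(tree, no_plot=True)
    return {k: dd[k] for k in ("icoord", "dcoord", "ivl", "leaves")}


def plot_dendrogram(
    tree: np.ndarray, path: str | Path, threshold: float | None = None
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import scipy.cluster.hierarchy as sch

    fig, ax = plt.subplots(figsize=(8, 5))
    sch.dendrogram(tree, ax=ax, color_threshold=threshold)
    if threshold is not None:
        ax.axhline(threshold, ls="--", c="k", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("RMSD (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_projection(
    m: CondensedRMSDMatrix, result: ClusterResult, path: str | Path
) -> np.ndarray:
    """2-D classical-MDS scatter of the frames, colored by cluster.

    Returns the embedding so callers can store the numbers as text.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = classical_mds(m, 2)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(X[:, 0], X[:, 1], c=result.labels, cmap="tab10", s=25)
    ax.set_xlabel("MDS 1 (Å)")
    ax.set_ylabel("MDS 2 (Å)")
    fig.colorbar(sc, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return X


def write_summary_json(path: str | Path, **payload) -> None:
    """Key-value run summary as JSON text."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, ClusterSummary):
            return asdict(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
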