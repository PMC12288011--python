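"""Model/Results front end tying the pipeline together.

:class:`TrajectoryClustering` is constructed from a trajectory (in memory
or from a file) plus the solute/solvent options; :meth:`fit` runs the
pairwise minimum-RMSD matrix, the hierarchical linkage and the threshold
selection, and returns a :class:`ClusteringResults` carrying labels,
scores, medoids and writers for all output artifacts.

Example
-------
>>> model = TrajectoryClustering.from_file("traj.xyz", n_solute=5)
>>> res = model.fit(threshold="auto")
>>> print(res.summary())
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import report as _report
from .pairdist import (
    CondensedRMSDMatrix,
    PairOptions,
    matrix_sum,
    rmsd_matrix,
)
from .traj_io import (
    SoluteSpec,
    Trajectory,
    apply_selection,
    parse_ranges,
    read_trajectory,
)

__all__ = ["TrajectoryClustering", "ClusteringResults"]

logger = logging.getLogger(__name__)


class TrajectoryClustering:
    """Solvent-informed hierarchical clustering of a molecular trajectory.

    Parameters
    ----------
    trajectory : Trajectory
        Frames of identical composition, solute atoms first.
    n_solute : int
        Number of leading solute atoms in the *original* frames.
    w_solute : float or None
        Total solute weight in [0, 1]; ``None`` means uniform atom weights.
    reorder : str
        Label-reordering algorithm: hungarian (default), hungarian_inertia,
        distance, brute, or none.
    linkage : str
        Linkage method (default ward).
    no_hydrogen : bool
        Drop all H/D atoms before clustering.
    exclude : str or iterable of int
        Additional exclusions, as comma-separated 1-based inclusive ranges
        ("5-9,22") or an iterable of 1-based labels.
    final_kabsch : bool
        Apply the optional all-atom rotation after solvent relabeling
        (default True; it can only lower the reported RMSD).
    n_workers : int
        Worker processes for the pair matrix (results are identical for
        any count).
    cache_path : path or None
        Where to cache / reuse the condensed RMSD matrix.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        n_solute: int,
        w_solute: float | None = None,
        reorder: str = "hungarian",
        linkage: str = "ward",
        no_hydrogen: bool = False,
        exclude: str | tuple = (),
        final_kabsch: bool = True,
        reorder_solute: bool = True,
        n_workers: int = 1,
        cache_path: str | Path | None = None,
        force_recompute: bool = False,
    ):
        if trajectory.n_frames < 2:
            raise ValueError("clustering needs at least two frames")
        if isinstance(exclude, str):
            excluded = parse_ranges(exclude)
        else:
            excluded = frozenset(int(i) for i in exclude)
        spec = SoluteSpec(
            n_solute=n_solute,
            w_solute=w_solute,
            excluded=excluded,
            no_hydrogen=no_hydrogen,
        )
        sel = apply_selection(trajectory, spec, n_solute_original=n_solute)
        self.original_trajectory = trajectory
        self.trajectory = sel.trajectory
        self.index_map = sel.index_map
        self.spec = sel.spec
        self.options = PairOptions(
            spec=self.spec,
            reorder_alg=reorder,
            final_kabsch=final_kabsch,
            reorder_solute=reorder_solute,
        )
        self.linkage_method = linkage
        if linkage not in _cluster.LINKAGE_METHODS:
            raise ValueError(
                f"unknown linkage method {linkage!r}; "
                f"choose from {_cluster.LINKAGE_METHODS}"
            )
        self.n_workers = int(n_workers)
        self.cache_path = cache_path
        self.force_recompute = force_recompute
        self._matrix: CondensedRMSDMatrix | None = None

    @classmethod
    def from_file(cls, path, n_solute, format_hint=None, **kwargs):
        return cls(read_trajectory(path, format_hint), n_solute, **kwargs)

    @property
    def distances(self) -> CondensedRMSDMatrix:
        """The condensed pairwise minimum-RMSD matrix (computed lazily)."""
        if self._matrix is None:
            self._matrix = rmsd_matrix(
                self.trajectory,
                self.options,
                n_workers=self.n_workers,
                cache_path=self.cache_path,
                force=self.force_recompute,
            )
        return self._matrix

    def fit(self, threshold: float | str = "auto") -> "ClusteringResults":
        """Cluster the trajectory; ``threshold`` in Å or "auto".

        "auto" maximizes the silhouette score over all candidate cuts of
        the dendrogram.
        """
        m = self.distances
        tree = _cluster.linkage(m, self.linkage_method)
        if threshold == "auto":
            thr, res = _cluster.auto_threshold(m, tree)
        else:
            thr = float(threshold)
            if thr <= 0:
                raise ValueError("threshold must be positive or 'auto'")
            res = _cluster.cut(tree, thr)
            try:
                res.scores = _cluster.scores(m, res.labels, tree)
            except ValueError as exc:  # e.g. single cluster
                logger.warning("quality scores unavailable: %s", exc)
        logger.info(
            "threshold %.4f Å -> %d clusters; scores: %s",
            thr, res.n_clusters, res.scores,
        )
        return ClusteringResults(self, m, tree, res, thr)


class ClusteringResults:
    """Fitted clustering: labels, scores, medoids and output writers."""

    def __init__(self, model, m, tree, result, threshold):
        self.model = model
        self.distances = m
        self.linkage_matrix = tree
        self.result = result
        self.threshold = float(threshold)
        self.labels = result.labels
        self.n_clusters = result.n_clusters
        self.scores = result.scores or {}
        self.matrix_sum = matrix_sum(m)
        self.summaries = _report.cluster_summaries(m, result)

    @property
    def medoids(self) -> list[int]:
        """Medoid frame index (0-based, reduced trajectory) per cluster."""
        return [s.medoid_frame for s in self.summaries]

    def populations(self) -> list[int]:
        return [s.population for s in self.summaries]

    def summary(self) -> str:
        """Human-readable run summary table."""
        head = pd.DataFrame(
            {
                "value": {
                    "frames": self.distances.M,
                    "atoms (after selection)": self.model.trajectory.n_atoms,
                    "solute atoms": self.model.spec.n_solute,
                    "reorder": self.model.options.reorder_alg,
                    "linkage": self.model.linkage_method,
                    "threshold (Å)": round(self.threshold, 4),
                    "n_clusters": self.n_clusters,
                    "RMSD matrix sum (Å)": round(self.matrix_sum, 3),
                }
            }
        )
        lines = ["Trajectory clustering results", str(head)]
        if self.scores:
            sc = {k: round(v, 4) for k, v in self.scores.items()}
            lines.append(f"scores: {sc}")
        body = pd.DataFrame(
            [
                {
                    "cluster": s.cluster_id,
                    "population": s.population,
                    "medoid_frame": s.medoid_frame + 1,
                    "mean_intra_rmsd": round(s.mean_intra_rmsd, 4),
                }
                for s in self.summaries
            ]
        )
        lines.append(body.to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir: str | Path, fmt: str | None = None) -> None:
        """Write the full artifact set under ``outdir``.

        assignments.dat, matrix.cache, summary.json, dendrogram data +
        image, 2-D projection data + image, and clusters/cluster_<k>.<ext>.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _report.write_assignments(self.result, outdir / "assignments.dat")
        from .pairdist import save_matrix

        fp = self.model.options.fingerprint(
            self.distances.M, self.model.trajectory.n_atoms
        )
        save_matrix(self.distances, outdir / "matrix.cache", fp)
        np.savetxt(
            outdir / "linkage.dat",
            self.linkage_matrix,
            header="left right height size",
        )
        _report.plot_dendrogram(
            self.linkage_matrix, outdir / "dendrogram.png", self.threshold
        )
        X = _report.plot_projection(
            self.distances, self.result, outdir / "projection.png"
        )
        np.savetxt(outdir / "projection.dat", X, header="mds1 mds2")
        fmt = fmt or (self.model.trajectory.fmt
                      if self.model.trajectory.fmt in ("xyz", "pdb") else "xyz")
        _report.write_cluster_trajectories(
            self.model.trajectory,
            self.result,
            self.distances,
            self.model.options,
            outdir / "clusters",
            fmt=fmt,
        )
        _report.write_summary_json(
            outdir / "summary.json",
            threshold=self.threshold,
            n_clusters=self.n_clusters,
            scores=self.scores,
            matrix_sum=self.matrix_sum,
            populations=self.populations(),
            clusters=self.summaries,
        )
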