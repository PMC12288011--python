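"""Minimum pairwise RMSD with the solute–solvent split, and the RMSD matrix.

The staged procedure for one pair of frames (reference ``A``, candidate
``B``) is the heart of the package:

1. center both frames on the solute centroid;
2. Kabsch rotation fitted on the solute atoms only;
3. relabel the solute atoms (skipped when no element repeats, or on request);
4. Kabsch on the solute again, now with sensible label pairing;
5. relabel the solvent atoms, which by now sit in comparable positions;
6. optionally, a final Kabsch rotation fitted on all atoms.

The returned value is the weighted RMSD with the solute/solvent split
weights.  The translation is fixed at step 1 (solute centroid); steps 2–6
are rotations and relabelings only.

Relabeling acts per atom, per element: a solvent molecule's atoms may in
principle be matched to atoms of different solvent molecules.  In practice,
once the solutes are superposed, atoms of nearby solvent molecules are the
cheap assignments and whole-molecule matchings emerge from the assignment
problem on their own.

The condensed matrix holds the M(M-1)/2 pair minima with frame i as the
reference for pair (i, j), i < j.  Work is partitioned over pair indices
in fixed blocks, so the result is bit-for-bit identical for any worker
count.  Matrices can be cached on disk together with a fingerprint of the
options that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    kabsch,
    solute_weights,
    uniform_weights,
    weighted_rmsd,
)
from .reorder import (
    align_inertia,
    iter_species_permutations,
    reorder_distance,
    reorder_hungarian,
    species_permutation_count,
    BRUTE_FORCE_CAP,
)
from .traj_io import Snapshot, SoluteSpec, Trajectory

__all__ = [
    "PairOptions",
    "CondensedRMSDMatrix",
    "pair_min_rmsd",
    "direct_min_rmsd",
    "rmsd_matrix",
    "matrix_sum",
    "save_matrix",
    "load_matrix",
]

logger = logging.getLogger(__name__)

REORDER_ALGORITHMS = ("hungarian", "hungarian_inertia", "distance", "brute", "none")


@dataclass(frozen=True)
class PairOptions:
    """Options controlling the pairwise minimum-RMSD procedure."""

    spec: SoluteSpec
    reorder_alg: str = "hungarian"
    final_kabsch: bool = True
    reorder_solute: bool = True

    def __post_init__(self):
        if self.reorder_alg not in REORDER_ALGORITHMS:
            raise ValueError(
                f"unknown reorder algorithm {self.reorder_alg!r}; "
                f"choose from {REORDER_ALGORITHMS}"
            )

    def fingerprint(self, n_frames: int, n_atoms: int) -> str:
        """Stable hash of everything that determines the matrix entries."""
        payload = json.dumps(
            {
                "reorder_alg": self.reorder_alg,
                "final_kabsch": self.final_kabsch,
                "reorder_solute": self.reorder_solute,
                "n_solute": self.spec.n_solute,
                "w_solute": self.spec.w_solute,
                "excluded": sorted(self.spec.excluded),
                "no_hydrogen": self.spec.no_hydrogen,
                "M": n_frames,
                "N": n_atoms,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class CondensedRMSDMatrix:
    """The M(M-1)/2 pairwise minimized RMSDs (Å), upper triangle row-major."""

    d: np.ndarray
    M: int

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.M * (self.M - 1) // 2,):
            raise ValueError("condensed vector length must be M(M-1)/2")
        if np.any(self.d < 0):
            raise ValueError("RMSD entries must be non-negative")

    def index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no diagonal in a condensed matrix")
        if i > j:
            i, j = j, i
        return self.M * i - i * (i + 1) // 2 + (j - i - 1)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.d[self.index(*ij)])

    def squareform(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d)


def matrix_sum(m: CondensedRMSDMatrix) -> float:
    """Sum of all condensed entries (Å) — a reordering-quality diagnostic."""
    return float(m.d.sum())


# ------------------------------------------------------------- pair RMSD


def _block_reorder(
    A: np.ndarray,
    B: np.ndarray,
    lo: int,
    hi: int,
    elements: Sequence[str],
    alg: str,
    w: np.ndarray,
    final_kabsch: bool,
) -> np.ndarray:
    """Reorder atoms lo..hi of B in place; returns the updated B.

    For the brute algorithm the candidate permutations are scored on the
    full system (weighted RMSD after the optional all-atom Kabsch), i.e.
    exactly the objective the caller will report.
    """
    if hi - lo < 2:
        return B
    block_elems = elements[lo:hi]
    if len(set(block_elems)) == len(block_elems):
        return B  # no element repeats: nothing to permute
    if alg in ("hungarian", "hungarian_inertia"):
        perm = reorder_hungarian(A[lo:hi], B[lo:hi], block_elems)
    elif alg == "distance":
        perm = reorder_distance(A[lo:hi], B[lo:hi], block_elems)
    elif alg == "brute":
        n_perm = species_permutation_count(block_elems)
        if n_perm > BRUTE_FORCE_CAP:
            raise ValueError(
                f"brute force would enumerate {n_perm} permutations "
                f"(cap {BRUTE_FORCE_CAP}); use the Hungarian algorithm instead"
            )
        best, best_perm = np.inf, None
        for cand in iter_species_permutations(block_elems):
            Bc = B.copy()
            Bc[lo:hi] = B[lo:hi][cand]
            if final_kabsch:
                R = kabsch(A, Bc, w, center=False)
                Bc = Bc @ R.T
            r = weighted_rmsd(A, Bc, w)
            if r < best - 1e-15:
                best, best_perm = r, cand
        perm = best_perm
    else:  # "none"
        return B
    B = B.copy()
    B[lo:hi] = B[lo:hi][perm]
    return B


def pair_min_rmsd(
    A: Snapshot | np.ndarray,
    B: Snapshot | np.ndarray,
    opts: PairOptions,
    elements: Sequence[str] | None = None,
    return_aligned: bool = False,
):
    """Minimum RMSD between two frames via the solute–solvent split.

    Parameters
    ----------
    A, B : Snapshot or (N, 3) arrays
        Reference and candidate frames of identical composition.  When
        arrays are passed, ``elements`` must be given.
    opts : PairOptions
        Reorder algorithm, weights and staging options; ``opts.spec``
        defines the solute/solvent partition.
    return_aligned : bool
        Also return the relabeled, superposed copy of ``B`` expressed in
        ``A``'s original coordinate frame.

    Returns
    -------
    float or (float, numpy.ndarray)
        The weighted RMSD (Å), optionally with the aligned coordinates.
    """
    if isinstance(A, Snapshot):
        elements = A.elements
        Ax, Bx = A.coords, B.coords
        if isinstance(B, Snapshot) and B.elements != elements:
            raise ValueError("frames differ in composition")
    else:
        Ax, Bx = np.asarray(A, float), np.asarray(B, float)
        if elements is None:
            raise ValueError("elements required with raw coordinate arrays")
    if Ax.shape != Bx.shape:
        raise ValueError("frames differ in shape")

    n = Ax.shape[0]
    ns = opts.spec.n_solute
    if not 0 <= ns <= n:
        raise ValueError("n_solute inconsistent with frame size")
    w = solute_weights(n, ns, opts.spec.effective_w_solute(n))

    # step 1: fix the translation at the solute centroid
    if ns:
        cA, cB = Ax[:ns].mean(axis=0), Bx[:ns].mean(axis=0)
    else:
        cA, cB = Ax.mean(axis=0), Bx.mean(axis=0)
    A0 = Ax - cA
    B0 = Bx - cB

    if opts.reorder_alg == "hungarian_inertia" and n >= 3:
        candidates = [np.eye(3)] + align_inertia(A0, B0)
    else:
        candidates = [np.eye(3)]

    best = np.inf
    best_B: np.ndarray | None = None
    for R0 in candidates:
        Bc = B0 @ R0.T
        # steps 2-4: align and relabel the solute (solute centroids sit at
        # the origin, so these rotation fits need no re-centering)
        if ns >= 2:
            R = kabsch(A0[:ns], Bc[:ns], center=False)
            Bc = Bc @ R.T
            if opts.reorder_solute:
                Bc = _block_reorder(
                    A0, Bc, 0, ns, elements, opts.reorder_alg, w,
                    opts.final_kabsch,
                )
                R = kabsch(A0[:ns], Bc[:ns], center=False)
                Bc = Bc @ R.T
        # step 5: relabel the solvent
        Bc = _block_reorder(
            A0, Bc, ns, n, elements, opts.reorder_alg, w, opts.final_kabsch
        )
        # step 6: optional all-atom rotation about the solute-centroid origin
        # (the translation was fixed at step 1, so the rotation is fitted
        # without re-centering)
        if opts.final_kabsch:
            R = kabsch(A0, Bc, w, center=False)
            Bc = Bc @ R.T
        r = weighted_rmsd(A0, Bc, w)
        if r < best - 1e-15:
            best, best_B = r, Bc
    if return_aligned:
        return best, best_B + cA
    return best


def direct_min_rmsd(
    A: Snapshot | np.ndarray,
    B: Snapshot | np.ndarray,
    reorder_alg: str = "hungarian",
    elements: Sequence[str] | None = None,
    w: np.ndarray | None = None,
) -> float:
    """Minimum RMSD without the solute–solvent split.

    The whole system is centered, relabeled in one joint assignment and
    rotated once — the conventional single-stage approach the split
    strategy is measured against.
    """
    if isinstance(A, Snapshot):
        elements = A.elements
        Ax, Bx = A.coords, B.coords
    else:
        Ax, Bx = np.asarray(A, float), np.asarray(B, float)
        if elements is None:
            raise ValueError("elements required with raw coordinate arrays")
    n = Ax.shape[0]
    wv = uniform_weights(n) if w is None else np.asarray(w, float)
    A0 = Ax - wv @ Ax
    B0 = Bx - wv @ Bx
    if reorder_alg == "hungarian_inertia" and n >= 3:
        candidates = [np.eye(3)] + align_inertia(A0, B0)
    else:
        candidates = [np.eye(3)]
    best = np.inf
    for R0 in candidates:
        Bc = B0 @ R0.T
        Bc = _block_reorder(A0, Bc, 0, n, elements, reorder_alg, wv, True)
        R = kabsch(A0, Bc, wv)
        r = weighted_rmsd(A0, Bc @ R.T, wv)
        best = min(best, r)
    return best


# ----------------------------------------------------------- RMSD matrix


def _pair_indices(M: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(M) for j in range(i + 1, M)]


def _worker_block(args):
    coords, elements, opts, pairs = args
    return [
        pair_min_rmsd(coords[i], coords[j], opts, elements=elements)
        for i, j in pairs
    ]


def rmsd_matrix(
    traj: Trajectory,
    opts: PairOptions,
    n_workers: int = 1,
    cache_path: str | Path | None = None,
    force: bool = False,
) -> CondensedRMSDMatrix:
    """All M(M-1)/2 pairwise minimized RMSDs of a trajectory.

    Deterministic for any ``n_workers``: pairs are assigned to fixed
    blocks and written back by index.  If ``cache_path`` exists and its
    header matches the current frame count and options fingerprint, the
    cached matrix is returned; a stale cache raises unless ``force``.
    """
    M = traj.n_frames
    if M < 2:
        raise ValueError("need at least two frames")
    fp = opts.fingerprint(M, traj.n_atoms)
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            try:
                cached = load_matrix(cache_path, expect_fingerprint=fp)
            except ValueError:
                if not force:
                    raise
                logger.info("stale RMSD matrix cache ignored (--force)")
            else:
                logger.info("reusing cached RMSD matrix from %s", cache_path)
                return cached

    coords = traj.coords_array()
    elements = traj.elements
    pairs = _pair_indices(M)
    if n_workers <= 1 or len(pairs) < 4:
        d = np.array(
            [pair_min_rmsd(coords[i], coords[j], opts, elements=elements)
             for i, j in pairs]
        )
    else:
        blocks = np.array_split(np.arange(len(pairs)), n_workers * 4)
        blocks = [b for b in blocks if len(b)]
        args = [
            (coords, elements, opts, [pairs[k] for k in b]) for b in blocks
        ]
        d = np.empty(len(pairs))
        with ProcessPoolExecutor(max_workers=n_workers) as ex:
            for b, res in zip(blocks, ex.map(_worker_block, args)):
                d[b] = res
    m = CondensedRMSDMatrix(d, M)
    if cache_path is not None:
        save_matrix(m, cache_path, fp)
        logger.info("RMSD matrix cached to %s", cache_path)
    return m


# ------------------------------------------------------------- disk cache
# Layout: NumPy .npz archive with arrays
#   d           float64 condensed vector, length M(M-1)/2
#   M           int64 scalar frame count
#   fingerprint string scalar, sha256 of the producing options


def save_matrix(m: CondensedRMSDMatrix, path: str | Path, fingerprint: str) -> None:
    with open(path, "wb") as fh:  # file object: exact path, no .npz appended
        np.savez(fh, d=m.d, M=np.int64(m.M), fingerprint=np.str_(fingerprint))


def load_matrix(
    path: str | Path, expect_fingerprint: str | None = None
) -> CondensedRMSDMatrix:
    path = Path(path)
    with np.load(path) as z:
        d = z["d"]
        M = int(z["M"])
        fp = str(z["fingerprint"])
    if expect_fingerprint is not None and fp != expect_fingerprint:
        raise ValueError(
            f"cached RMSD matrix at {path} was produced with different "
            "options or input (fingerprint mismatch); pass force=True to "
            "recompute"
        )
    return CondensedRMSDMatrix(d, M)
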