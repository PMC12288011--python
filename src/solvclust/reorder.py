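"""Species-preserving atom relabeling to minimize RMSD.

When a configuration contains identical molecules (e.g. many waters), the
plain RMSD between two frames depends on the arbitrary storage order of
those molecules: swapping two waters leaves the physical configuration
unchanged but can inflate the RMSD by several Å.  The operations here find
a permutation of one configuration's atom labels — restricted to atoms of
the same element — that pairs spatially close atoms, so the subsequent
Kabsch superposition sees a sensible correspondence.

Three relabeling strategies are provided, ordered by cost and exactness:

``reorder_brute``
    enumerates every species-respecting permutation and keeps the one with
    the lowest post-Kabsch RMSD; the global optimum by construction, with
    factorial cost (a configurable cap refuses hopeless inputs).
``reorder_hungarian``
    solves, per element, the linear assignment problem with squared
    Euclidean cost; the exact optimum of the assignment objective in
    O(K^3), though not necessarily of the post-rotation RMSD.
``reorder_distance``
    sorts atoms of each element by distance to the block centroid and
    matches by rank; O(K log K), approximate.

``align_inertia`` supplies the four proper rotations aligning one
configuration's principal inertia axes (unit masses) onto the other's, a
cheap pre-alignment that can help the Hungarian step when the frames are
arbitrarily oriented.

A permutation ``perm`` is applied as ``B[perm]``: position ``i`` of the
reordered configuration holds the atom that should pair with atom ``i``
of the reference.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .geometry import kabsch_rmsd, uniform_weights

__all__ = [
    "reorder_hungarian",
    "reorder_distance",
    "reorder_brute",
    "align_inertia",
    "species_permutation_count",
    "iter_species_permutations",
]

logger = logging.getLogger(__name__)

BRUTE_FORCE_CAP = 10**6


def _species_groups(elements: Sequence[str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        groups.setdefault(el, []).append(i)
    return {el: np.array(idx) for el, idx in groups.items()}


def _check_same_species(elements_a, elements_b) -> None:
    if sorted(elements_a) != sorted(elements_b):
        raise ValueError("element multisets of the two blocks differ")


def check_permutation(perm: np.ndarray, elements: Sequence[str]) -> None:
    """Validate that ``perm`` is a species-preserving bijection."""
    perm = np.asarray(perm)
    n = len(elements)
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("not a bijection")
    for i, j in enumerate(perm):
        if elements[i] != elements[j]:
            raise ValueError("permutation maps across element species")


def reorder_hungarian(
    A_block: np.ndarray, B_block: np.ndarray, elements: Sequence[str]
) -> np.ndarray:
    """Exact minimum-cost assignment per element species.

    Cost between reference atom ``i`` and candidate atom ``j`` of the same
    element is the squared Euclidean distance of their current Cartesian
    positions (the quantity whose weighted sum the RMSD is built from).
    """
    A_block = np.asarray(A_block, dtype=float)
    B_block = np.asarray(B_block, dtype=float)
    if A_block.shape != B_block.shape:
        raise ValueError("blocks must have the same shape")
    if len(elements) != A_block.shape[0]:
        raise ValueError("elements length mismatch")
    _check_same_species(elements, elements)
    perm = np.empty(len(elements), dtype=int)
    for el, idx in _species_groups(elements).items():
        cost = cdist(A_block[idx], B_block[idx], "sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        perm[idx[rows]] = idx[cols]
    return perm


def reorder_distance(
    A_block: np.ndarray, B_block: np.ndarray, elements: Sequence[str]
) -> np.ndarray:
    """Rank-matching by distance to the block centroid, per species.

    Ties in centroid distance are broken by original index order (stable
    sort), making the result deterministic.
    """
    A_block = np.asarray(A_block, dtype=float)
    B_block = np.asarray(B_block, dtype=float)
    if A_block.shape != B_block.shape:
        raise ValueError("blocks must have the same shape")
    ca = A_block.mean(axis=0)
    cb = B_block.mean(axis=0)
    da = np.linalg.norm(A_block - ca, axis=1)
    db = np.linalg.norm(B_block - cb, axis=1)
    perm = np.empty(len(elements), dtype=int)
    for el, idx in _species_groups(elements).items():
        order_a = idx[np.argsort(da[idx], kind="stable")]
        order_b = idx[np.argsort(db[idx], kind="stable")]
        perm[order_a] = order_b
    return perm


def species_permutation_count(elements: Sequence[str]) -> int:
    """Number of species-respecting permutations (product of factorials)."""
    count = 1
    for el, idx in _species_groups(elements).items():
        count *= math.factorial(len(idx))
    return count


def iter_species_permutations(elements: Sequence[str]):
    """Yield every species-respecting permutation in deterministic order."""
    groups = _species_groups(elements)
    keys = sorted(groups)
    n = len(elements)
    for combo in itertools.product(
        *(itertools.permutations(groups[k]) for k in keys)
    ):
        perm = np.empty(n, dtype=int)
        for k, assigned in zip(keys, combo):
            perm[groups[k]] = assigned
        yield perm


def reorder_brute(
    A_block: np.ndarray,
    B_block: np.ndarray,
    elements: Sequence[str],
    w: np.ndarray | None = None,
    cap: int = BRUTE_FORCE_CAP,
) -> np.ndarray:
    """Exhaustive search for the permutation minimizing post-Kabsch RMSD.

    Every species-respecting permutation of ``B_block`` is scored by the
    weighted RMSD after an optimal rotation onto ``A_block``; the first
    minimizer in the deterministic enumeration order is returned.  Raises
    if the permutation count exceeds ``cap`` (default 10^6), advising the
    Hungarian algorithm instead.
    """
    A_block = np.asarray(A_block, dtype=float)
    B_block = np.asarray(B_block, dtype=float)
    if A_block.shape != B_block.shape:
        raise ValueError("blocks must have the same shape")
    n_perm = species_permutation_count(elements)
    if n_perm > cap:
        raise ValueError(
            f"brute force would enumerate {n_perm} permutations "
            f"(cap {cap}); use the Hungarian algorithm instead"
        )
    n = len(elements)
    wv = uniform_weights(n) if w is None else np.asarray(w, dtype=float)
    wv = wv / wv.sum()
    best_perm: np.ndarray | None = None
    best = np.inf
    for perm in iter_species_permutations(elements):
        r = kabsch_rmsd(A_block, B_block[perm], wv)
        if r < best - 1e-15:
            best = r
            best_perm = perm
    assert best_perm is not None
    return best_perm


_AXIS_SIGNS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)

#: relative eigenvalue gap below which the inertia tensor is flagged degenerate
_INERTIA_DEGENERACY_RTOL = 1e-6


def _principal_axes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of the unit-mass inertia tensor about the centroid."""
    Xc = X - X.mean(axis=0)
    r2 = np.einsum("ij,ij->i", Xc, Xc).sum()
    I = r2 * np.eye(3) - Xc.T @ Xc
    vals, vecs = np.linalg.eigh(I)
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1  # keep a right-handed frame
    return vals, vecs


def align_inertia(A: np.ndarray, B: np.ndarray) -> list[np.ndarray]:
    """Proper rotations aligning B's principal inertia axes onto A's.

    Unit atom masses are used (the clustering operates on geometry, not
    dynamics).  The axis directions are defined only up to sign, so the
    four proper sign combinations are all returned; the caller evaluates
    its downstream objective for each and keeps the best.  A degenerate
    (symmetric-top) spectrum is logged as a warning — the candidates are
    still valid rotations, just not a complete symmetry set.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] < 3:
        raise ValueError("need at least 3 atoms for inertia alignment")
    vals_a, ax_a = _principal_axes(A)
    vals_b, ax_b = _principal_axes(B)
    for vals in (vals_a, vals_b):
        scale = max(abs(vals).max(), 1e-300)
        if np.min(np.diff(np.sort(vals))) / scale < _INERTIA_DEGENERACY_RTOL:
            logger.warning(
                "degenerate inertia tensor: principal axes are not unique; "
                "evaluating all candidates"
            )
            break
    return [ax_a @ S @ ax_b.T for S in _AXIS_SIGNS]
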