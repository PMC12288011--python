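"""Weighted RMSD, atom weights, centering and Kabsch superposition.

The dissimilarity used throughout the package is the weighted root mean
square deviation between two configurations ``A`` and ``B`` with ``N``
paired atoms,

.. math::

    \\mathrm{RMSD}(A, B) = \\sqrt{\\sum_{i=1}^{N} w_i \\lVert a_i - b_i \\rVert^2},

where the non-negative weights satisfy ``sum(w) == 1``.  Uniform weights
``w_i = 1/N`` reproduce the conventional RMSD; the solute/solvent weighting
scheme (:func:`solute_weights`) splits a total solute weight ``W`` uniformly
over the first ``n_solute`` atoms and the remainder uniformly over the
solvent atoms, letting the solute dominate the superposition when desired.

All computations are carried out in double precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "solute_weights",
    "uniform_weights",
    "weighted_rmsd",
    "weighted_centroid",
    "center_on",
    "kabsch",
    "kabsch_rmsd",
]

#: absolute tolerance for geometric equality used in tests and invariants
GEOM_ATOL = 1e-8


def uniform_weights(n: int) -> np.ndarray:
    """Return the uniform weight vector ``w_i = 1/n``."""
    if n <= 0:
        raise ValueError("need at least one atom")
    return np.full(n, 1.0 / n)


def solute_weights(n_total: int, n_solute: int, w_solute: float) -> np.ndarray:
    """Build the solute/solvent split weight vector.

    The first ``n_solute`` positions (the solute, by convention the leading
    atoms of every frame) share the total solute weight ``w_solute``
    uniformly; the remaining solvent atoms share ``1 - w_solute`` uniformly.
    Choosing ``w_solute = n_solute / n_total`` recovers uniform weights.

    Parameters
    ----------
    n_total : int
        Number of atoms in the (possibly reduced) configuration.
    n_solute : int
        Number of solute atoms, occupying positions ``0..n_solute-1``.
    w_solute : float
        Total solute weight in ``[0, 1]``.

    Returns
    -------
    numpy.ndarray
        Length ``n_total`` weight vector summing to 1.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_solute <= n_total:
        raise ValueError("n_solute must be in [0, n_total]")
    if not 0.0 <= w_solute <= 1.0:
        raise ValueError("w_solute must be in [0, 1]")
    if n_solute == 0 and w_solute > 0:
        raise ValueError("w_solute > 0 requires at least one solute atom")
    if n_solute == n_total and w_solute != 1.0:
        raise ValueError("all atoms are solute: w_solute must be 1")

    w = np.empty(n_total, dtype=float)
    if n_solute:
        w[:n_solute] = w_solute / n_solute
    if n_solute < n_total:
        w[n_solute:] = (1.0 - w_solute) / (n_total - n_solute)
    return w


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight vector must have length {n}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return w


def weighted_rmsd(A: np.ndarray, B: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted RMSD between two paired coordinate sets (Å).

    Zero if and only if ``A == B``; symmetric in its arguments and invariant
    under a common rigid rotation of both sets.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must both be N x 3 with the same N")
    n = A.shape[0]
    w = uniform_weights(n) if w is None else _check_weights(w, n)
    sq = np.einsum("ij,ij->i", A - B, A - B)
    return float(np.sqrt(np.dot(w, sq)))


def weighted_centroid(A: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Weighted centroid of a coordinate set."""
    A = np.asarray(A, dtype=float)
    if w is None:
        return A.mean(axis=0)
    w = _check_weights(w, A.shape[0])
    return w @ A


def center_on(
    A: np.ndarray, on: np.ndarray | slice | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Translate ``A`` so a (sub)centroid sits at the origin.

    Parameters
    ----------
    A : numpy.ndarray
        ``N x 3`` coordinates.
    on : weight vector, index array/slice, or None
        If a length-``N`` float vector, the weighted centroid is removed.
        If an integer index array or slice, the uniform centroid of that
        atom subset is removed.  ``None`` removes the uniform full centroid.

    Returns
    -------
    (centered, translation)
        ``centered = A + translation``; applying :func:`center_on` twice
        yields a zero second translation.
    """
    A = np.asarray(A, dtype=float)
    if on is None:
        c = A.mean(axis=0)
    elif isinstance(on, slice):
        sub = A[on]
        if sub.shape[0] == 0:
            raise ValueError("empty atom subset")
        c = sub.mean(axis=0)
    else:
        arr = np.asarray(on)
        if arr.dtype.kind in "iub":
            sub = A[arr]
            if sub.shape[0] == 0:
                raise ValueError("empty atom subset")
            c = sub.mean(axis=0)
        else:
            c = weighted_centroid(A, arr)
    return A - c, -c


def kabsch(
    A: np.ndarray,
    B: np.ndarray,
    w: np.ndarray | None = None,
    center: bool = True,
) -> np.ndarray:
    """Optimal proper rotation superposing ``B`` onto ``A``.

    With ``center=True`` (default) both sets are centered on their
    weighted centroids internally and the returned ``R`` minimizes
    ``weighted_rmsd(A_c, B_c @ R.T, w)`` over all proper rotations (SVD of
    the weighted covariance with the determinant sign correction, so
    reflections are never returned).  With ``center=False`` the rotation
    is fitted about the *current origin* — the optimal rotation when the
    translation has already been fixed by the caller (e.g. at the solute
    centroid).  For degenerate inputs (coincident or collinear atoms) the
    result is still a valid proper rotation; ties are resolved by the
    SVD's deterministic convention.

    Returns
    -------
    numpy.ndarray
        ``3 x 3`` rotation matrix with ``det(R) = +1``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must both be N x 3 with the same N")
    n = A.shape[0]
    w = uniform_weights(n) if w is None else _check_weights(w, n)
    if center:
        Ac = A - w @ A
        Bc = B - w @ B
    else:
        Ac, Bc = A, B
    C = (w[:, None] * Ac).T @ Bc  # 3x3 weighted covariance
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    if d == 0:  # rank-deficient covariance: pick the proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def kabsch_rmsd(A: np.ndarray, B: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted RMSD of ``B`` onto ``A`` after optimal translation+rotation."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    wv = uniform_weights(n) if w is None else _check_weights(w, n)
    Ac = A - wv @ A
    Bc = B - wv @ B
    R = kabsch(Ac, Bc, wv)
    return weighted_rmsd(Ac, Bc @ R.T, wv)
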