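"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, explicit
loops) and independent of the library code paths they check.
"""

import numpy as np
import pytest

from solvclust.geometry import kabsch, solute_weights, weighted_rmsd
from solvclust.reorder import iter_species_permutations
from solvclust.synthetic import FixtureSpec, make_solvated_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


def random_rotation(rng):
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def one_solute_two_waters(seed, noise=0.3):
    """A 1-atom solute plus two waters; B is a perturbed copy of A."""
    spec = FixtureSpec(n_solvent=2, rng_seed=seed, noise_sigma=0.0)
    gen = np.random.default_rng(seed)
    el, xyz, ns_full = make_solvated_frame(spec, gen)
    keep = [0] + list(range(ns_full, len(el)))
    elements = tuple(el[i] for i in keep)
    A = xyz[keep]
    B = A + gen.normal(scale=noise, size=A.shape)
    return elements, A, B


def global_min_rmsd_oracle(A, B, elements, n_solute, w=None):
    """Exhaustive minimum over species permutations x rotations.

    The translation is fixed at the solute centroid, matching the staged
    procedure's convention; for each permutation the optimal rotation
    about that origin is computed in closed form.
    """
    n = len(elements)
    if w is None:
        w = solute_weights(n, n_solute, n_solute / n)
    if n_solute:
        A0 = A - A[:n_solute].mean(axis=0)
        B0 = B - B[:n_solute].mean(axis=0)
    else:
        A0 = A - A.mean(axis=0)
        B0 = B - B.mean(axis=0)
    best = np.inf
    for perm in iter_species_permutations(elements):
        Bp = B0[perm]
        R = kabsch(A0, Bp, w, center=False)
        best = min(best, weighted_rmsd(A0, Bp @ R.T, w))
    return best


def naive_single_linkage(square):
    """O(M^3) agglomerative single linkage returning sorted merge heights."""
    d = square.astype(float).copy()
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = min(
                    d[i, j] for i in clusters[a] for j in clusters[b]
                )
                if dist < best[0]:
                    best = (dist, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def pearson_loop(x, y):
    """Pearson correlation by the textbook explicit-sum formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den
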