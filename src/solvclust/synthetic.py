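"""Synthetic solute–solvent trajectories with known ground truth.

Every test of the package runs on configurations built here: a rigid
solute surrounded by rigid solvent molecules (3-site waters by default),
optionally subjected to the three nuisances the pairwise procedure must
undo — molecule-wise relabeling of identical solvent molecules, rigid
rotation+translation of the whole frame, and small Gaussian coordinate
noise.

Two generators cover the study conditions:

* :func:`make_congruent_pair` — frame B is an exact copy of frame A up to
  a rigid motion and a solvent-molecule permutation, so the true minimum
  RMSD is exactly zero while the naive (label-order) RMSD is large.
* :func:`make_clustered_trajectory` — frames are noisy copies of a few
  well-separated conformer geometries, each frame independently permuted
  and rigidly moved; the generating conformer of every frame is returned
  as the ground-truth label.

All randomness flows through one explicitly passed NumPy generator; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_io import Snapshot, Trajectory

__all__ = [
    "FixtureSpec",
    "water_template",
    "default_solute_template",
    "make_solvated_frame",
    "make_congruent_pair",
    "make_clustered_trajectory",
]


def water_template() -> tuple[tuple[str, ...], np.ndarray]:
    """Rigid 3-site water (O, H, H), experimental-ish geometry in Å."""
    elements = ("O", "H", "H")
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.9572, 0.0, 0.0],
            [-0.2400, 0.9266, 0.0],
        ]
    )
    return elements, coords


def default_solute_template() -> tuple[tuple[str, ...], np.ndarray]:
    """A small rigid 5-atom solute with all-distinct elements.

    Chosen chiral (no internal mirror symmetry) so superposition tests
    exercise the proper-rotation constraint.
    """
    elements = ("C", "N", "O", "F", "S")
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.45, 0.0, 0.0],
            [-0.5, 1.30, 0.0],
            [-0.4, -0.6, 1.15],
            [0.9, -0.9, -1.0],
        ]
    )
    return elements, coords


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic solute–solvent fixture.

    Defaults model a small solvation shell: five rigid waters around a
    5-atom solute, 20 frames, coordinate noise of 0.05 Å — far below the
    ≳3 Å separation between independently drawn conformer geometries, so
    synthetic conformers are unambiguous.
    """

    n_solvent: int = 5
    n_frames: int = 20
    n_conformers: int = 2
    noise_sigma: float = 0.05
    permute: bool = True
    rotate: bool = True
    rng_seed: int = 0
    solvent_template: tuple = field(default_factory=water_template)
    solute_template: tuple = field(default_factory=default_solute_template)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def make_solvated_frame(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[tuple[str, ...], np.ndarray, int]:
    """One random solute+solvent layout.

    Solvent molecules are dropped at random positions on shells 3–7 Å
    from the solute centroid with random orientations, rejecting overlaps
    closer than 1.5 Å between molecular centers.

    Returns (elements, coords, n_solute).
    """
    sol_el, sol_xyz = spec.solute_template
    wat_el, wat_xyz = spec.solvent_template
    coords = [sol_xyz - sol_xyz.mean(axis=0)]
    elements = list(sol_el)
    centers: list[np.ndarray] = []
    while len(centers) < spec.n_solvent:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = direction * rng.uniform(3.0, 7.0)
        if any(np.linalg.norm(center - c) < 1.5 for c in centers):
            continue
        centers.append(center)
        R = _random_rotation(rng)
        mol = (wat_xyz - wat_xyz.mean(axis=0)) @ R.T + center
        coords.append(mol)
        elements.extend(wat_el)
    return tuple(elements), np.vstack(coords), len(sol_el)


def _permute_solvent_molecules(
    coords: np.ndarray, n_solute: int, mol_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Permute whole solvent molecules (physically meaningful relabeling)."""
    n_mol = (coords.shape[0] - n_solute) // mol_size
    order = rng.permutation(n_mol)
    out = coords.copy()
    solvent = coords[n_solute:].reshape(n_mol, mol_size, 3)
    out[n_solute:] = solvent[order].reshape(-1, 3)
    return out


def _rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    R = _random_rotation(rng)
    t = rng.uniform(-5.0, 5.0, size=3)
    return coords @ R.T + t


def make_congruent_pair(
    spec: FixtureSpec | None = None, rng: np.random.Generator | None = None
) -> tuple[Snapshot, Snapshot, int]:
    """A pair of geometrically identical frames with scrambled bookkeeping.

    B is A under a solvent-molecule permutation (if ``spec.permute``) and
    a rigid rotation+translation (if ``spec.rotate``); the ground-truth
    minimum RMSD is exactly 0.  Returns (A, B, n_solute).
    """
    spec = spec or FixtureSpec()
    rng = rng or np.random.default_rng(spec.rng_seed)
    elements, coords, n_solute = make_solvated_frame(spec, rng)
    mol_size = len(spec.solvent_template[0])
    b = coords
    if spec.permute:
        b = _permute_solvent_molecules(b, n_solute, mol_size, rng)
    if spec.rotate:
        b = _rigid_motion(b, rng)
    return (
        Snapshot(elements, coords, 0),
        Snapshot(elements, b, 1),
        n_solute,
    )


def make_clustered_trajectory(
    spec: FixtureSpec | None = None, rng: np.random.Generator | None = None
) -> tuple[Trajectory, np.ndarray, int]:
    """Noisy multi-conformer trajectory with ground-truth labels.

    ``spec.n_conformers`` independent solute+solvent layouts serve as the
    underlying states; each frame is one of them plus isotropic Gaussian
    noise of ``spec.noise_sigma`` Å, then solvent-permuted and rigidly
    moved.  Conformers are visited in a shuffled round-robin so every
    state appears.  Returns (trajectory, true_labels, n_solute).
    """
    spec = spec or FixtureSpec()
    if spec.n_conformers < 1:
        raise ValueError("need at least one conformer")
    rng = rng or np.random.default_rng(spec.rng_seed)
    mol_size = len(spec.solvent_template[0])

    elements = None
    conformers = []
    for _ in range(spec.n_conformers):
        el, xyz, n_solute = make_solvated_frame(spec, rng)
        elements = el
        conformers.append(xyz)

    labels = np.array(
        [i % spec.n_conformers for i in range(spec.n_frames)]
    )
    rng.shuffle(labels)
    snaps = []
    for f, lab in enumerate(labels):
        x = conformers[lab] + rng.normal(
            scale=spec.noise_sigma, size=conformers[lab].shape
        )
        if spec.permute:
            x = _permute_solvent_molecules(x, n_solute, mol_size, rng)
        if spec.rotate:
            x = _rigid_motion(x, rng)
        snaps.append(Snapshot(elements, x, f))
    return Trajectory(snaps), labels, n_solute
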