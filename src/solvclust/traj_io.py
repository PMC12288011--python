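"""Multi-frame trajectory reading/writing and atom selection.

Supported input formats are multi-frame XYZ (extended-XYZ comment lines are
tolerated and ignored), PDB (ATOM/HETATM records, MODEL/ENDMDL frame
delimiters, read through MDAnalysis) and fixed-column GRO (concatenated
frames; coordinates are converted from nm to Å on input).  Output formats
are multi-frame XYZ and PDB.

Frames are parsed one at a time; a frame that cannot be parsed raises an
error naming its index, and a frame whose element composition differs from
the first frame raises an "inconsistent composition" error.

Atom selections (hydrogen exclusion and manual 1-based inclusive label
ranges) reduce every frame identically; solute atoms are assumed to occupy
the leading positions of each frame and remain leading after selection.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Snapshot",
    "Trajectory",
    "SoluteSpec",
    "read_trajectory",
    "write_trajectory",
    "iter_frames",
    "apply_selection",
    "parse_ranges",
]

# nm -> Å for GRO coordinates
_NM_TO_ANG = 10.0

# two-letter element symbols recognised when inferring elements from
# atom names (GRO files carry names like OW / HW1 / CA)
_TWO_LETTER = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca",
    "Ti", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "Kr",
    "Rb", "Sr", "Pd", "Ag", "Cd", "Sn", "Te", "Xe", "Cs", "Ba", "Pt",
    "Au", "Hg", "Pb",
}


@dataclass(frozen=True)
class Snapshot:
    """One trajectory frame: element symbols plus Cartesian coordinates (Å)."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3) float64
    frame_index: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords disagree in length")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames of identical composition."""

    snapshots: list[Snapshot]
    source_path: str | None = None
    fmt: str | None = None  # xyz | pdb | gro

    def __post_init__(self):
        if self.snapshots:
            ref = self.snapshots[0].elements
            for s in self.snapshots:
                if s.elements != ref:
                    raise ValueError(
                        f"inconsistent composition at frame {s.frame_index}"
                    )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]

    @property
    def n_frames(self) -> int:
        return len(self.snapshots)

    @property
    def n_atoms(self) -> int:
        return self.snapshots[0].n_atoms if self.snapshots else 0

    @property
    def elements(self) -> tuple[str, ...]:
        return self.snapshots[0].elements if self.snapshots else ()

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as an (M, N, 3) array."""
        return np.stack([s.coords for s in self.snapshots])


@dataclass(frozen=True)
class SoluteSpec:
    """Solute/solvent partition plus exclusion options.

    ``n_solute`` counts solute atoms *after* any exclusions have been
    applied; ``w_solute`` is the total solute weight in [0, 1] (``None``
    means uniform weights, i.e. ``w_solute = n_solute / N``); ``excluded``
    holds original 1-based atom labels to drop; ``no_hydrogen`` drops every
    H (and D) atom by element symbol, case-insensitively.
    """

    n_solute: int
    w_solute: float | None = None
    excluded: frozenset[int] = field(default_factory=frozenset)
    no_hydrogen: bool = False

    def __post_init__(self):
        if self.n_solute < 0:
            raise ValueError("n_solute must be >= 0")
        if self.w_solute is not None and not 0.0 <= self.w_solute <= 1.0:
            raise ValueError("w_solute must be in [0, 1]")
        object.__setattr__(self, "excluded", frozenset(self.excluded))

    def effective_w_solute(self, n_total: int) -> float:
        if self.w_solute is None:
            return self.n_solute / n_total if n_total else 0.0
        return self.w_solute


def parse_ranges(text: str) -> frozenset[int]:
    """Parse comma-separated 1-based inclusive label ranges, e.g. "5-9,22"."""
    out: set[int] = set()
    text = text.strip()
    if not text:
        return frozenset()
    for part in text.split(","):
        part = part.strip()
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", part)
        if not m:
            raise ValueError(f"bad atom range {part!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo < 1 or hi < lo:
            raise ValueError(f"bad atom range {part!r}")
        out.update(range(lo, hi + 1))
    return frozenset(out)


def _is_hydrogen(symbol: str) -> bool:
    return symbol.strip().capitalize() in ("H", "D")


def _element_from_name(name: str) -> str:
    """Infer an element symbol from an atom name (e.g. OW1 -> O)."""
    letters = "".join(ch for ch in name if ch.isalpha())
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    cand2 = letters[:2].capitalize()
    if cand2 in _TWO_LETTER:
        return cand2
    return letters[0].upper()


# ---------------------------------------------------------------- readers


def _iter_xyz(path: Path) -> Iterator[Snapshot]:
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header.strip():
                if header == "" or not fh.readline():
                    return
                continue
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise ValueError(
                    f"unparseable frame {idx} in {path}: bad atom count line"
                ) from exc
            fh.readline()  # comment / extended-xyz line, ignored
            elements: list[str] = []
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"unparseable frame {idx} in {path}")
                elements.append(parts[0].capitalize())
                try:
                    coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                except ValueError as exc:
                    raise ValueError(f"unparseable frame {idx} in {path}") from exc
            yield Snapshot(tuple(elements), coords, idx)
            idx += 1


def _iter_gro(path: Path) -> Iterator[Snapshot]:
    with open(path) as fh:
        idx = 0
        while True:
            title = fh.readline()
            if not title.strip():
                return
            count_line = fh.readline()
            try:
                n = int(count_line.split()[0])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable frame {idx} in {path}") from exc
            elements: list[str] = []
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                if len(line) < 44:
                    raise ValueError(f"unparseable frame {idx} in {path}")
                name = line[10:15].strip()
                try:
                    coords[i] = [
                        float(line[20:28]),
                        float(line[28:36]),
                        float(line[36:44]),
                    ]
                except ValueError as exc:
                    raise ValueError(f"unparseable frame {idx} in {path}") from exc
                elements.append(_element_from_name(name))
            fh.readline()  # box vectors
            yield Snapshot(tuple(elements), coords * _NM_TO_ANG, idx)
            idx += 1


def _iter_pdb(path: Path) -> Iterator[Snapshot]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        try:
            elements = tuple(
                el.capitalize() for el in u.atoms.elements
            )
        except Exception:
            elements = tuple(_element_from_name(nm) for nm in u.atoms.names)
        for idx, _ts in enumerate(u.trajectory):
            yield Snapshot(elements, u.atoms.positions.astype(float), idx)


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("xyz", "pdb", "gro"):
        raise ValueError(f"unsupported trajectory format {fmt!r} (xyz/pdb/gro)")
    return fmt


def iter_frames(path: str | Path, format_hint: str | None = None) -> Iterator[Snapshot]:
    """Stream frames one by one without holding the whole file in memory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    it = {"xyz": _iter_xyz, "gro": _iter_gro, "pdb": _iter_pdb}[fmt]
    ref: tuple[str, ...] | None = None
    for snap in it(path):
        if ref is None:
            ref = snap.elements
        elif snap.elements != ref:
            raise ValueError(
                f"inconsistent composition at frame {snap.frame_index} of {path}"
            )
        yield snap


def read_trajectory(path: str | Path, format_hint: str | None = None) -> Trajectory:
    """Read all frames of a multi-frame XYZ/PDB/GRO file."""
    path = Path(path)
    snaps = list(iter_frames(path, format_hint))
    if not snaps:
        raise ValueError(f"no frames found in {path}")
    fmt = _detect_format(path, format_hint)
    return Trajectory(snaps, source_path=str(path), fmt=fmt)


# ---------------------------------------------------------------- writers


def _write_xyz(traj_or_frames, path: Path) -> None:
    with open(path, "w") as fh:
        for snap in traj_or_frames:
            fh.write(f"{snap.n_atoms}\n")
            fh.write(f"frame {snap.frame_index}\n")
            for el, (x, y, z) in zip(snap.elements, snap.coords):
                fh.write(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def _write_pdb(frames: Sequence[Snapshot], path: Path) -> None:
    import MDAnalysis as mda

    frames = list(frames)
    n = frames[0].n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", list(frames[0].elements))
        u.add_TopologyAttr("elements", list(frames[0].elements))
        u.add_TopologyAttr("resnames", ["MOL"])
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for snap in frames:
                u.atoms.positions = snap.coords
                w.write(u.atoms)


def write_trajectory(traj: Trajectory | Sequence[Snapshot], path: str | Path,
                     fmt: str | None = None) -> None:
    """Write frames as multi-frame XYZ or PDB."""
    path = Path(path)
    frames = list(traj)
    if not frames:
        raise ValueError("nothing to write")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        _write_xyz(frames, path)
    elif fmt == "pdb":
        _write_pdb(frames, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r} (xyz/pdb)")


# --------------------------------------------------------------- selection


class Selection(NamedTuple):
    trajectory: Trajectory
    index_map: tuple[int, ...]  # reduced position -> original 1-based label
    spec: SoluteSpec  # n_solute recomputed for the reduced frames


def apply_selection(
    traj: Trajectory, spec: SoluteSpec, n_solute_original: int | None = None
) -> Selection:
    """Reduce every frame by the exclusion options of ``spec``.

    ``n_solute_original`` is the pre-exclusion solute atom count (the
    leading atoms of each original frame); when omitted, ``spec.n_solute``
    is taken to already refer to the original frame.  The returned spec's
    ``n_solute`` counts the solute atoms that survive the selection, which
    remain the leading positions of every reduced frame.

    Idempotent: applying the returned (exclusion-free) spec again is the
    identity.
    """
    n = traj.n_atoms
    ns_orig = spec.n_solute if n_solute_original is None else n_solute_original
    if not 0 <= ns_orig <= n:
        raise ValueError("solute atom count out of range")
    bad = [i for i in spec.excluded if not 1 <= i <= n]
    if bad:
        raise ValueError(f"excluded labels out of range: {sorted(bad)}")

    elements = traj.elements
    keep = [
        i
        for i in range(n)
        if (i + 1) not in spec.excluded
        and not (spec.no_hydrogen and _is_hydrogen(elements[i]))
    ]
    if not keep:
        raise ValueError("selection removes every atom")
    n_solute_new = sum(1 for i in keep if i < ns_orig)
    w_eff = spec.w_solute
    if n_solute_new == 0 and w_eff is not None and w_eff > 0:
        raise ValueError(
            "selection removes all solute atoms but w_solute > 0"
        )
    keep_arr = np.array(keep)
    new_snaps = [
        Snapshot(
            tuple(elements[i] for i in keep),
            s.coords[keep_arr],
            s.frame_index,
        )
        for s in traj
    ]
    new_spec = replace(
        spec, n_solute=n_solute_new, excluded=frozenset(), no_hydrogen=False
    )
    reduced = Trajectory(new_snaps, source_path=traj.source_path, fmt=traj.fmt)
    return Selection(reduced, tuple(i + 1 for i in keep), new_spec)
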