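"""Multi-model PDB reading/writing and atom selection.

The fixed-column ATOM/HETATM/MODEL/ENDMDL subset of the PDB format is the
canonical interchange format for both single structures and coordinate
ensembles (one MODEL block per frame).  Author residue numbering is kept
exactly as found in the source file; nothing is renumbered.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AmbiguousSelectionError,
    EmptyStructureError,
    InsufficientFramesError,
    NoMatchError,
    ParameterError,
    PDBParseError,
)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "EnsembleTrajectory",
    "AtomSelection",
    "read_structure",
    "read_ensemble",
    "select_atoms",
    "select_one",
    "write_structure",
    "write_ensemble",
]


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record.

    ``resid`` is the author residue number; ``icode`` the insertion code
    (empty string when absent).  ``coords`` is a length-3 tuple in Å.
    """

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    coords: tuple[float, float, float]
    bfactor: float = 0.0
    element: str = ""
    occupancy: float = 1.0
    altloc: str = ""
    icode: str = ""
    hetatm: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ParameterError(f"non-finite coordinates for atom {self.serial}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.icode)


@dataclasses.dataclass
class StructureModel:
    """An ordered list of atoms belonging to one MODEL block."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ParameterError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            dataclasses.replace(a, coords=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return StructureModel(atoms=atoms, model_id=self.model_id)


class EnsembleTrajectory:
    """Frames × atoms coordinate stack over a fixed topology.

    Every frame shares the atom order of ``topology``; the topology's own
    coordinates are ignored.
    """

    def __init__(self, topology: Sequence[AtomRecord], frames: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ParameterError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(topology):
            raise ParameterError(
                f"frame atom count {frames.shape[1]} != topology size {len(topology)}"
            )
        if frames.shape[0] < 1:
            raise InsufficientFramesError("an ensemble needs at least one frame")
        self.topology = list(topology)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @classmethod
    def from_models(cls, models: Sequence[StructureModel]) -> "EnsembleTrajectory":
        if not models:
            raise EmptyStructureError("no models given")
        n = len(models[0].atoms)
        for m in models:
            if len(m.atoms) != n:
                raise ParameterError(
                    f"model {m.model_id} has {len(m.atoms)} atoms, expected {n}"
                )
        frames = np.stack([m.coords for m in models])
        return cls(models[0].atoms, frames)

    def model(self, i: int) -> StructureModel:
        """Materialize frame ``i`` as a StructureModel."""
        return StructureModel(self.topology, model_id=i + 1).with_coords(self.frames[i])


@dataclasses.dataclass(frozen=True)
class AtomSelection:
    """Conjunctive atom-selection criteria; empty criteria select everything."""

    chain: str | None = None
    resid_range: tuple[int, int] | None = None
    resids: frozenset[int] | None = None
    names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.resid_range is not None:
            lo, hi = self.resid_range
            if lo > hi:
                raise ParameterError(f"resid_range lo {lo} > hi {hi}")
        if self.resids is not None:
            object.__setattr__(self, "resids", frozenset(self.resids))
        if self.names is not None:
            object.__setattr__(self, "names", frozenset(self.names))

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resid_range is not None and not (
            self.resid_range[0] <= atom.resid <= self.resid_range[1]
        ):
            return False
        if self.resids is not None and atom.resid not in self.resids:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        return True

    def describe(self) -> str:
        parts = []
        if self.chain is not None:
            parts.append(f"chain={self.chain}")
        if self.resid_range is not None:
            parts.append(f"resid_range={self.resid_range[0]}-{self.resid_range[1]}")
        if self.resids is not None:
            parts.append(f"resids={{{','.join(map(str, sorted(self.resids)))}}}")
        if self.names is not None:
            parts.append(f"names={{{','.join(sorted(self.names))}}}")
        return " and ".join(parts) if parts else "<all atoms>"


# ---------------------------------------------------------------------------
# PDB parsing

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(b_field) if b_field else 0.0
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if not element:
        # Standard PDB atom names carry the element in columns 13-14.
        element = line[12:14].strip().lstrip("0123456789")[:1]
    return AtomRecord(
        serial=serial,
        name=name,
        resname=resname,
        chain=chain,
        resid=resid,
        coords=(x, y, z),
        bfactor=bfactor,
        element=element,
        occupancy=occupancy,
        altloc=altloc,
        icode=icode,
        hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per (chain, resid, icode, name): the highest
    occupancy, ties broken by first occurrence."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain, a.resid, a.icode, a.name)
        if key not in best:
            best[key] = i
        elif a.occupancy > atoms[best[key]].occupancy:
            best[key] = i
    keep = sorted(best.values())
    out = []
    for i in keep:
        a = atoms[i]
        if a.altloc:
            a = dataclasses.replace(a, altloc="")
        out.append(a)
    return out


def read_structure(path: str | Path) -> list[StructureModel]:
    """Read a (possibly multi-model) PDB file.

    Returns one :class:`StructureModel` per MODEL block; a file without
    MODEL records yields a single model.  Alternate locations are reduced
    to the highest-occupancy conformer.
    """
    path = Path(path)
    models: list[StructureModel] = []
    current: list[AtomRecord] = []
    model_id = 1
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(StructureModel(_resolve_altlocs(current), model_id))
                    current = []
                try:
                    model_id = int(line.split()[1])
                except (IndexError, ValueError):
                    model_id = len(models) + 1
                in_model = True
            elif rec == "ENDMDL":
                models.append(StructureModel(_resolve_altlocs(current), model_id))
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
    if current:
        models.append(StructureModel(_resolve_altlocs(current), model_id if in_model else 1))
    if not models or all(len(m) == 0 for m in models):
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return [m for m in models if len(m) > 0]


def read_ensemble(path: str | Path) -> EnsembleTrajectory:
    """Read a multi-model PDB as an ensemble (one frame per MODEL)."""
    return EnsembleTrajectory.from_models(read_structure(path))


# ---------------------------------------------------------------------------
# Selection

def select_atoms(
    model_or_traj: StructureModel | EnsembleTrajectory | Sequence[AtomRecord],
    sel: AtomSelection,
) -> np.ndarray:
    """Indices (ascending, topology order) of atoms matching all criteria."""
    atoms = _atoms_of(model_or_traj)
    return np.array([i for i, a in enumerate(atoms) if sel.matches(a)], dtype=int)


def select_one(
    model_or_traj: StructureModel | EnsembleTrajectory | Sequence[AtomRecord],
    sel: AtomSelection,
) -> int:
    """Index of the unique atom matching ``sel``; raises otherwise."""
    idx = select_atoms(model_or_traj, sel)
    if len(idx) == 0:
        raise NoMatchError(f"no atom matches {sel.describe()}")
    if len(idx) > 1:
        raise AmbiguousSelectionError(
            f"{len(idx)} atoms match {sel.describe()}; exactly one required"
        )
    return int(idx[0])


def _atoms_of(obj) -> Sequence[AtomRecord]:
    if isinstance(obj, StructureModel):
        return obj.atoms
    if isinstance(obj, EnsembleTrajectory):
        return obj.topology
    return obj


# ---------------------------------------------------------------------------
# Writing

def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.hetatm else "ATOM  "
    # Atom-name column convention: names shorter than 4 chars start in col 14.
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{record}{serial:>5d} {name:<4s}{a.altloc or ' ':1s}{a.resname:>3s} "
        f"{a.chain or ' ':1s}{a.resid:>4d}{a.icode or ' ':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write one model in fixed-column PDB format.

    Round-trips (chain, resid, name) exactly and coordinates to 3 decimals.
    """
    if len(model.atoms) == 0:
        raise EmptyStructureError("refusing to write an empty model")
    path = Path(path)
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            fh.write(_format_atom_line(a, i % 100000) + "\n")
        fh.write("END\n")
    return path


def write_ensemble(traj: EnsembleTrajectory, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB (one MODEL block per frame)."""
    if traj.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty ensemble")
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            for i, (a, xyz) in enumerate(zip(traj.topology, traj.frames[f]), start=1):
                a = dataclasses.replace(a, coords=tuple(float(v) for v in xyz))
                fh.write(_format_atom_line(a, i % 100000) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path
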