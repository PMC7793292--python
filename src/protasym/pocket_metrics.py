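"""Binding-pocket metrics: landmark distance series/populations and
probe-based solvent-accessible surface area (Shrake-Rupley)."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InsufficientDataError,
    NoMatchError,
    ParameterError,
    RadiusAssignmentError,
)
from .structure_io import (
    AtomSelection,
    EnsembleTrajectory,
    StructureModel,
    select_atoms,
    select_one,
)

__all__ = [
    "DistanceSeries",
    "DistancePopulation",
    "SasaResult",
    "VDW_RADII",
    "atom_pair_distance_series",
    "distance_population",
    "population_mass",
    "golden_spiral_points",
    "pocket_sasa",
]

# Element-based van der Waals radii (Å).
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}


@dataclasses.dataclass
class DistanceSeries:
    values: np.ndarray
    atom1_id: str
    atom2_id: str

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))


@dataclasses.dataclass
class DistancePopulation:
    bin_centers: np.ndarray
    probability: np.ndarray  # density per Å; integrates to 1
    binwidth: float


@dataclasses.dataclass
class SasaResult:
    areas: np.ndarray  # per-frame pocket area, Å²
    probe_radius: float
    pocket_residues: list[int]
    n_sphere_points: int


def _as_traj(obj: StructureModel | EnsembleTrajectory) -> EnsembleTrajectory:
    if isinstance(obj, StructureModel):
        return EnsembleTrajectory(obj.atoms, obj.coords[None, :, :])
    return obj


def atom_pair_distance_series(
    traj_or_model: StructureModel | EnsembleTrajectory,
    sel1: AtomSelection,
    sel2: AtomSelection,
) -> DistanceSeries:
    """Per-frame Euclidean distance between two uniquely selected atoms.

    No superposition is applied: pair distances are invariant to global
    motion.
    """
    traj = _as_traj(traj_or_model)
    i1 = select_one(traj, sel1)
    i2 = select_one(traj, sel2)
    diff = traj.frames[:, i1] - traj.frames[:, i2]
    a1, a2 = traj.topology[i1], traj.topology[i2]
    return DistanceSeries(
        values=np.linalg.norm(diff, axis=1),
        atom1_id=f"{a1.chain}:{a1.resid}:{a1.name}",
        atom2_id=f"{a2.chain}:{a2.resid}:{a2.name}",
    )


def distance_population(series: DistanceSeries, binwidth: float = 0.1) -> DistancePopulation:
    """Normalized histogram of a distance series, padded one bin each side."""
    if binwidth <= 0:
        raise ParameterError("binwidth must be positive")
    v = series.values
    if len(v) < 2:
        raise InsufficientDataError("need >= 2 frames to form a population")
    lo = max(0.0, np.floor(v.min() / binwidth) * binwidth - binwidth)
    hi = np.ceil(v.max() / binwidth) * binwidth + binwidth
    nbins = max(int(round((hi - lo) / binwidth)), 1)
    density, edges = np.histogram(v, bins=nbins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DistancePopulation(bin_centers=centers, probability=density, binwidth=binwidth)


def population_mass(pop: DistancePopulation, lo: float, hi: float) -> float:
    """Probability mass carried by bins whose centers lie in [lo, hi]."""
    mask = (pop.bin_centers >= lo) & (pop.bin_centers <= hi)
    return float(np.sum(pop.probability[mask]) * pop.binwidth)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms, overrides: dict[str, float] | None) -> np.ndarray:
    table = dict(VDW_RADII)
    if overrides:
        table.update(overrides)
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = (a.element or "").capitalize()
        if el not in table:
            raise RadiusAssignmentError(
                f"no van der Waals radius for element '{a.element}' "
                f"(atom {a.chain}:{a.resid}:{a.name}); supply an override"
            )
        radii[i] = table[el]
    return radii


def _frame_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    pocket_idx: np.ndarray,
    probe: float,
    sphere: np.ndarray,
) -> float:
    """Shrake-Rupley accessible area of the pocket atoms in one frame.

    Every atom in the model occludes, not only pocket atoms.
    """
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = expanded.max()
    area = 0.0
    for i in pocket_idx:
        r_i = expanded[i]
        pts = coords[i] + r_i * sphere
        neigh = tree.query_ball_point(coords[i], r_i + max_reach)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        area += frac * 4.0 * np.pi * r_i * r_i
    return float(area)


def pocket_sasa(
    model_or_traj: StructureModel | EnsembleTrajectory,
    pocket_residues: AtomSelection,
    probe_radius: float = 2.8,
    n_sphere_points: int = 960,
    radius_overrides: dict[str, float] | None = None,
) -> SasaResult:
    """Probe-accessible surface area of the pocket selection, per frame.

    The default 2.8 Å probe approximates the radius of a sphere with the
    ligand's molecular volume (configurable; recorded in the result).
    """
    if probe_radius <= 0:
        raise ParameterError("probe_radius must be positive")
    if n_sphere_points < 10:
        raise ParameterError("n_sphere_points too small")
    traj = _as_traj(model_or_traj)
    pocket_idx = select_atoms(traj, pocket_residues)
    if len(pocket_idx) == 0:
        raise NoMatchError(f"pocket selection matched nothing: {pocket_residues.describe()}")
    radii = _radii_for(traj.topology, radius_overrides)
    sphere = golden_spiral_points(n_sphere_points)
    areas = np.array(
        [
            _frame_sasa(traj.frames[f], radii, pocket_idx, probe_radius, sphere)
            for f in range(traj.n_frames)
        ]
    )
    resids = sorted({traj.topology[i].resid for i in pocket_idx})
    return SasaResult(
        areas=areas,
        probe_radius=probe_radius,
        pocket_residues=resids,
        n_sphere_points=n_sphere_points,
    )
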