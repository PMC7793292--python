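"""Inter-domain polar displacement vectors, the per-frame asymmetry index,
and helix hinge-angle decomposition."""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InsufficientDataError,
    NormalizationError,
    PairingError,
)
from .structure_io import (
    AtomSelection,
    EnsembleTrajectory,
    StructureModel,
    select_atoms,
    select_one,
)
from .superposition import kabsch_superpose

__all__ = [
    "PolarVectorSeries",
    "AsymmetryResult",
    "HingeAngles",
    "interdomain_vector_series",
    "asymmetry_index",
    "hinge_angles",
]


@dataclasses.dataclass
class PolarVectorSeries:
    """Per-frame (d, theta, phi) of an anchor-to-anchor vector.

    Angles are in degrees: theta in [0, 180] measured from the body-frame
    +z axis, phi in (-180, 180] from +x.  The body frame is defined by
    superposing each frame onto frame 0 over ``frame_definition`` atoms.
    """

    d: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    anchorA_id: str
    anchorB_id: str
    frame_definition: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if not len(self.d) == len(self.theta) == len(self.phi):
            raise PairingError("d/theta/phi series lengths differ")

    def __len__(self) -> int:
        return len(self.d)


@dataclasses.dataclass(frozen=True)
class AsymmetryResult:
    """Mean-normalized per-frame difference of theta, phi, d (percent)."""

    delta_theta: float
    delta_phi: float
    delta_d: float
    n_frames: int


@dataclasses.dataclass(frozen=True)
class HingeAngles:
    angle_BC: float
    angle_CN: float
    segment_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    axis_method: str = "principal-axis"


def _to_polar(vec: np.ndarray) -> tuple[float, float, float]:
    d = float(np.linalg.norm(vec))
    if d == 0.0:
        raise DegenerateGeometryError("anchors coincide; polar angles undefined")
    theta = float(np.degrees(np.arccos(np.clip(vec[2] / d, -1.0, 1.0))))
    # On the polar axis the azimuth is undefined; report 0 by convention.
    if np.hypot(vec[0], vec[1]) < 1e-12 * d:
        phi = 0.0
    else:
        phi = float(np.degrees(np.arctan2(vec[1], vec[0])))
        if phi <= -180.0:
            phi += 360.0
    return d, theta, phi


def interdomain_vector_series(
    traj: EnsembleTrajectory,
    anchorA_sel: AtomSelection,
    anchorB_sel: AtomSelection,
    body_frame_sel: AtomSelection,
) -> PolarVectorSeries:
    """Spherical coordinates of anchorB - anchorA per frame.

    Global motion is removed by superposing every frame onto frame 0 using
    the ``body_frame_sel`` atoms; the body axes are inherited from the
    frame-0 coordinates.
    """
    ia = select_one(traj, anchorA_sel)
    ib = select_one(traj, anchorB_sel)
    body_idx = select_atoms(traj, body_frame_sel)
    if len(body_idx) < 3:
        raise DegenerateGeometryError(
            f"body frame needs >= 3 atoms, got {len(body_idx)}"
        )
    reference = traj.frames[0, body_idx]
    d_out = np.empty(traj.n_frames)
    t_out = np.empty(traj.n_frames)
    p_out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fit = kabsch_superpose(traj.frames[f, body_idx], reference)
        pair = fit.apply(traj.frames[f, [ia, ib]])
        d_out[f], t_out[f], p_out[f] = _to_polar(pair[1] - pair[0])
    atomA = traj.topology[ia]
    atomB = traj.topology[ib]
    return PolarVectorSeries(
        d=d_out,
        theta=t_out,
        phi=p_out,
        anchorA_id=f"{atomA.chain}:{atomA.resid}:{atomA.name}",
        anchorB_id=f"{atomB.chain}:{atomB.resid}:{atomB.name}",
        frame_definition=f"superposed onto frame 0 via {body_frame_sel.describe()}",
    )


def _normalized(x: np.ndarray, label: str) -> np.ndarray:
    mean = x.mean()
    if abs(mean) < 1e-12:
        raise NormalizationError(f"mean of {label} is zero; cannot normalize")
    return x / mean


def asymmetry_index(series1: PolarVectorSeries, series2: PolarVectorSeries) -> AsymmetryResult:
    """DeltaX = 100 * mean_frames |X1/mean(X1) - X2/mean(X2)| for X in
    (theta, phi, d).

    Azimuth series are unwrapped onto a continuous branch before the means
    are taken, so branch cuts at ±180° cannot corrupt the normalization.
    """
    if len(series1) != len(series2):
        raise PairingError(
            f"series lengths differ: {len(series1)} vs {len(series2)}"
        )
    n = len(series1)

    def delta(x1: np.ndarray, x2: np.ndarray, label: str) -> float:
        return float(100.0 * np.mean(np.abs(_normalized(x1, label) - _normalized(x2, label))))

    phi1 = np.degrees(np.unwrap(np.radians(series1.phi)))
    phi2 = np.degrees(np.unwrap(np.radians(series2.phi)))
    return AsymmetryResult(
        delta_theta=delta(series1.theta, series2.theta, "theta"),
        delta_phi=delta(phi1, phi2, "phi"),
        delta_d=delta(series1.d, series2.d, "d"),
        n_frames=n,
    )


def _segment_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis of a segment, oriented from first to last atom."""
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10:
        raise DegenerateGeometryError("segment atoms are coincident")
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def hinge_angles(
    model: StructureModel,
    segB: tuple[int, int],
    segC: tuple[int, int],
    segN: tuple[int, int],
    atom_name: str = "CA",
    chain: str | None = None,
) -> HingeAngles:
    """Angles between consecutive helix-segment axes.

    Each segment axis is the largest-variance principal direction of the
    segment's ``atom_name`` atoms, oriented along increasing residue number;
    the reported angle is arccos of the axis dot product, in degrees.
    """
    ranges = [tuple(segB), tuple(segC), tuple(segN)]
    for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
        if lo2 <= hi1 and lo1 <= hi2:
            raise ConfigurationError(
                f"segment ranges {lo1}-{hi1} and {lo2}-{hi2} overlap"
            )
    axes = []
    for lo, hi in ranges:
        sel = AtomSelection(chain=chain, resid_range=(lo, hi), names=frozenset({atom_name}))
        idx = select_atoms(model, sel)
        if len(idx) < 3:
            raise InsufficientDataError(
                f"segment {lo}-{hi} has {len(idx)} '{atom_name}' atoms; need >= 3"
            )
        coords = model.coords[idx]
        order = np.argsort([model.atoms[i].resid for i in idx], kind="stable")
        axes.append(_segment_axis(coords[order]))

    def angle(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))

    return HingeAngles(
        angle_BC=angle(axes[0], axes[1]),
        angle_CN=angle(axes[1], axes[2]),
        segment_ranges=(ranges[0], ranges[1], ranges[2]),
    )
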