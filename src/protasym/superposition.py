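"""Least-squares rigid-body superposition and per-residue RMSF profiles."""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateGeometryError, InsufficientFramesError, NoMatchError
from .structure_io import AtomSelection, EnsembleTrajectory, select_atoms

__all__ = ["SuperpositionResult", "FlexibilityProfile", "kabsch_superpose", "compute_rmsf"]


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation minimizing weighted RMSD.

    Applying the transform maps ``mobile`` onto ``reference``:
    ``mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Reflections are excluded by flipping the sign of the smallest singular
    value when the raw determinant is negative.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise DegenerateGeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    pm = mobile - mu_m
    pr = reference - mu_r
    cov = (pm * w[:, None]).T @ pr
    u, s, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise DegenerateGeometryError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = pm @ rot.T - pr
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    trans = mu_r - rot @ mu_m
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


@dataclasses.dataclass
class FlexibilityProfile:
    """Per-residue RMSF after ensemble superposition."""

    chains: list[str]
    resids: list[int]
    rmsf: np.ndarray
    align_selection: AtomSelection
    target_selection: AtomSelection

    def as_records(self) -> list[dict]:
        return [
            {"chain": c, "resid": r, "rmsf_A": float(v)}
            for c, r, v in zip(self.chains, self.resids, self.rmsf)
        ]


def align_frames(
    traj: EnsembleTrajectory,
    align_idx: np.ndarray,
    n_iterations: int = 2,
) -> np.ndarray:
    """Superpose every frame onto the iterated mean structure.

    Round 0 aligns to frame 0; each further round re-aligns to the mean of
    the previous round's aligned frames.  Returns the aligned coordinate
    stack (same shape as ``traj.frames``).
    """
    frames = traj.frames.copy()
    reference = frames[0, align_idx]
    for _ in range(n_iterations):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            fit = kabsch_superpose(frames[f, align_idx], reference)
            aligned[f] = fit.apply(frames[f])
        frames = aligned
        reference = frames[:, align_idx].mean(axis=0)
    return frames


def compute_rmsf(
    traj: EnsembleTrajectory,
    align_sel: AtomSelection,
    target_sel: AtomSelection,
) -> FlexibilityProfile:
    """Residue-level RMSF of ``target_sel`` atoms after aligning on ``align_sel``.

    Atom RMSF_i = sqrt(mean_frames |x_i - <x_i>|^2); residue values average
    the residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    align_idx = select_atoms(traj, align_sel)
    target_idx = select_atoms(traj, target_sel)
    if len(align_idx) == 0:
        raise NoMatchError(f"alignment selection matched nothing: {align_sel.describe()}")
    if len(target_idx) == 0:
        raise NoMatchError(f"target selection matched nothing: {target_sel.describe()}")

    aligned = align_frames(traj, align_idx)
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    atom_rmsf = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))

    # Group target atoms by residue, preserving first-seen order.
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in target_idx:
        a = traj.topology[i]
        groups.setdefault(a.residue_key, []).append(int(i))
    chains, resids, values = [], [], []
    for (chain, resid, _icode), idxs in groups.items():
        chains.append(chain)
        resids.append(resid)
        values.append(float(atom_rmsf[idxs].mean()))
    return FlexibilityProfile(
        chains=chains,
        resids=resids,
        rmsf=np.array(values),
        align_selection=align_sel,
        target_selection=target_sel,
    )
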