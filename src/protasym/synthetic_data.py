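"""Synthetic test-data generators.

Three families of inputs are produced, matching the statistical structure
the downstream analyses assume:

* coarse two-protomer ensembles in which equivalent mobile domains hinge
  with unequal amplitude and a two-state binding pocket opens and closes,
* uniform bead spheres whose scattering, Rg and volume have closed forms,
* noisy Hill-model activation curves with known generator parameters.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .activation import DoseResponse, hill_model
from .errors import ParameterError
from .structure_io import AtomRecord, EnsembleTrajectory, StructureModel

__all__ = [
    "ProtomerTemplate",
    "EnsembleParams",
    "SyntheticTruth",
    "default_template",
    "make_two_protomer_ensemble",
    "make_sphere_bead_model",
    "make_dose_response",
    "OPEN_DISTANCE",
    "CLOSED_DISTANCE",
    "POCKET_SPREAD",
]

# Pocket landmark separations (Å): open / cAMP-bound-like closed state, with
# a Gaussian spread that makes two-state distance populations resolvable.
OPEN_DISTANCE = 6.9
CLOSED_DISTANCE = 4.9
POCKET_SPREAD = 0.3


@dataclasses.dataclass
class ProtomerTemplate:
    """Coarse single-protomer geometry.

    ``atoms`` are template-local records (chain is overwritten on placement);
    ``mobile_mask`` flags the atoms of the hinged domain.  Anchors A/B play
    the roles of the stable-domain and mobile-domain displacement-vector
    endpoints; ``pocket_pair`` indexes the two pocket landmark atoms.
    """

    atoms: list[AtomRecord]
    mobile_mask: np.ndarray
    pivot_index: int
    anchorA_index: int
    anchorB_index: int
    pocket_pair: tuple[int, int]
    hinge_axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        self.mobile_mask = np.asarray(self.mobile_mask, dtype=bool)
        if len(self.mobile_mask) != len(self.atoms):
            raise ParameterError("mobile_mask length must equal atom count")
        if self.mobile_mask[self.pivot_index]:
            raise ParameterError("pivot atom must belong to the core")
        if self.mobile_mask[self.anchorA_index]:
            raise ParameterError("anchor A must be on the core side")
        if not self.mobile_mask[self.anchorB_index]:
            raise ParameterError("anchor B must be in the mobile domain")
        if not (
            self.mobile_mask[self.pocket_pair[0]] and self.mobile_mask[self.pocket_pair[1]]
        ):
            raise ParameterError("pocket pair atoms must be in the mobile domain")
        self.hinge_axis = np.asarray(self.hinge_axis, dtype=float)
        self.hinge_axis = self.hinge_axis / np.linalg.norm(self.hinge_axis)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclasses.dataclass
class EnsembleParams:
    n_frames: int
    hinge_sigma_p1: float
    hinge_sigma_p2: float
    core_jitter_sigma: float = 0.0
    pocket_open_fraction_p1: float = 0.5
    pocket_open_fraction_p2: float = 0.5
    pocket_spread: float = POCKET_SPREAD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        for name in ("hinge_sigma_p1", "hinge_sigma_p2", "core_jitter_sigma", "pocket_spread"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("pocket_open_fraction_p1", "pocket_open_fraction_p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")


@dataclasses.dataclass
class SyntheticTruth:
    """Generator parameters and per-frame latent states, for recovery tests."""

    params: dict
    latents: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "params": self.params,
            "latents": {k: np.asarray(v).tolist() for k, v in self.latents.items()},
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _res(serial, name, resname, resid, xyz, element) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name,
        resname=resname,
        chain="A",
        resid=resid,
        coords=tuple(float(v) for v in xyz),
        element=element,
    )


def default_template(arm_offset: float = 15.0) -> ProtomerTemplate:
    """Build the default coarse protomer.

    A stable core of CA pseudo-atoms (resids 210-265) runs up the local z
    direction at x = ``arm_offset``; the mobile domain (resids 330-369)
    continues outward past the pivot (resid 265).  Anchor A is resid 230 CA
    (core), anchor B resid 359 CA (mobile); the pocket pair is resid 360 CB
    vs resid 351 CG, both in the mobile domain.
    """
    atoms: list[AtomRecord] = []
    mobile: list[bool] = []
    serial = 1

    # Core: gentle helix-like sweep so the coordinates have full rank.
    core_resids = list(range(210, 266))
    for k, resid in enumerate(core_resids):
        angle = 0.6 * k
        xyz = (
            arm_offset + 2.0 * np.cos(angle),
            2.0 * np.sin(angle),
            1.2 * k,
        )
        atoms.append(_res(serial, "CA", "GLY", resid, xyz, "C"))
        mobile.append(False)
        serial += 1

    pivot_index = len(atoms) - 1  # resid 265 CA
    pivot_xyz = np.array(atoms[pivot_index].coords)
    anchorA_index = core_resids.index(230)

    # Mobile domain: continues outward/up from the pivot.
    mobile_resids = list(range(330, 370))
    direction = np.array([0.8, 0.3, 0.52])
    direction /= np.linalg.norm(direction)
    mobile_index_of: dict[int, int] = {}
    for k, resid in enumerate(mobile_resids):
        angle = 0.7 * k
        base = pivot_xyz + direction * (2.0 + 1.1 * k)
        perp = np.array([1.5 * np.cos(angle), 1.5 * np.sin(angle), 0.0])
        atoms.append(_res(serial, "CA", "GLY", resid, base + perp, "C"))
        mobile_index_of[resid] = len(atoms) - 1
        mobile.append(True)
        serial += 1

    # Pocket landmark atoms hang off their residues' CA positions.
    ca351 = np.array(atoms[mobile_index_of[351]].coords)
    ca360 = np.array(atoms[mobile_index_of[360]].coords)
    sep_dir = ca360 - ca351
    sep_dir /= np.linalg.norm(sep_dir)
    mid = 0.5 * (ca351 + ca360)
    atoms.append(_res(serial, "CG", "LEU", 351, mid - sep_dir * (OPEN_DISTANCE / 2), "C"))
    mobile.append(True)
    pocket_j = len(atoms) - 1
    serial += 1
    atoms.append(_res(serial, "CB", "ALA", 360, mid + sep_dir * (OPEN_DISTANCE / 2), "C"))
    mobile.append(True)
    pocket_i = len(atoms) - 1

    anchorB_index = mobile_index_of[359]
    return ProtomerTemplate(
        atoms=atoms,
        mobile_mask=np.array(mobile),
        pivot_index=pivot_index,
        anchorA_index=anchorA_index,
        anchorB_index=anchorB_index,
        pocket_pair=(pocket_i, pocket_j),
    )


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis."""
    ux, uy, uz = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )


_C2_FLIP = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)


def make_two_protomer_ensemble(
    template: ProtomerTemplate,
    params: EnsembleParams,
) -> tuple[EnsembleTrajectory, SyntheticTruth]:
    """Two C2-related template copies with independently hinged mobile domains.

    Per frame and protomer, the mobile domain rotates about the pivot by an
    angle drawn N(0, hinge_sigma); core atoms get isotropic Gaussian jitter;
    the pocket-pair separation is reset to a two-state draw
    (open ~ N(6.9, 0.3), closed ~ N(4.9, 0.3) Å) according to the latent
    pocket state.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    hinge = np.stack(
        [
            rng.normal(0.0, params.hinge_sigma_p1, size=n),
            rng.normal(0.0, params.hinge_sigma_p2, size=n),
        ]
    )  # degrees, shape (2, n)
    open_state = np.stack(
        [
            rng.random(n) < params.pocket_open_fraction_p1,
            rng.random(n) < params.pocket_open_fraction_p2,
        ]
    )
    pocket_target = np.where(open_state, OPEN_DISTANCE, CLOSED_DISTANCE) + rng.normal(
        0.0, params.pocket_spread, size=(2, n)
    )
    pocket_target = np.clip(pocket_target, 0.5, None)

    base = template.coords
    n_atoms = len(template.atoms)
    core_mask = ~template.mobile_mask
    jitter = rng.normal(0.0, params.core_jitter_sigma, size=(2, n, int(core_mask.sum()), 3))

    pivot = base[template.pivot_index]
    pi, pj = template.pocket_pair
    frames = np.empty((n, 2 * n_atoms, 3))
    for p in range(2):
        place = np.eye(3) if p == 0 else _C2_FLIP
        for f in range(n):
            coords = base.copy()
            rot = _rotation_about_axis(template.hinge_axis, np.radians(hinge[p, f]))
            coords[template.mobile_mask] = (
                coords[template.mobile_mask] - pivot
            ) @ rot.T + pivot
            v = coords[pi] - coords[pj]
            coords[pi] = coords[pj] + v / np.linalg.norm(v) * pocket_target[p, f]
            coords = coords @ place.T
            coords[core_mask] += jitter[p, f]
            frames[f, p * n_atoms : (p + 1) * n_atoms] = coords

    topology: list[AtomRecord] = []
    for p, chain in enumerate("AB"):
        for a in template.atoms:
            topology.append(
                dataclasses.replace(a, chain=chain, serial=p * n_atoms + a.serial)
            )
    traj = EnsembleTrajectory(topology, frames)
    truth = SyntheticTruth(
        params=dataclasses.asdict(params),
        latents={
            "hinge_deg_p1": hinge[0],
            "hinge_deg_p2": hinge[1],
            "pocket_open_p1": open_state[0],
            "pocket_open_p2": open_state[1],
            "pocket_distance_p1": pocket_target[0],
            "pocket_distance_p2": pocket_target[1],
        },
    )
    return traj, truth


def make_sphere_bead_model(radius: float, n_beads: int, seed: int = 0) -> StructureModel:
    """Beads uniform in a solid ball (rejection sampling), unit weight each."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if n_beads < 100:
        raise ParameterError("need >= 100 beads for a usable sphere model")
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while len(pts) < n_beads:
        cand = rng.uniform(-radius, radius, size=(2 * n_beads, 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        pts = np.vstack([pts, cand])
    pts = pts[:n_beads]
    atoms = [
        _res(i + 1, "C", "BEA", i + 1, xyz, "C") for i, xyz in enumerate(pts)
    ]
    return StructureModel(atoms=atoms, model_id=1)


def make_dose_response(
    ec50: float,
    hill_n: float,
    y0: float,
    ymax: float,
    concentrations: Sequence[float],
    noise_sigma: float,
    n_replicates: int,
    seed: int = 0,
) -> tuple[DoseResponse, SyntheticTruth]:
    """Replicated Hill-model responses with additive Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if ec50 <= 0:
        raise ParameterError("ec50 must be positive")
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    clean = hill_model(conc, ec50, hill_n, y0, ymax)
    c_all, y_all, rep_all = [], [], []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sigma, size=len(conc))
        c_all.append(conc)
        y_all.append(clean + noise)
        rep_all.append(np.full(len(conc), rep + 1))
    data = DoseResponse(
        concentration=np.concatenate(c_all),
        response=np.concatenate(y_all),
        replicate_id=np.concatenate(rep_all),
    )
    truth = SyntheticTruth(
        params={
            "ec50": ec50,
            "hill_n": hill_n,
            "y0": y0,
            "ymax": ymax,
            "noise_sigma": noise_sigma,
            "n_replicates": n_replicates,
            "seed": seed,
        },
        latents={"clean_response": clean},
    )
    return data, truth
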