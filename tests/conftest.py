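import numpy as np
import pytest

from protasym.structure_io import AtomRecord, StructureModel
from protasym.synthetic_data import EnsembleParams, default_template, make_two_protomer_ensemble


def make_atom(serial=1, name="CA", resname="GLY", chain="A", resid=1,
              coords=(0.0, 0.0, 0.0), element="C", **kw):
    return AtomRecord(serial=serial, name=name, resname=resname, chain=chain,
                      resid=resid, coords=coords, element=element, **kw)


@pytest.fixture
def three_atom_model():
    atoms = [
        make_atom(1, "N", "ALA", "A", 1, (11.104, 13.207, 2.100), "N"),
        make_atom(2, "CA", "ALA", "A", 1, (12.560, 13.300, 2.000), "C"),
        make_atom(3, "CB", "ALA", "A", 1, (13.123, 14.700, -1.250), "C"),
    ]
    return StructureModel(atoms=atoms, model_id=1)


@pytest.fixture
def ten_residue_model():
    """Single chain, 10 residues, each with N/CA/C backbone-like atoms."""
    atoms = []
    serial = 1
    for resid in range(1, 11):
        for j, name in enumerate(("N", "CA", "C")):
            atoms.append(
                make_atom(serial, name, "GLY", "A", resid,
                          (1.2 * resid + 0.3 * j, 0.5 * j, 0.1 * resid),
                          "N" if name == "N" else "C")
            )
            serial += 1
    return StructureModel(atoms=atoms, model_id=1)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def asymmetric_ensemble(template):
    """2°/20° hinge ensemble used by several modules (session-cached)."""
    params = EnsembleParams(
        n_frames=2000,
        hinge_sigma_p1=2.0,
        hinge_sigma_p2=20.0,
        core_jitter_sigma=0.1,
        seed=1234,
    )
    return make_two_protomer_ensemble(template, params)


def rigid_transform(coords, angle_deg=30.0, axis=(0, 0, 1.0), shift=(1.0, -2.0, 3.0)):
    """Apply an arbitrary rigid-body motion (for invariance tests)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    ux, uy, uz = axis
    c, s, cc = np.cos(a), np.sin(a), 1 - np.cos(a)
    rot = np.array([
        [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
        [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
        [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
    ])
    return coords @ rot.T + np.asarray(shift)
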