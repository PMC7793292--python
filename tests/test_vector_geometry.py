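import numpy as np
import pytest

from protasym.errors import (
    AmbiguousSelectionError,
    ConfigurationError,
    InsufficientDataError,
    NormalizationError,
    PairingError,
)
from protasym.structure_io import AtomSelection, EnsembleTrajectory, StructureModel
from protasym.synthetic_data import EnsembleParams, make_two_protomer_ensemble
from protasym.vector_geometry import (
    PolarVectorSeries,
    asymmetry_index,
    hinge_angles,
    interdomain_vector_series,
)

from conftest import make_atom, rigid_transform


def _static_traj(anchor_b_offset, n_frames=3):
    """Body-frame tripod (resids 1-3) plus anchors at resid 4 (A) and 5 (B)."""
    atoms = [
        make_atom(1, "CA", "GLY", "A", 1, (0, 0, 0)),
        make_atom(2, "CA", "GLY", "A", 2, (5, 0, 0)),
        make_atom(3, "CA", "GLY", "A", 3, (0, 5, 0)),
        make_atom(4, "CA", "GLY", "A", 4, (1, 1, 1)),
        make_atom(5, "CA", "GLY", "A", 5, tuple(np.add((1, 1, 1), anchor_b_offset))),
    ]
    base = np.array([a.coords for a in atoms], dtype=float)
    return EnsembleTrajectory(atoms, np.repeat(base[None], n_frames, axis=0))


def _series(traj):
    return interdomain_vector_series(
        traj,
        AtomSelection(resids={4}),
        AtomSelection(resids={5}),
        AtomSelection(resid_range=(1, 3)),
    )


class TestInterdomainVector:
    def test_axis_aligned_z(self):
        s = _series(_static_traj((0, 0, 10.0)))
        assert np.allclose(s.d, 10.0)
        assert np.allclose(s.theta, 0.0)
        assert np.allclose(s.phi, 0.0)  # undefined azimuth reported as 0

    def test_closed_form_conversion(self):
        s = _series(_static_traj((1.0, 1.0, 0.0)))
        assert np.allclose(s.d, np.sqrt(2))
        assert np.allclose(s.theta, 90.0)
        assert np.allclose(s.phi, 45.0)

    def test_global_motion_removed(self):
        traj = _static_traj((1.0, 1.0, 0.0), n_frames=4)
        moved = traj.frames.copy()
        for f in range(1, 4):
            moved[f] = rigid_transform(moved[f], 25.0 * f, (1, 1, 0), (f, -f, 2 * f))
        s = _series(EnsembleTrajectory(traj.topology, moved))
        assert np.allclose(s.d, np.sqrt(2), atol=1e-9)
        assert np.allclose(s.theta, 90.0, atol=1e-6)
        assert np.allclose(s.phi, 45.0, atol=1e-6)

    def test_d_invariant_to_body_frame_choice(self, asymmetric_ensemble):
        traj, _ = asymmetric_ensemble
        common = dict(
            anchorA_sel=AtomSelection(chain="A", resids={230}, names={"CA"}),
            anchorB_sel=AtomSelection(chain="A", resids={359}, names={"CA"}),
        )
        s1 = interdomain_vector_series(
            traj, body_frame_sel=AtomSelection(chain="A", resid_range=(210, 265)), **common
        )
        s2 = interdomain_vector_series(
            traj, body_frame_sel=AtomSelection(chain="B", resid_range=(210, 240)), **common
        )
        assert np.allclose(s1.d, s2.d, atol=1e-9)
        assert not np.allclose(s1.theta, s2.theta)

    def test_ambiguous_anchor_rejected(self, asymmetric_ensemble):
        traj, _ = asymmetric_ensemble
        with pytest.raises(AmbiguousSelectionError):
            interdomain_vector_series(
                traj,
                AtomSelection(chain="A", names={"CA"}),
                AtomSelection(chain="A", resids={359}, names={"CA"}),
                AtomSelection(chain="A", resid_range=(210, 265)),
            )

    def test_flexible_protomer_wider_distributions(self, asymmetric_ensemble, template):
        traj, truth = asymmetric_ensemble
        series = {}
        for chain in "AB":
            series[chain] = interdomain_vector_series(
                traj,
                AtomSelection(chain=chain, resids={230}, names={"CA"}),
                AtomSelection(chain=chain, resids={359}, names={"CA"}),
                AtomSelection(chain=chain, resid_range=(210, 265), names={"CA"}),
            )
        assert series["B"].theta.std() > 3 * series["A"].theta.std()
        assert series["B"].d.std() > series["A"].d.std()

        # generator-truth oracle: hinge rotation about the pivot fixes the
        # anchorB position; recompute d for protomer B from latent angles
        base = template.coords
        pivot = base[template.pivot_index]
        a_xyz = base[template.anchorA_index]
        b_xyz = base[template.anchorB_index]
        axis = template.hinge_axis
        expected_d = []
        for ang in np.radians(truth.latents["hinge_deg_p2"]):
            c, s = np.cos(ang), np.sin(ang)
            v = b_xyz - pivot
            vrot = (
                v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)
            )
            expected_d.append(np.linalg.norm(vrot + pivot - a_xyz))
        # core jitter perturbs anchors by ~sigma; tolerate a small rms error
        err = np.abs(series["B"].d - np.array(expected_d))
        assert np.sqrt(np.mean(err**2)) < 0.5


def _make_series(d, theta=None, phi=None):
    n = len(d)
    return PolarVectorSeries(
        d=np.asarray(d, float),
        theta=np.full(n, 45.0) if theta is None else np.asarray(theta, float),
        phi=np.full(n, 30.0) if phi is None else np.asarray(phi, float),
        anchorA_id="A", anchorB_id="B", frame_definition="test",
    )


class TestAsymmetryIndex:
    def test_identical_series_zero(self):
        s = _make_series([10.0, 11.0, 12.0, 11.5])
        res = asymmetry_index(s, s)
        assert res.delta_theta == res.delta_phi == res.delta_d == 0.0

    def test_proportional_series_zero(self):
        d = np.array([10.0, 11.0, 12.0, 11.5])
        s1 = _make_series(d, theta=d + 30, phi=d)
        s2 = _make_series(3.7 * d, theta=(d + 30) * 2.0, phi=d * 0.5)
        res = asymmetry_index(s1, s2)
        assert res.delta_d == pytest.approx(0.0, abs=1e-12)
        assert res.delta_theta == pytest.approx(0.0, abs=1e-12)
        assert res.delta_phi == pytest.approx(0.0, abs=1e-12)

    def test_alternating_ten_percent(self):
        n = 100
        base = 50.0
        alternating = base * (1 + 0.1 * np.where(np.arange(n) % 2 == 0, 1, -1))
        s1 = _make_series(np.full(n, base), theta=np.full(n, base), phi=np.full(n, base))
        s2 = _make_series(alternating, theta=alternating, phi=alternating)
        res = asymmetry_index(s1, s2)
        assert res.delta_d == pytest.approx(10.0, abs=1e-9)
        assert res.delta_theta == pytest.approx(10.0, abs=1e-9)
        assert res.delta_phi == pytest.approx(10.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        s1 = _make_series(rng.uniform(8, 12, 50))
        s2 = _make_series(rng.uniform(8, 12, 50))
        r12 = asymmetry_index(s1, s2)
        r21 = asymmetry_index(s2, s1)
        assert r12.delta_d == pytest.approx(r21.delta_d, abs=1e-12)

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        d1 = rng.uniform(8, 12, 60)
        d2 = rng.uniform(8, 12, 60)
        r1 = asymmetry_index(_make_series(d1), _make_series(d2))
        r2 = asymmetry_index(_make_series(5 * d1), _make_series(5 * d2))
        assert r1.delta_d == pytest.approx(r2.delta_d, abs=1e-9)

    def test_phi_unwrapping(self):
        # phi oscillating across the ±180° branch cut must not explode
        phi1 = np.array([179.0, -179.0, 179.0, -179.0])
        phi2 = np.array([178.0, -178.0, 178.0, -178.0])
        s1 = _make_series(np.full(4, 10.0), phi=phi1)
        s2 = _make_series(np.full(4, 10.0), phi=phi2)
        res = asymmetry_index(s1, s2)
        assert res.delta_phi < 2.0

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            asymmetry_index(_make_series([1, 2, 3.0]), _make_series([1, 2.0]))

    def test_zero_mean_component(self):
        s1 = _make_series([10.0, 10.0], theta=[1.0, -1.0])
        s2 = _make_series([10.0, 10.0])
        with pytest.raises(NormalizationError):
            asymmetry_index(s1, s2)

    def test_asymmetric_exceeds_symmetric_across_seeds(self, template):
        wins = 0
        for seed in range(10):
            kw = dict(n_frames=300, core_jitter_sigma=0.05)
            asym_params = EnsembleParams(hinge_sigma_p1=2.0, hinge_sigma_p2=20.0,
                                         seed=seed, **kw)
            sym_params = EnsembleParams(hinge_sigma_p1=2.0, hinge_sigma_p2=2.0,
                                        seed=seed, **kw)
            deltas = {}
            for label, params in (("asym", asym_params), ("sym", sym_params)):
                traj, _ = make_two_protomer_ensemble(template, params)
                series = []
                for chain in "AB":
                    series.append(
                        interdomain_vector_series(
                            traj,
                            AtomSelection(chain=chain, resids={230}, names={"CA"}),
                            AtomSelection(chain=chain, resids={359}, names={"CA"}),
                            AtomSelection(chain=chain, resid_range=(210, 265), names={"CA"}),
                        )
                    )
                deltas[label] = asymmetry_index(series[0], series[1])
            if (
                deltas["asym"].delta_theta > deltas["sym"].delta_theta
                and deltas["asym"].delta_d > deltas["sym"].delta_d
            ):
                wins += 1
        assert wins == 10


def helix(resids, rise=1.5, twist_deg=100.0, radius=2.3, axis_dir=(0, 0, 1.0),
          origin=(0, 0, 0), chain="A", start_serial=1):
    """Parametric ideal alpha-helix CA trace along an arbitrary axis."""
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # build orthonormal frame around the axis
    ref = np.array([1.0, 0, 0]) if abs(axis_dir[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    atoms = []
    for k, resid in enumerate(resids):
        ang = np.radians(twist_deg * k)
        xyz = (
            np.asarray(origin, float)
            + axis_dir * rise * k
            + u * radius * np.cos(ang)
            + v * radius * np.sin(ang)
        )
        atoms.append(make_atom(start_serial + k, "CA", "ALA", chain, resid, tuple(xyz)))
    return atoms


class TestHingeAngles:
    def test_collinear_segments_zero(self):
        atoms = []
        for i in range(30):
            atoms.append(make_atom(i + 1, "CA", "GLY", "A", i + 1, (0.0, 0.0, 1.5 * i)))
        model = StructureModel(atoms)
        res = hinge_angles(model, (1, 10), (11, 20), (21, 30))
        assert res.angle_BC == pytest.approx(0.0, abs=1e-6)
        assert res.angle_CN == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_constructed_segments(self):
        atoms = []
        for i in range(10):  # B along z
            atoms.append(make_atom(i + 1, "CA", "GLY", "A", i + 1, (0.0, 0.0, 1.5 * i)))
        for i in range(10):  # C along x
            atoms.append(make_atom(11 + i, "CA", "GLY", "A", 11 + i, (1.5 * (i + 1), 0.0, 13.5)))
        for i in range(10):  # N along z again
            atoms.append(make_atom(21 + i, "CA", "GLY", "A", 21 + i,
                                   (16.5, 0.0, 13.5 + 1.5 * (i + 1))))
        model = StructureModel(atoms)
        res = hinge_angles(model, (1, 10), (11, 20), (21, 30))
        assert res.angle_BC == pytest.approx(90.0, abs=0.5)
        assert res.angle_CN == pytest.approx(90.0, abs=0.5)

    def test_ideal_helix_30_degree_kink(self):
        seg1 = helix(range(1, 13), axis_dir=(0, 0, 1))
        kinked_dir = (np.sin(np.radians(30)), 0.0, np.cos(np.radians(30)))
        seg2 = helix(range(13, 25), axis_dir=kinked_dir,
                     origin=(0, 0, 18.0), start_serial=13)
        seg3 = helix(range(25, 37), axis_dir=kinked_dir,
                     origin=(np.sin(np.radians(30)) * 18, 0, 18 + np.cos(np.radians(30)) * 18),
                     start_serial=25)
        model = StructureModel(seg1 + seg2 + seg3)
        res = hinge_angles(model, (1, 12), (13, 24), (25, 36))
        assert res.angle_BC == pytest.approx(30.0, abs=2.0)
        assert res.angle_CN == pytest.approx(0.0, abs=2.0)

    def test_overlapping_ranges_rejected(self, ten_residue_model):
        with pytest.raises(ConfigurationError):
            hinge_angles(ten_residue_model, (1, 5), (4, 7), (8, 10))

    def test_too_few_atoms(self, ten_residue_model):
        with pytest.raises(InsufficientDataError):
            hinge_angles(ten_residue_model, (1, 2), (3, 6), (7, 10))
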