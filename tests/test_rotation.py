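import math

import numpy as np
import pytest

from channelrot import rotation as rot
from channelrot.model_io import Ensemble, Frame, SelectionSpec, resolve_selection
from channelrot.synthetic import EnsembleSpec, generate_rotated_ensemble, _rot_z

from conftest import random_rigid_transform, transform_ensemble


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Horn's closed-form quaternion superposition; returns the fitted RMSD.

    Independent of the package's SVD-based Kabsch implementation.
    """
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    S = x.T @ y
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
             S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
             S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
             -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2],
             S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (x**2).sum() + (y**2).sum()
    msd = max((e0 - 2.0 * lam) / len(x), 0.0)
    return math.sqrt(msd)


def atan2_dihedral(p1, p2, p3, p4) -> float:
    """Textbook dihedral via projections onto the plane normal to the axis."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    v1 = p1 - p2 - ((p1 - p2) @ axis) * axis
    v2 = p4 - p3 - ((p4 - p3) @ axis) * axis
    x = v1 @ v2
    y = np.cross(v1, v2) @ axis
    return math.degrees(math.atan2(y, x))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


class TestSuperposition:
    def test_translation_removed(self, toy_start, toy_reference):
        f = toy_start.frames[0]
        moved = Frame(0, 0, f.coords + np.array([10.0, 0.0, 0.0]))
        fitted, rmsd = rot.superimpose_pore(moved, f, toy_reference.pore_selection)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fitted.coords, f.coords, atol=1e-9)

    def test_identity(self, toy_start, toy_reference):
        f = toy_start.frames[0]
        fitted, rmsd = rot.superimpose_pore(f, f, toy_reference.pore_selection)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rmsd_matches_quaternion_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            target = rng.standard_normal((15, 3)) * 5
            mobile = rng.standard_normal((15, 3)) * 5
            ref = Frame(0, 0, target)
            mob = Frame(0, 0, mobile)
            _, rmsd = rot.superimpose_pore(mob, ref, np.arange(15))
            assert rmsd == pytest.approx(
                quaternion_superpose_rmsd(mobile, target), abs=1e-8)

    def test_fit_never_increases_rmsd(self):
        rng = np.random.default_rng(22)
        target = rng.standard_normal((20, 3)) * 4
        mobile = target + rng.standard_normal((20, 3))
        R, t = random_rigid_transform(rng)
        mobile = mobile @ R.T + t
        raw = math.sqrt(np.mean(np.sum((mobile - target) ** 2, axis=1)))
        _, fitted = rot.superimpose_pore(
            Frame(0, 0, mobile), Frame(0, 0, target), np.arange(20))
        assert fitted <= raw + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(rot.GeometryError):
            rot.superimpose_pore(Frame(0, 0, line), Frame(0, 0, line),
                                 np.arange(5))


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------


class TestDihedral:
    def test_zero_azimuthal_displacement(self):
        assert rot.dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [1, 0, 1]) == (
            pytest.approx(0.0))

    def test_quarter_turn_magnitude(self):
        ang = rot.dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [0, 1, 1])
        assert abs(ang) == pytest.approx(90.0)
        assert ang == pytest.approx(atan2_dihedral(
            [1, 0, 0], [0, 0, 0], [0, 0, 1], [0, 1, 1]))

    def test_matches_independent_formula_on_random_quadruples(self):
        """Sign and magnitude agree with an independent atan2 projection
        formula on 10^4 random point quadruples."""
        rng = np.random.default_rng(23)
        pts = rng.standard_normal((10_000, 4, 3)) * 3
        for q in pts:
            try:
                ours = rot.dihedral(*q)
            except rot.GeometryError:
                continue
            assert ours == pytest.approx(atan2_dihedral(*q), abs=1e-8)

    def test_point_on_axis_rejected(self):
        with pytest.raises(rot.GeometryError):
            rot.dihedral([0, 0, 0.5], [0, 0, 0], [0, 0, 1], [1, 0, 0])


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


class TestRotationReference:
    def test_axis_points_on_symmetry_axis(self, toy_reference):
        """C4 symmetry forces points II and III onto the z axis."""
        assert np.abs(toy_reference.point_II[:2]).max() < 1e-10
        assert np.abs(toy_reference.point_III[:2]).max() < 1e-10

    def test_point_I_is_centroid_of_four_elbow_CA(self, toy_start, toy_reference):
        topo = toy_start.topology
        for sub in range(4):
            sel = resolve_selection(
                topo, SelectionSpec(res_ids=(60, 61, 62, 63), subunits=(sub,),
                                    atom_filter="CA"))
            assert len(sel) == 4
            np.testing.assert_allclose(
                toy_reference.points_I[sub],
                toy_start.frames[0].coords[sel].mean(axis=0))

    def test_hand_computed_centroids(self):
        """Points match hand-computed centroids on explicit coordinates."""
        from channelrot.model_io import AtomRecord, Topology

        atoms, coords = [], []
        serial = 0
        for s in range(4):
            ang = math.pi / 2 * s
            for rid, r, z in [(1, 2.0, 0.0), (2, 2.0, 4.0), (3, 6.0, -3.0)]:
                serial += 1
                atoms.append(AtomRecord(serial, "CA", "C", "ALA", rid, s,
                                        False, True))
                coords.append([r * math.cos(ang), r * math.sin(ang), z])
            # extra CA so the pore span is non-collinear per subunit
            serial += 1
            atoms.append(AtomRecord(serial, "CA", "C", "ALA", 4, s, False, True))
            coords.append([3 * math.cos(ang + 0.3), 3 * math.sin(ang + 0.3), 2.0])
        topo = Topology(atoms)
        frame = Frame(0, 0, np.array(coords))
        ens = Ensemble(topology=topo, frames=[frame])
        ref = rot.build_rotation_reference(
            ens, elbow_res=(3,), pore_res_upper=2, pore_res_lower=1,
            pore_span=(1, 2, 4))
        np.testing.assert_allclose(ref.point_II, [0, 0, 4.0], atol=1e-12)
        np.testing.assert_allclose(ref.point_III, [0, 0, 0.0], atol=1e-12)
        np.testing.assert_allclose(ref.points_I[0], [6.0, 0.0, -3.0], atol=1e-12)


# ---------------------------------------------------------------------------
# rotation measurement
# ---------------------------------------------------------------------------


class TestRotationAngle:
    def test_start_structure_measures_zero(self, toy_start, toy_reference):
        f = toy_start.frames[0]
        for sub in range(4):
            assert rot.rotation_angle(f, toy_reference, sub) == pytest.approx(
                0.0, abs=1e-10)

    def test_exact_rotation_recovered(self, toy_start, toy_reference):
        """An exact 5° axial rotation of the CL block reads back as 5.000°
        on every subunit."""
        ens = generate_rotated_ensemble(
            toy_start, EnsembleSpec(n_replicas=1, n_frames=1, rotation_mean=5.0,
                                    rotation_sd=0.0, noise_amplitude=0.0))
        for sub in range(4):
            assert rot.rotation_angle(ens.frames[0], toy_reference, sub) == (
                pytest.approx(5.0, abs=1e-6))

    @pytest.mark.parametrize("theta", [-30.0, -12.5, -1.0, 1.0, 17.0, 30.0])
    def test_axial_rotation_shifts_angle_by_theta(self, toy_start,
                                                  toy_reference, theta):
        ens = generate_rotated_ensemble(
            toy_start, EnsembleSpec(n_replicas=1, n_frames=1,
                                    rotation_mean=theta, rotation_sd=0.0,
                                    noise_amplitude=0.0))
        for sub in range(4):
            assert rot.rotation_angle(ens.frames[0], toy_reference, sub) == (
                pytest.approx(theta, abs=1e-8))

    def test_invariant_under_rigid_body_motion(self, toy_start, toy_reference):
        ens = generate_rotated_ensemble(
            toy_start, EnsembleSpec(n_replicas=1, n_frames=5, rotation_mean=4.0,
                                    rotation_sd=1.0, noise_amplitude=0.05,
                                    seed=31))
        moved = transform_ensemble(ens, per_frame=True, seed=32)
        a = rot.rotation_summary(ens, toy_reference)
        b = rot.rotation_summary(moved, toy_reference)
        np.testing.assert_allclose(
            a.per_frame["angle_deg"], b.per_frame["angle_deg"], atol=1e-8)


class TestRotationSummary:
    def test_static_ensemble_zero(self, toy_start, toy_reference):
        frames = [Frame(0, i, toy_start.frames[0].coords) for i in range(4)]
        ens = Ensemble(topology=toy_start.topology, frames=frames)
        rs = rot.rotation_summary(ens, toy_reference)
        assert rs.mean == pytest.approx(0.0, abs=1e-10)
        assert rs.sem == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_recovery_and_difference(self, toy_start, toy_reference):
        """Ensembles generated around 3.45° and 0.52° recover their means
        within 3 SEM; the difference of grand means is ≈ 2.9°."""
        common = dict(n_replicas=8, n_frames=25, rotation_sd=1.0,
                      noise_amplitude=0.05)
        apo = rot.rotation_summary(
            generate_rotated_ensemble(
                toy_start, EnsembleSpec(rotation_mean=3.45, seed=33, **common)),
            toy_reference)
        mut = rot.rotation_summary(
            generate_rotated_ensemble(
                toy_start, EnsembleSpec(rotation_mean=0.52, seed=34, **common)),
            toy_reference)
        assert abs(apo.mean - 3.45) <= 3 * apo.sem + 1e-9
        assert abs(mut.mean - 0.52) <= 3 * mut.sem + 1e-9
        assert apo.mean - mut.mean == pytest.approx(2.93, abs=0.15)
        assert apo.n == mut.n == 32


class TestAverageStructure:
    def test_single_frame_identity(self, toy_start):
        avg = rot.average_structure(toy_start)
        np.testing.assert_allclose(avg.coords, toy_start.frames[0].coords)

    def test_mirrored_frames_average_to_midpoint(self, toy_start):
        c = toy_start.frames[0].coords
        center = c.mean(axis=0)
        mirrored = 2 * center - c
        ens = Ensemble(topology=toy_start.topology,
                       frames=[Frame(0, 0, c), Frame(0, 1, mirrored)])
        avg = rot.average_structure(ens, align=False)
        np.testing.assert_allclose(avg.coords,
                                   np.tile(center, (len(c), 1)), atol=1e-9)

    def test_noisy_ensemble_converges_to_mean(self, toy_start, toy_reference):
        sigma, n_frames = 0.2, 200
        ens = generate_rotated_ensemble(
            toy_start, EnsembleSpec(n_replicas=1, n_frames=n_frames,
                                    rotation_mean=0.0, rotation_sd=0.0,
                                    noise_amplitude=sigma, seed=35))
        avg = rot.average_structure(ens, toy_reference.pore_selection)
        err = np.linalg.norm(avg.coords - toy_start.frames[0].coords, axis=1)
        # per-coordinate SE is sigma/sqrt(n); allow 6x the 3D displacement SE
        assert np.median(err) < 6 * sigma * math.sqrt(3.0 / n_frames)
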