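import math

import numpy as np
import pytest

from channelrot.interactions import (
    ContactDefinition,
    contact_frequency,
    detect_hbond,
    min_distance,
    salt_bridge_frequency,
)
from channelrot.model_io import Ensemble, Frame, SelectionSpec, SelectionError, resolve_selection
from channelrot.synthetic import generate_contact_trajectory

from conftest import make_minimal_tetramer, transform_ensemble

OPP_DEF = ContactDefinition(
    donor_res_id=64, donor_filter="sidechain-N",
    acceptor_res_id=5, acceptor_filter="backbone-O", role="opposite",
)


def _frame(*points):
    return Frame(0, 0, np.array(points, dtype=float))


class TestDetectHbond:
    def test_collinear_within_cutoff(self):
        f = _frame([0, 0, 0], [1, 0, 0], [2, 0, 0])
        assert detect_hbond(f, 0, [1], 2) is True

    def test_distance_exceeded(self):
        f = _frame([0, 0, 0], [1, 0, 0], [0, 0, 3.6])
        assert detect_hbond(f, 0, [1], 2) is False

    def test_angle_below_cutoff_rejected(self):
        """Acceptor constructed by explicit rotation to a 110° D-H-A angle
        at 2.8 Å donor–acceptor distance; verified with an independent
        arccos evaluation before asserting rejection."""
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        psi = math.radians(110.0)
        # direction from H making angle psi with (d - h) = -x
        v = np.array([-math.cos(psi), math.sin(psi), 0.0])
        # choose |HA| so that |DA| = 2.8 (law of cosines)
        b = -2.0 * math.cos(psi)
        t = (-b + math.sqrt(b * b - 4 * (1 - 2.8**2))) / 2
        a = h + t * v
        # independent check of the construction
        v1, v2 = d - h, a - h
        ang = math.degrees(
            math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert ang == pytest.approx(110.0, abs=1e-9)
        assert np.linalg.norm(a - d) == pytest.approx(2.8, abs=1e-9)
        f = _frame(d, h, a)
        assert detect_hbond(f, 0, [1], 2) is False

    def test_distance_only_mode_ignores_angle(self):
        f = _frame([0, 0, 0], [1, 0, 0], [0, 0, 3.0])
        assert detect_hbond(f, 0, [], 2, distance_only=True) is True

    def test_degenerate_hydrogen_fails_angle(self):
        f = _frame([0, 0, 0], [0, 0, 0], [0, 0, 2.0])
        assert detect_hbond(f, 0, [1], 2) is False


class TestContactFrequency:
    def test_scripted_seven_of_ten(self, toy_start):
        """A pair in contact geometry in 7 of 10 frames scores 0.70."""
        base = toy_start.frames[0].coords
        ens = generate_contact_trajectory(toy_start, p=0.5, n_frames=10, seed=3)
        # overwrite with a deterministic script: bonded frames 0..6
        for f_idx, frame in enumerate(ens.frames):
            frame.coords = base.copy()
            if f_idx >= 7:  # move every site residue out of contact
                topo = ens.topology
                for j in range(4):
                    site = np.flatnonzero(
                        (topo.res_ids == 5) & (topo.subunits == j))
                    frame.coords[site] += np.array([0.0, 0.0, 50.0])
        res = contact_frequency(ens, OPP_DEF)
        assert res.per_pair_per_replica["frequency"].to_numpy() == pytest.approx(
            [0.7] * 4)
        assert res.mean == pytest.approx(0.7)

    @pytest.mark.parametrize("p,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_bounds(self, toy_start, p, expected):
        ens = generate_contact_trajectory(toy_start, p=p, n_frames=20, seed=4)
        res = contact_frequency(ens, OPP_DEF)
        assert res.mean == expected
        assert res.n == 4

    def test_matches_bernoulli_draws_exactly(self, toy_start):
        """Measured frequencies equal the generator's recorded draws."""
        ens = generate_contact_trajectory(toy_start, p=0.4, n_frames=100,
                                          seed=5, n_replicas=2)
        res = contact_frequency(ens, OPP_DEF)
        truth = ens.truth["bonded"]  # (replica, frame, donor_subunit)
        for _, row in res.per_pair_per_replica.iterrows():
            expect = truth[int(row.replica), :, int(row.donor_subunit)].mean()
            assert row.frequency == pytest.approx(expect)

    def test_brute_force_oracle_random_frames(self):
        """Exact agreement with an exhaustive all-pairs detector on random
        ~40-atom frames."""
        topo, base = make_minimal_tetramer()
        rng = np.random.default_rng(12)
        frames = [
            Frame(0, i, rng.uniform(0, 9, size=base.shape)) for i in range(100)
        ]
        ens = Ensemble(topology=topo, frames=frames)
        cdef = ContactDefinition(
            donor_res_id=9, donor_filter="sidechain-N",
            acceptor_res_id=2, acceptor_filter="backbone-O", role="opposite",
            distance_cutoff=3.5, angle_cutoff=120.0,
        )
        res = contact_frequency(ens, cdef)

        # independent brute force, plain python math
        def brute(frame, donor_sub, acc_sub):
            nz = [i for i, a in enumerate(topo.atoms)
                  if a.name == "NZ" and a.subunit == donor_sub]
            hz = [i for i, a in enumerate(topo.atoms)
                  if a.name.startswith("HZ") and a.subunit == donor_sub]
            o = [i for i, a in enumerate(topo.atoms)
                 if a.name == "O" and a.res_id == 2 and a.subunit == acc_sub]
            c = frame.coords
            for d in nz:
                for acc in o:
                    dd = math.dist(c[d], c[acc])
                    if dd > 3.5:
                        continue
                    for h in hz:
                        v1 = c[d] - c[h]
                        v2 = c[acc] - c[h]
                        cosang = (v1 @ v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2))
                        if math.degrees(math.acos(max(-1, min(1, cosang)))) >= 120:
                            return True
            return False

        for _, row in res.per_pair_per_replica.iterrows():
            expect = np.mean(
                [brute(f, int(row.donor_subunit), int(row.acceptor_subunit))
                 for f in frames]
            )
            assert row.frequency == pytest.approx(expect)

    def test_rigid_body_invariance(self, toy_start):
        ens = generate_contact_trajectory(toy_start, p=0.5, n_frames=30, seed=6)
        moved = transform_ensemble(ens, per_frame=True, seed=7)
        a = contact_frequency(ens, OPP_DEF).per_pair_per_replica["frequency"]
        b = contact_frequency(moved, OPP_DEF).per_pair_per_replica["frequency"]
        np.testing.assert_allclose(a, b)

    def test_monotone_in_cutoffs(self, toy_start):
        ens = generate_contact_trajectory(toy_start, p=0.5, n_frames=50, seed=8)
        base = contact_frequency(ens, OPP_DEF).mean
        looser_d = contact_frequency(
            ens, ContactDefinition(64, "sidechain-N", 5, "backbone-O",
                                   distance_cutoff=7.0)).mean
        stricter_a = contact_frequency(
            ens, ContactDefinition(64, "sidechain-N", 5, "backbone-O",
                                   angle_cutoff=175.0)).mean
        assert looser_d >= base >= stricter_a


class TestMinDistance:
    def test_identical_selection_zero(self, toy_start):
        f = toy_start.frames[0]
        assert min_distance(f, np.array([3]), np.array([3])) == 0.0

    def test_two_point_distance(self):
        f = _frame([0, 0, 0], [0, 0, 5.2])
        assert min_distance(f, np.array([0]), np.array([1])) == pytest.approx(5.2)

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-10, 10, (30, 3))
        f = Frame(0, 0, coords)
        a, b = np.arange(0, 12), np.arange(12, 30)
        expect = min(math.dist(coords[i], coords[j]) for i in a for j in b)
        assert min_distance(f, a, b) == pytest.approx(expect)

    def test_empty_selection_raises(self, toy_start):
        with pytest.raises(SelectionError):
            min_distance(toy_start.frames[0], np.array([]), np.array([1]))


class TestSaltBridge:
    def test_wrong_chemistry_rejected(self, toy_start):
        with pytest.raises(ValueError, match="acidic"):
            salt_bridge_frequency(toy_start, basic_res_id=64, acidic_res_id=36)
        with pytest.raises(ValueError, match="basic"):
            salt_bridge_frequency(toy_start, basic_res_id=36, acidic_res_id=36)

    def test_held_contact_and_broken_contact(self):
        """K/E pair at N–O 2.9 Å with a 160° hydrogen scores 1.0; the same
        pair at 4.0 Å scores 0.0."""
        from channelrot.model_io import AtomRecord, Topology

        atoms, coords = [], []
        serial = 0
        for s in range(4):
            off = np.array([40.0 * s, 0.0, 0.0])
            psi = math.radians(160.0)
            b = -2.0 * math.cos(psi)
            t = (-b + math.sqrt(b * b - 4 * (1 - 2.9**2))) / 2
            oe = np.array([1.0 - t * math.cos(psi), t * math.sin(psi), 0.0])
            for name, elem, rn, rid, xyz in [
                ("NZ", "N", "LYS", 464, [0.0, 0.0, 0.0]),
                ("HZ1", "H", "LYS", 464, [1.0, 0.0, 0.0]),
                ("CA", "C", "LYS", 464, [-1.5, 0.0, 0.0]),
            ]:
                serial += 1
                atoms.append(AtomRecord(serial, name, elem, rn, rid, s,
                                        elem == "H", name == "CA"))
                coords.append(off + np.array(xyz))
            serial += 1
            # acceptor owned by the opposite subunit bookkeeping-wise is
            # irrelevant here: place one Glu OE1 per subunit at the scripted
            # geometry relative to the *previous* subunit's donor
            atoms.append(AtomRecord(serial, "OE1", "O", "GLU", 243, s,
                                    False, False))
            coords.append(np.array([40.0 * ((s + 2) % 4), 0.0, 0.0]) + oe)
        topo = Topology(atoms)
        frames = [Frame(0, i, np.array(coords)) for i in range(5)]
        ens = Ensemble(topology=topo, frames=frames)
        res = salt_bridge_frequency(ens, basic_res_id=464, acidic_res_id=243)
        assert res.mean == 1.0
        far = [c + np.array([0.0, 0.0, 50.0]) if topo.atoms[i].name == "OE1"
               else c for i, c in enumerate(coords)]
        ens2 = Ensemble(topology=topo,
                        frames=[Frame(0, i, np.array(far)) for i in range(5)])
        assert salt_bridge_frequency(ens2, 464, 243).mean == 0.0

    def test_bernoulli_occupancy_within_binomial_error(self, toy_start):
        """Scripted occupancy p=0.25 over 200 frames recovers within the
        binomial 99% interval (donor here is the toy lysine)."""
        ens = generate_contact_trajectory(toy_start, p=0.25, n_frames=200,
                                          seed=9)
        res = contact_frequency(ens, OPP_DEF)
        n_draws = 200 * 4
        ci = 2.576 * math.sqrt(0.25 * 0.75 / n_draws)
        assert abs(res.per_pair_per_replica["frequency"].mean() - 0.25) <= ci
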