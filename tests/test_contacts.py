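import logging

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import oligotraj as ot
from oligotraj.contacts import HBParams, detect_hbonds, residue_pair_energy
from oligotraj.core import AtomRecord, Frame, Trajectory


def _atom(name, resname, resid, chain, **kw):
    return AtomRecord(
        atom_name=name, residue_name=resname, residue_index=resid, chain_id=chain, **kw
    )


def _two_cb_residues(distance):
    """Two alanines on different chains whose CB atoms sit ``distance`` apart."""
    topo = [_atom("CB", "ALA", 1, "A"), _atom("CB", "ALA", 1, "B")]
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return topo, Frame(0.0, coords)


class TestSidechainContact:
    @pytest.mark.parametrize("distance,expected", [(6.0, True), (7.0, False), (6.5, True)])
    def test_cutoff_is_boundary_inclusive(self, distance, expected):
        topo, frame = _two_cb_residues(distance)
        assert ot.sc_contact(frame, topo, ("A", 1), ("B", 1)) is expected

    def test_symmetry(self):
        topo, frame = _two_cb_residues(5.0)
        assert ot.sc_contact(frame, topo, ("A", 1), ("B", 1)) == ot.sc_contact(
            frame, topo, ("B", 1), ("A", 1)
        )

    def test_missing_residue_raises(self):
        topo, frame = _two_cb_residues(5.0)
        with pytest.raises(KeyError):
            ot.sc_contact(frame, topo, ("A", 1), ("C", 9))

    def test_mass_weighting_of_center(self):
        # heavy CG pulls the center toward itself
        topo = [
            _atom("CB", "LEU", 1, "A", mass=12.011),
            _atom("SD", "MET", 1, "A", mass=32.06),
            _atom("CB", "ALA", 1, "B"),
        ]
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [8.0, 0, 0]])
        frame = Frame(0.0, coords)
        com_x = (0.0 * 12.011 + 2.0 * 32.06) / (12.011 + 32.06)
        expected = (8.0 - com_x) <= 6.5
        assert ot.sc_contact(frame, topo, ("A", 1), ("B", 1)) is expected


def _nh_o_frame(d_no, angle_deg=180.0):
    """Donor N-H on chain A, acceptor O on chain B.

    The hydrogen sits 1 A from N along +x; the acceptor is placed so the
    D-H-A angle is ``angle_deg`` and the N...O distance is ``d_no``.
    """
    topo = [
        _atom("N", "ALA", 1, "A"),
        _atom("H", "ALA", 1, "A"),
        _atom("O", "ALA", 1, "B"),
    ]
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # direction from H making the requested angle with H->N = (-1, 0, 0)
    theta = np.radians(angle_deg)
    direction = np.array([-np.cos(theta), np.sin(theta), 0.0])
    # choose the H->O distance giving the requested N...O distance
    lo, hi = 0.0, d_no + 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.linalg.norm(h + mid * direction - n) < d_no:
            lo = mid
        else:
            hi = mid
    o = h + 0.5 * (lo + hi) * direction
    return topo, Frame(0.0, np.vstack([n, h, o]))


class TestHydrogenBonds:
    def test_ideal_collinear_bond(self):
        topo, frame = _nh_o_frame(2.9, 180.0)
        assert len(detect_hbonds(frame, topo)) == 1

    def test_beyond_distance_cutoff(self):
        topo, frame = _nh_o_frame(3.6, 180.0)
        assert detect_hbonds(frame, topo) == []

    def test_below_angle_threshold(self):
        topo, frame = _nh_o_frame(3.0, 120.0)
        assert detect_hbonds(frame, topo) == []

    def test_angle_right_at_threshold_passes(self):
        topo, frame = _nh_o_frame(3.0, 140.0)
        assert len(detect_hbonds(frame, topo)) == 1

    def test_donor_without_hydrogen_is_skipped_with_warning(self, caplog):
        topo = [_atom("N", "ALA", 1, "A"), _atom("O", "ALA", 1, "B")]
        frame = Frame(0.0, np.array([[0.0, 0, 0], [2.9, 0, 0]]))
        logging.getLogger("oligotraj.contacts").setLevel(logging.WARNING)
        with caplog.at_level(logging.WARNING, logger="oligotraj.contacts"):
            assert detect_hbonds(frame, topo) == []
        assert "no attached hydrogen" in caplog.text

    def test_invariance_under_rigid_motion(self, ordered_dimer):
        frame = ordered_dimer.frames[0]
        bonds = set(detect_hbonds(frame, ordered_dimer.topology))
        rng = np.random.default_rng(14)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = Frame(0.0, frame.coords @ rot.T + np.array([3.0, -7.0, 11.0]))
        assert set(detect_hbonds(moved, ordered_dimer.topology)) == bonds


class TestBackboneHBCount:
    def test_ordered_frame_has_at_least_two(self, ordered_dimer):
        count = ot.backbone_hb_count(ordered_dimer.frames[0], ordered_dimer.topology)
        assert count >= 2

    def test_separated_chains_have_none(self, scripted_dimer):
        _, traj = scripted_dimer
        assert ot.backbone_hb_count(traj.frames[0], traj.topology) == 0


class TestContactProbabilityMap:
    def test_always_in_contact_gives_one(self, ordered_dimer):
        cmap = ot.contact_probability_map(ordered_dimer, kind="sidechain")
        # antiparallel registry: residue i of A faces residue n+1-i of B
        n = 7
        for i in range(n):
            assert cmap.values[i, n - 1 - i] == pytest.approx(1.0)

    def test_half_frames_in_contact(self):
        topo = [_atom("CB", "ALA", 1, "A"), _atom("CB", "ALA", 1, "B")]
        frames = [
            Frame(float(t), np.array([[0.0, 0, 0], [5.0 if t % 2 == 0 else 8.0, 0, 0]]))
            for t in range(100)
        ]
        traj = Trajectory(topo, frames)
        cmap = ot.contact_probability_map(traj, kind="sidechain")
        assert cmap.values[0, 0] == pytest.approx(0.5)

    def test_map_shape_and_range(self, ordered_dimer):
        cmap = ot.contact_probability_map(ordered_dimer, kind="hbond")
        assert cmap.values.shape == (7, 7)
        assert np.all(cmap.values >= 0) and np.all(cmap.values <= 1)

    def test_equilibration_cut_requires_frames(self, ordered_dimer):
        with pytest.raises(ValueError, match="equilibration"):
            ot.contact_probability_map(ordered_dimer, equilibration_cut=1e6)


class TestResiduePairEnergy:
    def test_coulomb_constant_arithmetic(self):
        topo = [
            _atom("CB", "ALA", 1, "A", charge=1.0, lj_sigma=1.0, lj_epsilon=0.0),
            _atom("CB", "ALA", 1, "B", charge=-1.0, lj_sigma=1.0, lj_epsilon=0.0),
        ]
        frame = Frame(0.0, np.array([[0.0, 0, 0], [3.320636, 0, 0]]))
        e = residue_pair_energy(frame, topo, ("A", 1), ("B", 1))
        assert e == pytest.approx(-100.0, abs=1e-6)

    @pytest.mark.parametrize(
        "r_over_sigma,expected_over_eps", [(1.0, 0.0), (2 ** (1 / 6), -1.0)]
    )
    def test_lj_landmarks(self, r_over_sigma, expected_over_eps):
        sigma, eps = 3.4, 0.25
        topo = [
            _atom("CB", "ALA", 1, "A", charge=0.0, lj_sigma=sigma, lj_epsilon=eps),
            _atom("CB", "ALA", 1, "B", charge=0.0, lj_sigma=sigma, lj_epsilon=eps),
        ]
        frame = Frame(0.0, np.array([[0.0, 0, 0], [r_over_sigma * sigma, 0, 0]]))
        e = residue_pair_energy(frame, topo, ("A", 1), ("B", 1))
        assert e == pytest.approx(expected_over_eps * eps, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(15)
        topo = [
            _atom("CB", "ALA", 1, "A", charge=0.4, lj_sigma=3.2, lj_epsilon=0.2),
            _atom("CG", "LEU", 1, "A", charge=-0.1, lj_sigma=3.6, lj_epsilon=0.12),
            _atom("CB", "ALA", 1, "B", charge=-0.3, lj_sigma=3.0, lj_epsilon=0.3),
        ]
        frame = Frame(0.0, rng.uniform(0, 8, (3, 3)))
        a = residue_pair_energy(frame, topo, ("A", 1), ("B", 1))
        b = residue_pair_energy(frame, topo, ("B", 1), ("A", 1))
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_parameters_named(self):
        topo = [
            _atom("CB", "ALA", 1, "A", charge=0.4, lj_sigma=3.2, lj_epsilon=0.2),
            _atom("CB", "ALA", 1, "B"),
        ]
        frame = Frame(0.0, np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        with pytest.raises(ValueError, match="CB B:1"):
            residue_pair_energy(frame, topo, ("A", 1), ("B", 1))
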