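"""Geometric observables: distances, radius of gyration, kappa^2, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fretloop.synthetic import gen_bead_chain, gen_random_dipoles, write_frames_pdb
from fretloop.trajectory import (DistanceTrace, Frame, LabelMap,
                                 ca_ca_distance, end_to_end_distance,
                                 extract_traces, kappa_squared,
                                 radius_of_gyration, read_trace,
                                 read_trajectory, write_trace)


def make_frame(coords):
    return Frame(np.asarray(coords, dtype=float), time=0.0)


class TestDistances:
    def test_end_to_end_midpoint_geometry(self, simple_labels):
        coords = np.zeros((10, 3))
        coords[0] = (0, 0, 0)
        coords[1] = (0, 0, 0.2)
        coords[8] = (0, 0, 1.0)
        coords[9] = (0, 0, 1.2)
        assert end_to_end_distance(make_frame(coords), simple_labels) == pytest.approx(1.0)

    def test_coincident_midpoints_zero(self, simple_labels):
        coords = np.zeros((10, 3))
        coords[1] = (0, 0, 0.4)
        coords[8] = (0, 0, 0.4)  # midpoints both at (0,0,0.2)
        coords[9] = (0, 0, 0.0)
        assert end_to_end_distance(make_frame(coords), simple_labels) == pytest.approx(0.0)

    def test_matches_bruteforce_arithmetic(self, random_frame, simple_labels):
        c = random_frame.coordinates
        mid_d = (c[0] + c[1]) / 2
        mid_a = (c[8] + c[9]) / 2
        expected = np.sqrt(((mid_d - mid_a) ** 2).sum())
        assert end_to_end_distance(random_frame, simple_labels) == pytest.approx(
            expected, abs=1e-12)
        expected_ca = np.sqrt(((c[0] - c[9]) ** 2).sum())
        assert ca_ca_distance(random_frame, simple_labels) == pytest.approx(
            expected_ca, abs=1e-12)

    def test_ca_ca_hand_value(self, simple_labels):
        coords = np.zeros((10, 3))
        coords[9] = (0.38, 0, 0)
        assert ca_ca_distance(make_frame(coords), simple_labels) == pytest.approx(0.38)

    def test_degenerate_label_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            LabelMap((0, 0), (2, 3), (0, 1), (2, 3), (0, 3))

    def test_out_of_range_index_rejected(self, simple_labels):
        frame = make_frame(np.zeros((5, 3)))
        with pytest.raises(IndexError):
            end_to_end_distance(frame, simple_labels)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        labels = LabelMap((0, 1), (0, 2), (0, 1), (1, 2), (0, 2),
                          heavy_atoms=(0, 1), masses=np.ones(3))
        coords = np.zeros((3, 3))
        coords[1] = (1.0, 0, 0)
        assert radius_of_gyration(make_frame(coords), labels) == pytest.approx(0.5)

    def test_matches_direct_sum(self, random_frame, simple_labels, rng):
        masses = rng.uniform(1, 16, 10)
        labels = LabelMap((0, 1), (8, 9), (0, 1), (8, 9), (0, 9),
                          heavy_atoms=tuple(range(10)), masses=masses)
        c = random_frame.coordinates
        com = (masses[:, None] * c).sum(0) / masses.sum()
        expected = np.sqrt((masses * ((c - com) ** 2).sum(1)).sum() / masses.sum())
        assert radius_of_gyration(random_frame, labels) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_mass_rejected(self):
        labels = LabelMap((0, 1), (1, 2), (0, 1), (1, 2), (0, 2),
                          heavy_atoms=(0, 1, 2), masses=np.zeros(3))
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(make_frame(np.zeros((3, 3))), labels)


class TestKappaSquared:
    @pytest.mark.parametrize("donor,acceptor,ree,expected", [
        ((0, 0, 1), (0, 0, 1), (0, 0, 1), 4.0),   # collinear maximum
        ((1, 0, 0), (1, 0, 0), (0, 0, 1), 1.0),   # parallel, perpendicular to ree
        ((1, 0, 0), (0, 1, 0), (0, 0, 1), 0.0),   # mutually orthogonal
    ])
    def test_reference_geometries(self, donor, acceptor, ree, expected):
        assert kappa_squared(donor, acceptor, ree) == pytest.approx(expected)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            kappa_squared((0, 0, 2), (0, 0, 1), (0, 0, 1))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_and_dipole_inversion_evenness(self, seed):
        d = gen_random_dipoles(8, seed=seed)
        k2 = kappa_squared(d.donor_unit, d.acceptor_unit, d.ree_unit)
        assert np.all(k2 >= 0) and np.all(k2 <= 4 + 1e-12)
        flipped = kappa_squared(-d.donor_unit, d.acceptor_unit, d.ree_unit)
        np.testing.assert_allclose(k2, flipped, atol=1e-12)

    def test_isotropic_average_is_two_thirds(self):
        d = gen_random_dipoles(10 ** 6, seed=42)
        mean = np.mean(kappa_squared(d.donor_unit, d.acceptor_unit, d.ree_unit))
        assert mean == pytest.approx(2.0 / 3.0, abs=0.002)


class TestRigidMotionInvariance:
    def test_scalars_invariant_under_rotation_translation(self, random_frame,
                                                          simple_labels):
        rot = Rotation.from_euler("zyx", [0.7, -1.2, 0.4]).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        moved = Frame(random_frame.coordinates @ rot.T + shift, 0.0)
        for op in (end_to_end_distance, ca_ca_distance, radius_of_gyration):
            assert op(moved, simple_labels) == pytest.approx(
                op(random_frame, simple_labels), abs=1e-10)


class TestExtractTraces:
    def test_consistent_with_per_frame_calls(self):
        frames, labels = gen_bead_chain(n_beads=10, n_frames=20, seed=5)
        ree, rca, rg, dipoles = extract_traces(frames, labels)
        assert len(ree) == len(rca) == len(rg) == len(dipoles) == 20
        for i in (0, 7, 19):
            assert ree.values[i] == pytest.approx(
                end_to_end_distance(frames[i], labels), abs=1e-12)
            assert rca.values[i] == pytest.approx(
                ca_ca_distance(frames[i], labels), abs=1e-12)
            assert rg.values[i] == pytest.approx(
                radius_of_gyration(frames[i], labels), abs=1e-12)

    def test_constant_coordinates_give_constant_traces(self, simple_labels, rng):
        coords = rng.normal(size=(10, 3))
        frames = [Frame(coords.copy(), float(t)) for t in range(5)]
        ree, rca, rg, _ = extract_traces(frames, simple_labels)
        for trace in (ree, rca, rg):
            assert np.ptp(trace.values) == 0

    def test_needs_two_frames(self, random_frame, simple_labels):
        with pytest.raises(ValueError):
            extract_traces([random_frame], simple_labels)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        trace = DistanceTrace(np.arange(5) * 2.0, [1.0, 1.1, 0.9, 1.2, 1.0], "x")
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.times, trace.times)
        np.testing.assert_allclose(back.values, trace.values)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            DistanceTrace([0.0, 1.0, 3.0], [1.0, 1.0, 1.0])

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            DistanceTrace([0.0, 1.0, 2.0], [1.0, np.nan, 1.0])


class TestReadTrajectory:
    def test_round_trip_of_synthetic_frames(self, tmp_path):
        frames, _ = gen_bead_chain(n_beads=6, n_frames=3, dt=2.0, seed=0)
        path = tmp_path / "chain.pdb"
        write_frames_pdb(frames, str(path))
        back = read_trajectory(path, path, dt=2.0)
        assert len(back) == 3
        assert [f.time for f in back] == [0.0, 2.0, 4.0]
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm round-off
        np.testing.assert_allclose(back[1].coordinates, frames[1].coordinates,
                                   atol=1e-4)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_trajectory(tmp_path / "nope.xtc", tmp_path / "nope.gro")

    def test_empty_trajectory_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(Exception):
            read_trajectory(path, path)
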