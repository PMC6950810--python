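"""Contact occupancy, distance series and running averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from domainmotion.contacts_distances import (
    contact_occupancy,
    elbow_distance,
    residue_distance,
    running_average,
)
from domainmotion.exceptions import SelectionError
from domainmotion.model_io import Selection

from conftest import make_structure, make_trajectory


def _two_atom_trajectory(separations):
    structure = make_structure([[0.0, 0, 0], [1.0, 0, 0]], residues=[1, 2])
    frames = np.zeros((len(separations), 2, 3))
    frames[:, 1, 0] = separations
    return make_trajectory(frames, structure), structure


def test_occupancy_below_cutoff_every_frame():
    traj, _ = _two_atom_trajectory([4.0] * 5)
    series = contact_occupancy(
        traj, Selection(np.array([0])), Selection(np.array([1]))
    )
    assert series.occupancy == 1.0


def test_occupancy_above_cutoff_every_frame():
    traj, _ = _two_atom_trajectory([6.0] * 5)
    series = contact_occupancy(
        traj, Selection(np.array([0])), Selection(np.array([1]))
    )
    assert series.occupancy == 0.0


def test_occupancy_three_of_ten_frames():
    separations = [6.0, 4.9, 6.2, 4.0, 7.0, 6.5, 3.0, 8.0, 6.1, 9.0]
    traj, _ = _two_atom_trajectory(separations)
    series = contact_occupancy(
        traj, Selection(np.array([0])), Selection(np.array([1]))
    )
    assert series.occupancy == pytest.approx(0.3)
    assert series.per_frame.sum() == 3


def test_tie_at_cutoff_is_not_a_contact():
    traj, _ = _two_atom_trajectory([5.0] * 3)
    series = contact_occupancy(
        traj, Selection(np.array([0])), Selection(np.array([1])), cutoff=5.0
    )
    assert series.occupancy == 0.0


def test_hydrogens_excluded_by_default():
    structure = make_structure(
        [[0.0, 0, 0], [4.0, 0, 0], [20.0, 0, 0]],
        elements=["C", "H", "C"],
        residues=[1, 1, 2],
    )
    traj = make_trajectory(structure.coordinates[None].repeat(2, axis=0), structure)
    series = contact_occupancy(
        traj, Selection(np.array([0, 1])), Selection(np.array([2]))
    )
    assert series.occupancy == 0.0  # only the H is within 5 Å of nothing
    with pytest.raises(SelectionError):
        contact_occupancy(traj, Selection(np.array([1])), Selection(np.array([2])))


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_occupancy_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b, n_frames = 6, 8, 7
    structure = make_structure(
        rng.normal(scale=4.0, size=(n_a + n_b, 3)),
        residues=[1] * n_a + [2] * n_b,
    )
    frames = rng.normal(scale=4.0, size=(n_frames, n_a + n_b, 3))
    traj = make_trajectory(frames, structure)
    sel_a = Selection(np.arange(n_a))
    sel_b = Selection(np.arange(n_a, n_a + n_b))
    series = contact_occupancy(traj, sel_a, sel_b, cutoff=5.0)
    # brute-force double loop
    expected = []
    for f in range(n_frames):
        best = min(
            np.linalg.norm(frames[f, i] - frames[f, j])
            for i in range(n_a)
            for j in range(n_a, n_a + n_b)
        )
        expected.append(best < 5.0)
    assert list(series.per_frame) == expected
    assert series.occupancy == np.mean(expected)


def test_cutoff_limits():
    separations = [2.0, 6.0, 11.0]
    traj, _ = _two_atom_trajectory(separations)
    a, b = Selection(np.array([0])), Selection(np.array([1]))
    assert contact_occupancy(traj, a, b, cutoff=1e6).occupancy == 1.0
    assert contact_occupancy(traj, a, b, cutoff=1e-9).occupancy == 0.0


def test_residue_distance_345_triangle():
    structure = make_structure(
        [[0.0, 0, 0], [3.0, 4.0, 0.0]], names=["CA", "CA"], residues=[1, 2]
    )
    series = residue_distance(structure, ("A", 1, "CA"), ("A", 2, "CA"))
    assert series.values[0] == pytest.approx(5.0)


def test_residue_distance_coincident_atoms():
    structure = make_structure(
        [[1.0, 1, 1], [1.0, 1, 1]], names=["CA", "CA"], residues=[1, 2]
    )
    series = residue_distance(structure, ("A", 1, "CA"), ("A", 2, "CA"))
    assert series.values[0] == 0.0


def test_missing_atom_error_lists_available_names():
    structure = make_structure(
        [[0.0, 0, 0], [1.0, 0, 0]], names=["N", "CA"], residues=[1, 1]
    )
    with pytest.raises(SelectionError, match="CA"):
        residue_distance(structure, ("A", 1, "CB"), ("A", 1, "CA"))


def test_distance_invariant_under_rigid_motion():
    rng = np.random.default_rng(6)
    structure = make_structure(
        rng.normal(size=(4, 3)), names=["CA"] * 4, residues=[1, 2, 3, 4]
    )
    frames = rng.normal(size=(10, 4, 3))
    traj = make_trajectory(frames, structure)
    base = residue_distance(traj, ("A", 1, "CA"), ("A", 3, "CA"))
    rot = Rotation.from_rotvec([1.0, 0.2, -0.3]).as_matrix()
    traj2 = make_trajectory(frames @ rot.T + np.array([5, 6, 7.0]), structure)
    moved = residue_distance(traj2, ("A", 1, "CA"), ("A", 3, "CA"))
    assert np.allclose(base.values, moved.values, atol=1e-9)


def _pseudo_trna_pair(separations):
    structure = make_structure(
        [[0.0, 0, 0], [50.0, 0, 0]],
        names=["O3'", "O3'"],
        residues=[60, 8],
        residue_names=["U", "U"],
    )
    frames = np.zeros((len(separations), 2, 3))
    frames[:, 1, 0] = separations
    return make_trajectory(frames, structure)


def test_elbow_distance_fixture_50A():
    traj = _pseudo_trna_pair([50.0])
    series = elbow_distance(traj, ("A", 60), ("A", 8))
    assert series.label == "R_elbow"
    assert series.values[0] == pytest.approx(50.0)


def test_elbow_distance_accommodation_ramp():
    separations = np.linspace(50.0, 30.0, 11)
    traj = _pseudo_trna_pair(separations)
    series = elbow_distance(traj, ("A", 60), ("A", 8))
    assert series.values[0] == pytest.approx(50.0)
    assert series.values[-1] == pytest.approx(30.0)
    assert np.all(np.diff(series.values) < 0)


def test_elbow_distance_unicode_prime_dialect():
    structure = make_structure(
        [[0.0, 0, 0], [0.0, 0, 0]],
        names=["O3′", "O3′"],
        residues=[60, 8],
        residue_names=["U", "U"],
    )
    series = elbow_distance(structure, ("A", 60), ("A", 8))
    assert series.values[0] == 0.0


def test_running_average_window_one_is_identity():
    values = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    assert np.array_equal(running_average(values, 1), values)


def test_running_average_constant_series_unchanged():
    values = np.full(7, 2.5)
    assert np.allclose(running_average(values, 5), values)


def test_running_average_truncated_edges_hand_computed():
    values = np.array([0.0, 10.0, 0.0, 10.0, 0.0])
    expected = np.array([5.0, 10.0 / 3.0, 20.0 / 3.0, 10.0 / 3.0, 5.0])
    assert np.allclose(running_average(values, 3), expected)


def test_running_average_validation():
    values = np.arange(4.0)
    with pytest.raises(ValueError):
        running_average(values, 2)  # even
    with pytest.raises(ValueError):
        running_average(values, 5)  # longer than series
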