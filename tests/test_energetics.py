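"""Nonbonded interaction enthalpies and correlation summaries."""

import numpy as np
import pytest

from domainmotion.constants import COULOMB_CONSTANT_KJ_NM_E2
from domainmotion.energetics import (
    NonbondedParams,
    correlation_summary,
    enthalpy_distance_correlation,
    interaction_enthalpy,
)
from domainmotion.exceptions import ParameterError, SelectionError
from domainmotion.model_io import Selection

from conftest import make_structure, make_trajectory


def _pair_trajectory(separations_A, charges, sigmas=(0.0, 0.0), epsilons=(0.0, 0.0)):
    structure = make_structure(
        [[0.0, 0, 0], [1.0, 0, 0]],
        residues=[1, 2],
        charges=list(charges),
        sigmas=list(sigmas),
        epsilons=list(epsilons),
    )
    frames = np.zeros((len(separations_A), 2, 3))
    frames[:, 1, 0] = separations_A
    traj = make_trajectory(frames, structure)
    return traj, Selection(np.array([0]), "A"), Selection(np.array([1]), "B")


def test_unit_charges_at_point_one_nm():
    traj, a, b = _pair_trajectory([1.0], charges=(1.0, -1.0))  # 1 Å = 0.1 nm
    series = interaction_enthalpy(traj, a, b)
    assert series.coulomb[0] == pytest.approx(-1389.35458, abs=1e-6)
    assert series.lennard_jones[0] == 0.0
    assert series.coulomb[0] == pytest.approx(
        COULOMB_CONSTANT_KJ_NM_E2 * 1.0 * -1.0 / 0.1, abs=1e-9
    )


def test_pair_beyond_cutoff_contributes_nothing():
    traj, a, b = _pair_trajectory(
        [12.0], charges=(1.0, -1.0), sigmas=(3.0, 3.0), epsilons=(0.5, 0.5)
    )
    series = interaction_enthalpy(traj, a, b, NonbondedParams(cutoff=10.0))
    assert series.coulomb[0] == 0.0
    assert series.lennard_jones[0] == 0.0


def test_lj_zero_crossing_and_minimum():
    sigma = 3.0
    epsilon = 0.4
    traj, a, b = _pair_trajectory(
        [sigma, 2 ** (1 / 6) * sigma],
        charges=(0.0, 0.0),
        sigmas=(sigma, sigma),
        epsilons=(epsilon, epsilon),
    )
    series = interaction_enthalpy(traj, a, b)
    assert series.lennard_jones[0] == pytest.approx(0.0, abs=1e-12)
    assert series.lennard_jones[1] == pytest.approx(-epsilon, rel=1e-12)


def test_lorentz_berthelot_combination():
    # unequal atoms: sigma = (2+4)/2 = 3, eps = sqrt(0.2*0.8) = 0.4
    traj, a, b = _pair_trajectory(
        [2 ** (1 / 6) * 3.0], charges=(0.0, 0.0), sigmas=(2.0, 4.0),
        epsilons=(0.2, 0.8),
    )
    series = interaction_enthalpy(traj, a, b)
    assert series.lennard_jones[0] == pytest.approx(-0.4, rel=1e-12)


def test_symmetry_under_group_swap():
    rng = np.random.default_rng(0)
    n = 8
    structure = make_structure(
        rng.normal(scale=4.0, size=(n, 3)),
        residues=list(range(1, n + 1)),
        charges=list(rng.normal(scale=0.3, size=n)),
        sigmas=list(rng.uniform(2.5, 3.5, size=n)),
        epsilons=list(rng.uniform(0.1, 0.9, size=n)),
    )
    frames = rng.normal(scale=4.0, size=(5, n, 3))
    frames[:, :, 0] *= 2  # spread out, avoid singular pairs
    traj = make_trajectory(frames, structure)
    a = Selection(np.arange(4), "A")
    b = Selection(np.arange(4, n), "B")
    fwd = interaction_enthalpy(traj, a, b)
    bwd = interaction_enthalpy(traj, b, a)
    assert np.array_equal(fwd.total, bwd.total)


def test_matches_brute_force_all_pairs():
    rng = np.random.default_rng(1)
    n = 10
    charges = rng.normal(scale=0.4, size=n)
    sigmas = rng.uniform(2.5, 3.5, size=n)
    epsilons = rng.uniform(0.1, 0.8, size=n)
    coords = rng.uniform(-8, 8, size=(3, n, 3))
    structure = make_structure(
        coords[0], residues=list(range(1, n + 1)),
        charges=list(charges), sigmas=list(sigmas), epsilons=list(epsilons),
    )
    traj = make_trajectory(coords, structure)
    a_idx, b_idx = np.arange(5), np.arange(5, n)
    params = NonbondedParams(cutoff=10.0)
    series = interaction_enthalpy(
        traj, Selection(a_idx, "A"), Selection(b_idx, "B"), params
    )
    for f in range(3):
        coulomb = lj = 0.0
        for i in a_idx:
            for j in b_idx:
                r = np.linalg.norm(coords[f, i] - coords[f, j])
                if r > params.cutoff:
                    continue
                coulomb += COULOMB_CONSTANT_KJ_NM_E2 * charges[i] * charges[j] / (r / 10)
                s = 0.5 * (sigmas[i] + sigmas[j])
                e = np.sqrt(epsilons[i] * epsilons[j])
                lj += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert series.coulomb[f] == pytest.approx(coulomb, rel=1e-12)
        assert series.lennard_jones[f] == pytest.approx(lj, rel=1e-12)


def test_charge_scaling_is_quadratic():
    traj, a, b = _pair_trajectory(
        [3.0, 4.0], charges=(0.5, -0.3), sigmas=(3.0, 3.0), epsilons=(0.2, 0.2)
    )
    base = interaction_enthalpy(traj, a, b)
    scaled_structure = make_structure(
        [[0.0, 0, 0], [1.0, 0, 0]], residues=[1, 2],
        charges=[1.5, -0.9], sigmas=[3.0, 3.0], epsilons=[0.2, 0.2],
    )
    traj2 = make_trajectory(traj.frame_coordinates, scaled_structure)
    scaled = interaction_enthalpy(traj2, a, b)
    assert np.allclose(scaled.coulomb, 9.0 * base.coulomb, rtol=1e-12)
    assert np.allclose(scaled.lennard_jones, base.lennard_jones, rtol=1e-12)


def test_enthalpy_invariant_under_rigid_motion():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(2)
    n = 6
    structure = make_structure(
        rng.normal(scale=5.0, size=(n, 3)), residues=list(range(1, n + 1)),
        charges=list(rng.normal(scale=0.3, size=n)),
        sigmas=[3.0] * n, epsilons=[0.3] * n,
    )
    frames = rng.normal(scale=5.0, size=(4, n, 3))
    traj = make_trajectory(frames, structure)
    a, b = Selection(np.arange(3), "A"), Selection(np.arange(3, n), "B")
    base = interaction_enthalpy(traj, a, b)
    rot = Rotation.from_rotvec([0.5, -0.1, 0.8]).as_matrix()
    traj2 = make_trajectory(frames @ rot.T + np.array([3.0, 2, 1]), structure)
    moved = interaction_enthalpy(traj2, a, b)
    assert np.allclose(base.total, moved.total, atol=1e-9)


def test_overlapping_groups_rejected():
    traj, a, _ = _pair_trajectory([3.0], charges=(0.1, 0.1))
    with pytest.raises(SelectionError):
        interaction_enthalpy(traj, a, a)


def test_missing_parameters_named():
    structure = make_structure([[0.0, 0, 0], [3.0, 0, 0]], residues=[1, 2])
    traj = make_trajectory(structure.coordinates[None], structure)
    with pytest.raises(ParameterError, match="GLY1"):
        interaction_enthalpy(
            traj, Selection(np.array([0]), "A"), Selection(np.array([1]), "B")
        )


def test_singular_pair_distance_reported():
    traj, a, b = _pair_trajectory([0.01], charges=(1.0, 1.0))
    with pytest.raises(ParameterError, match="frame 0"):
        interaction_enthalpy(traj, a, b)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3, 4], [9, 11, 13, 15], 1.0),  # y = 2x + 7
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # hand-worked Pearson example
    ],
)
def test_pearson_examples(x, y, expected):
    assert enthalpy_distance_correlation(
        np.array(x, float), np.array(y, float)
    ) == pytest.approx(expected, abs=1e-12)


def test_correlation_zero_variance_is_an_error():
    with pytest.raises(ValueError, match="zero variance"):
        enthalpy_distance_correlation(
            np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])
        )


def test_correlation_summary_statistics():
    s = correlation_summary([0.5, 0.5])
    assert s.mean == 0.5 and s.sd == 0.0
    s = correlation_summary([0.0, 1.0])
    assert s.mean == pytest.approx(0.5)
    assert s.sd == pytest.approx(np.sqrt(0.5), abs=1e-12)  # ≈ 0.7071
    single = correlation_summary([0.3])
    assert single.mean == pytest.approx(0.3)
    assert not single.sd_defined
    with pytest.raises(ValueError):
        correlation_summary([])
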