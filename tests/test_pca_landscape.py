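"""PCA reaction coordinates, projections and density landscapes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from domainmotion.model_io import Selection
from domainmotion.pca_landscape import (
    build_pca,
    density_landscape,
    iso_density_contour,
    project,
)

from conftest import all_atoms, make_structure, make_trajectory


def _anchored_system(rng, n_mobile=4):
    """Four fixed anchors plus mobile atoms; returns (structure, mobile_idx)."""
    anchors = np.array(
        [[0.0, 0, 0], [20.0, 0, 0], [0, 20.0, 0], [0, 0, 20.0]]
    )
    mobile = rng.normal(scale=2.0, size=(n_mobile, 3)) + np.array([30.0, 30.0, 30.0])
    structure = make_structure(np.vstack([anchors, mobile]))
    return structure, np.arange(4, 4 + n_mobile)


def test_planted_mode_dominates(hinge, hinge_selections):
    trajectory, truth = hinge
    fit_sel, analysis_sel = hinge_selections
    model = build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
    mode = truth.mode_for(analysis_sel)
    assert abs(model.eigenvectors[0] @ mode) > 0.99
    assert model.eigenvalues[1] / model.eigenvalues[0] < 0.01


def test_static_trajectory_all_eigenvalues_zero():
    base = np.random.default_rng(1).normal(size=(6, 3))
    structure = make_structure(base)
    traj = make_trajectory(np.repeat(base[None], 5, axis=0), structure)
    sel = all_atoms(structure)
    model = build_pca(traj, structure, sel, sel)
    assert np.all(model.eigenvalues <= 1e-12)


def test_isotropic_noise_gives_flat_spectrum():
    rng = np.random.default_rng(8)
    structure, mobile_idx = _anchored_system(rng, n_mobile=3)
    sigma = 0.5
    frames = np.repeat(structure.coordinates[None], 10_000, axis=0)
    frames[:, mobile_idx, :] += rng.normal(scale=sigma, size=(10_000, 3, 3))
    traj = make_trajectory(frames, structure)
    anchors = Selection(np.arange(4), "anchors")
    analysis = Selection(mobile_idx, "mobile")
    model = build_pca(traj, structure, anchors, analysis)
    assert np.allclose(model.eigenvalues, sigma**2, rtol=0.10)


def test_projection_of_mean_is_zero_and_eigenvector_shift_projects_exactly(
    hinge, hinge_selections
):
    trajectory, _ = hinge
    fit_sel, analysis_sel = hinge_selections
    model = build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
    # Build a frame equal to the reference with analysis atoms moved to
    # mean + c·v1: its projections are (c, 0) on components (1, 2).
    c = 2.5
    coords = trajectory.topology.coordinates.copy()
    shifted = model.mean_coordinates + c * model.eigenvectors[0]
    coords[analysis_sel.atom_indices] = shifted.reshape(-1, 3)
    frame = trajectory.topology.with_coordinates(coords)
    p1 = project(model, frame, 0).values[0]
    p2 = project(model, frame, 1).values[0]
    assert p1 == pytest.approx(c, abs=1e-8)
    assert p2 == pytest.approx(0.0, abs=1e-8)
    coords[analysis_sel.atom_indices] = model.mean_coordinates.reshape(-1, 3)
    mean_frame = trajectory.topology.with_coordinates(coords)
    assert project(model, mean_frame, 0).values[0] == pytest.approx(0.0, abs=1e-8)


def test_projection_recovers_planted_amplitudes(hinge, hinge_selections):
    trajectory, truth = hinge
    fit_sel, analysis_sel = hinge_selections
    model = build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
    series = project(model, trajectory, 0)
    r = np.corrcoef(series.values, truth.amplitudes)[0, 1]
    assert abs(r) > 0.999


def test_projection_variance_equals_eigenvalue(hinge, hinge_selections):
    trajectory, _ = hinge
    fit_sel, analysis_sel = hinge_selections
    model = build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
    for component in (0, 1):
        series = project(model, trajectory, component)
        variance = np.mean((series.values - series.values.mean()) ** 2)
        assert variance == pytest.approx(model.eigenvalues[component], rel=1e-6)


def test_projections_invariant_under_global_rigid_motion(hinge, hinge_selections):
    trajectory, _ = hinge
    fit_sel, analysis_sel = hinge_selections
    model = build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
    base = project(model, trajectory, 0)
    rot = Rotation.from_rotvec([0.2, -0.7, 0.4]).as_matrix()
    moved = trajectory.frame_coordinates @ rot.T + np.array([15.0, -8.0, 3.0])
    traj2 = make_trajectory(moved, trajectory.topology)
    transformed = project(model, traj2, 0)
    assert np.allclose(base.values, transformed.values, atol=1e-6)


def test_covariance_matches_brute_force_on_small_system():
    rng = np.random.default_rng(9)
    structure, mobile_idx = _anchored_system(rng, n_mobile=4)
    frames = np.repeat(structure.coordinates[None], 50, axis=0)
    frames[:, mobile_idx, :] += rng.normal(scale=0.5, size=(50, 4, 3))
    traj = make_trajectory(frames, structure)
    anchors = Selection(np.arange(4), "anchors")
    analysis = Selection(mobile_idx, "mobile")
    model = build_pca(traj, structure, anchors, analysis)

    # Brute-force oracle: explicit fit of every frame, direct 3M×3M covariance.
    from domainmotion.superpose import apply_fit, fit as fit_op

    rows = []
    for f in range(50):
        res = fit_op(frames[f], structure, anchors)
        rows.append(apply_fit(res, frames[f])[mobile_idx].ravel())
    X = np.array(rows)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / X.shape[0]
    brute_eigenvalues = np.sort(np.linalg.eigvalsh(cov))[::-1]
    assert np.max(np.abs(brute_eigenvalues - model.eigenvalues)) < 1e-10


def test_landscape_normalization_single_bin():
    landscape = density_landscape(
        np.zeros(10), np.zeros(10), 1, 1, x_range=(-1, 1), y_range=(-2, 2)
    )
    area = 2.0 * 4.0
    assert landscape.log_density[0, 0] == pytest.approx(-np.log(area), abs=1e-12)


def test_landscape_total_probability_is_one(hinge, hinge_selections):
    rng = np.random.default_rng(2)
    landscape = density_landscape(
        rng.normal(size=2000), rng.normal(size=2000), 20, 20
    )
    dx = np.diff(landscape.x_edges)[:, None]
    dy = np.diff(landscape.y_edges)[None, :]
    rho = np.where(landscape.empty, 0.0, np.exp(landscape.log_density))
    assert float((rho * dx * dy).sum()) == pytest.approx(1.0, abs=1e-9)


def test_landscape_uniform_density_is_flat():
    rng = np.random.default_rng(12)
    x = rng.uniform(0, 2, size=1_000_000)
    y = rng.uniform(0, 1, size=1_000_000)
    landscape = density_landscape(x, y, 10, 10, x_range=(0, 2), y_range=(0, 1))
    values = landscape.log_density[~landscape.empty]
    assert values.max() - values.min() < 0.1


def test_landscape_zero_variance_axis_needs_explicit_range():
    with pytest.raises(ValueError, match="x_range"):
        density_landscape(np.zeros(5), np.arange(5.0), 10, 10)


def test_contour_single_bin_outline_and_empty_level():
    landscape = density_landscape(
        np.zeros(4), np.zeros(4), 1, 1, x_range=(0, 1), y_range=(0, 1)
    )
    loops = iso_density_contour(landscape, landscape.log_density[0, 0] - 1.0)
    assert len(loops) == 1
    corners = {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)}
    assert {tuple(v) for v in loops[0]} == corners
    assert iso_density_contour(landscape, landscape.log_density[0, 0] + 1.0) == []


def test_contour_two_disjoint_blobs_give_two_outlines():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(-5, 0.3, 4000), rng.normal(5, 0.3, 4000)])
    y = rng.normal(0, 0.3, 8000)
    landscape = density_landscape(x, y, 30, 10, x_range=(-8, 8), y_range=(-2, 2))
    level = np.nanmax(landscape.log_density) - 1.5
    loops = iso_density_contour(landscape, level)

    # Flood-fill oracle: count connected components of the thresholded mask.
    inside = (~landscape.empty) & (landscape.log_density >= level)
    seen = np.zeros_like(inside)
    components = 0
    for i in range(inside.shape[0]):
        for j in range(inside.shape[1]):
            if inside[i, j] and not seen[i, j]:
                components += 1
                stack = [(i, j)]
                while stack:
                    a, b = stack.pop()
                    if (
                        0 <= a < inside.shape[0]
                        and 0 <= b < inside.shape[1]
                        and inside[a, b]
                        and not seen[a, b]
                    ):
                        seen[a, b] = True
                        stack += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
    assert components == 2
    assert len(loops) == 2
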