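"""Covariance-matrix PCA of fitted coordinates and probability landscapes.

A collective "reaction coordinate" is the projection of rigid-body-fitted
atomic coordinates onto an eigenvector of their covariance matrix.  The
dominant eigenvector of an interdomain motion (e.g., one domain rotating
about a hinge helix while the others are held fixed by the fit) serves as
the coordinate along which landscapes and umbrella windows are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SelectionError
from .model_io import Selection, Structure, Trajectory
from .superpose import fit as _fit

__all__ = [
    "PcaModel",
    "ProjectionSeries",
    "DensityLandscape",
    "build_pca",
    "project",
    "density_landscape",
    "iso_density_contour",
]


@dataclass(frozen=True)
class PcaModel:
    """Mean coordinates (Å, flattened 3M) and orthonormal eigenvectors.

    Eigenvectors are stored row-wise in descending eigenvalue order with the
    sign convention that each eigenvector's largest-magnitude component is
    positive (the sign of an eigenvector is otherwise arbitrary, and fixing
    it keeps projections reproducible across runs and BLAS backends).
    """

    mean_coordinates: np.ndarray  # (3M,)
    eigenvectors: np.ndarray  # (n_components, 3M)
    eigenvalues: np.ndarray  # (n_components,), Å²
    reference: Structure
    fit_selection: Selection
    analysis_selection: Selection


@dataclass(frozen=True)
class ProjectionSeries:
    """Per-frame scalar reaction-coordinate values in Å."""

    values: np.ndarray
    component_index: int
    label: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path, times=None) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tvalue_A\n" if times is None else "time_ps\tvalue_A\n")
            keys = range(len(self.values)) if times is None else times
            for k, v in zip(keys, self.values):
                fh.write(f"{k}\t{v:.6f}\n")


def _fitted_analysis_coords(
    trajectories: list[Trajectory],
    reference: Structure,
    fit_selection: Selection,
    analysis_selection: Selection,
) -> np.ndarray:
    """Concatenated fitted analysis coordinates, flattened per frame."""
    blocks = []
    for traj in trajectories:
        for i in range(traj.n_frames):
            frame = traj.frame_coordinates[i]
            res = _fit(frame, reference, fit_selection)
            fitted = res.transform(frame)
            blocks.append(fitted[analysis_selection.atom_indices].ravel())
    return np.array(blocks)


def build_pca(
    trajectories: list[Trajectory] | Trajectory,
    reference: Structure,
    fit_selection: Selection,
    analysis_selection: Selection,
) -> PcaModel:
    """PCA of analysis-selection coordinates over fitted, concatenated frames.

    Each frame is rigid-body fitted to ``reference`` on ``fit_selection``;
    the covariance matrix of the analysis coordinates is accumulated in two
    passes (mean, then centered outer products) and diagonalized.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if len(analysis_selection) == 0:
        raise SelectionError("analysis_selection is empty")
    total_frames = sum(t.n_frames for t in trajectories)
    if total_frames < 2:
        raise ValueError("PCA requires at least 2 frames in total")

    coords = _fitted_analysis_coords(
        trajectories, reference, fit_selection, analysis_selection
    )
    mean = coords.mean(axis=0)
    centered = coords - mean
    covariance = centered.T @ centered / coords.shape[0]
    eigenvalues, eigenvectors = np.linalg.eigh(covariance)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order].T
    # Sign convention: largest-magnitude component positive.
    for k in range(eigenvectors.shape[0]):
        j = np.argmax(np.abs(eigenvectors[k]))
        if eigenvectors[k, j] < 0:
            eigenvectors[k] = -eigenvectors[k]
    return PcaModel(
        mean_coordinates=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        reference=reference,
        fit_selection=fit_selection,
        analysis_selection=analysis_selection,
    )


def project(
    model: PcaModel,
    frames: Trajectory | Structure,
    component: int = 0,
    label: str = "",
) -> ProjectionSeries:
    """Project frames (or a single structure) onto one PCA component.

    Frames are fitted to the model's reference on its fit selection, the
    analysis coordinates are centered by the stored mean and dotted with the
    chosen eigenvector.  A single Structure yields a length-1 series (used
    to place reference conformations on a landscape).
    """
    if component >= model.eigenvectors.shape[0]:
        raise ValueError(
            f"component {component} not available "
            f"({model.eigenvectors.shape[0]} stored)"
        )
    if isinstance(frames, Structure):
        frame_list = frames.coordinates[None, :, :]
        n_atoms = frames.n_atoms
    else:
        frame_list = frames.frame_coordinates
        n_atoms = frames.n_atoms
    if n_atoms != model.reference.n_atoms:
        raise ValueError(
            f"topology mismatch: frames have {n_atoms} atoms, model reference "
            f"has {model.reference.n_atoms}"
        )
    vec = model.eigenvectors[component]
    values = np.empty(frame_list.shape[0])
    for i, frame in enumerate(frame_list):
        res = _fit(frame, model.reference, model.fit_selection)
        fitted = res.transform(frame)
        flat = fitted[model.analysis_selection.atom_indices].ravel()
        values[i] = (flat - model.mean_coordinates) @ vec
    return ProjectionSeries(values, component, label)


@dataclass(frozen=True)
class DensityLandscape:
    """2D log probability density over binned coordinate pairs.

    ``log_density`` is ln ρ with ρ normalized so that Σ ρ·Δx·Δy = 1.
    Empty bins are flagged in ``empty`` and hold NaN, never −inf, so they
    serialize cleanly ("NA" in TSV output).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    log_density: np.ndarray  # (nx, ny), NaN where empty
    empty: np.ndarray  # boolean mask, True where the bin had no samples

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x_center\ty_center\tln_rho\n")
            for i, x in enumerate(self.x_centers):
                for j, y in enumerate(self.y_centers):
                    v = "NA" if self.empty[i, j] else f"{self.log_density[i, j]:.6f}"
                    fh.write(f"{x:.6f}\t{y:.6f}\t{v}\n")


def _series_values(series) -> np.ndarray:
    if hasattr(series, "values"):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def density_landscape(
    x,
    y,
    x_bins: int = 50,
    y_bins: int = 50,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> DensityLandscape:
    """Normalized 2D histogram of two per-frame series, as ln ρ.

    Bin ranges span the data with 2% padding unless given explicitly.  An
    axis with zero variance cannot be auto-ranged and raises with a hint to
    pass an explicit range.
    """
    xv = _series_values(x)
    yv = _series_values(y)
    if xv.shape != yv.shape:
        raise ValueError("x and y series must have equal length")
    if xv.size == 0:
        raise ValueError("density_landscape requires at least one sample")

    def _auto_range(values, given, axis):
        if given is not None:
            return given
        lo, hi = values.min(), values.max()
        if hi == lo:
            raise ValueError(
                f"{axis} axis has zero variance; pass an explicit {axis}_range"
            )
        pad = 0.02 * (hi - lo)
        return (lo - pad, hi + pad)

    xr = _auto_range(xv, x_range, "x")
    yr = _auto_range(yv, y_range, "y")
    counts, x_edges, y_edges = np.histogram2d(
        xv, yv, bins=(x_bins, y_bins), range=(xr, yr), density=True
    )
    empty = counts == 0
    log_density = np.where(empty, np.nan, np.log(np.where(empty, 1.0, counts)))
    return DensityLandscape(x_edges, y_edges, log_density, empty)


def iso_density_contour(
    landscape: DensityLandscape, level: float
) -> list[np.ndarray]:
    """Closed bin-boundary outlines enclosing bins with ln ρ ≥ level.

    Returns a list of closed polylines (arrays of (x, y) vertices, first
    vertex repeated at the end), one per connected region.  A level above
    the maximum density yields an empty list.
    """
    inside = (~landscape.empty) & (landscape.log_density >= level)
    if not inside.any():
        return []
    nx, ny = inside.shape
    # Collect boundary edges as vertex pairs on the bin grid.
    edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    def add_edge(a, b):
        edges.add((a, b) if a <= b else (b, a))

    for i in range(nx):
        for j in range(ny):
            if not inside[i, j]:
                continue
            if i == 0 or not inside[i - 1, j]:
                add_edge((i, j), (i, j + 1))
            if i == nx - 1 or not inside[i + 1, j]:
                add_edge((i + 1, j), (i + 1, j + 1))
            if j == 0 or not inside[i, j - 1]:
                add_edge((i, j), (i + 1, j))
            if j == ny - 1 or not inside[i, j + 1]:
                add_edge((i, j + 1), (i + 1, j + 1))

    # Chain edges into closed loops.
    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    remaining = set(edges)
    loops: list[np.ndarray] = []
    while remaining:
        a, b = next(iter(remaining))
        remaining.discard((a, b))
        loop = [a, b]
        while loop[-1] != loop[0]:
            current = loop[-1]
            previous = loop[-2]
            next_vertex = None
            for candidate in adjacency[current]:
                key = (current, candidate) if current <= candidate else (candidate, current)
                if candidate != previous and key in remaining:
                    next_vertex = candidate
                    remaining.discard(key)
                    break
            if next_vertex is None:
                break
            loop.append(next_vertex)
        vertices = np.array(
            [(landscape.x_edges[i], landscape.y_edges[j]) for i, j in loop]
        )
        loops.append(vertices)
    return loops
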