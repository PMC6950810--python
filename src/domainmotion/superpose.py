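"""Rigid-body superposition (Kabsch), RMSD and per-residue RMSF."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateFitError
from .model_io import Selection, Structure, Trajectory

__all__ = ["SuperpositionResult", "RmsfProfile", "fit", "apply_fit", "rmsd", "rmsf"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rotation + translation; ``fitted = R @ x + t``."""

    rotation: np.ndarray  # 3×3, orthonormal, det +1
    translation: np.ndarray  # Å
    rmsd: float  # Å over the fit selection

    def transform(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


def _coords_of(obj: Structure | np.ndarray) -> np.ndarray:
    if isinstance(obj, Structure):
        return obj.coordinates
    return np.asarray(obj, dtype=float)


def _check_fit_points(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError(
            f"rigid-body fit needs >= 3 atoms, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    # Collinear sets have rank < 2 after centering.
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear; rotation is underdetermined")


def fit(
    mobile: Structure | np.ndarray,
    reference: Structure | np.ndarray,
    fit_selection: Selection,
) -> SuperpositionResult:
    """Kabsch fit of ``mobile`` onto ``reference`` over ``fit_selection``.

    The same selection indexes both coordinate sets (paired atoms).
    Unweighted least squares; see the module docs for why no mass weighting
    is applied.
    """
    idx = fit_selection.atom_indices
    mob = _coords_of(mobile)[idx]
    ref = _coords_of(reference)[idx]
    if mob.shape != ref.shape:
        raise DegenerateFitError("fit selection yields unequal paired atom sets")
    _check_fit_points(mob)
    _check_fit_points(ref)
    mob_centroid = mob.mean(axis=0)
    ref_centroid = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_centroid, mob - mob_centroid)
    matrix = rot.as_matrix()
    translation = ref_centroid - matrix @ mob_centroid
    fitted = mob @ matrix.T + translation
    value = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(matrix, translation, value)


def apply_fit(result: SuperpositionResult, coordinates: np.ndarray) -> np.ndarray:
    """Apply a superposition to a full coordinate set."""
    return result.transform(np.asarray(coordinates, dtype=float))


def rmsd(
    a: Structure | np.ndarray, b: Structure | np.ndarray, selection: Selection
) -> float:
    """Plain coordinate RMSD over a selection, without fitting."""
    idx = selection.atom_indices
    diff = _coords_of(a)[idx] - _coords_of(b)[idx]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def fit_frames(
    trajectory: Trajectory,
    reference: Structure | np.ndarray,
    fit_selection: Selection,
) -> np.ndarray:
    """All frames fitted to ``reference``; returns (F, N, 3) coordinates."""
    out = np.empty_like(trajectory.frame_coordinates)
    for i in range(trajectory.n_frames):
        res = fit(trajectory.frame_coordinates[i], reference, fit_selection)
        out[i] = res.transform(trajectory.frame_coordinates[i])
    return out


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue (or per-atom) root mean-square fluctuations in Å."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue_number\trmsf_A\n")
            for num, val in zip(self.residue_numbers, self.rmsf):
                fh.write(f"{num}\t{val:.6f}\n")


def rmsf(
    trajectory: Trajectory,
    fit_selection: Selection,
    analysis_selection: Selection,
    per_residue: bool = True,
) -> RmsfProfile:
    """RMSF about the mean structure after rigid-body fitting.

    Mean-structure convention: frames are first fitted to frame 0, the mean
    of the fitted frames is computed, then every frame is refitted to that
    mean and the mean recomputed.  Per-atom RMSF is the root mean squared
    deviation from the final mean; the per-residue value is the unweighted
    mean over the residue's selected atoms.
    """
    if trajectory.n_frames < 2:
        raise ValueError("rmsf requires at least 2 frames")
    fitted = fit_frames(trajectory, trajectory.frame_coordinates[0], fit_selection)
    mean = fitted.mean(axis=0)
    refitted = np.empty_like(fitted)
    for i in range(trajectory.n_frames):
        res = fit(fitted[i], mean, fit_selection)
        refitted[i] = res.transform(fitted[i])
    mean = refitted.mean(axis=0)

    idx = analysis_selection.atom_indices
    deviations = refitted[:, idx, :] - mean[idx]
    atom_rmsf = np.sqrt(np.mean(np.sum(deviations**2, axis=2), axis=0))

    residues = trajectory.topology.residue_numbers[idx]
    if not per_residue:
        return RmsfProfile(residues, atom_rmsf)
    unique = []
    values = []
    seen = set()
    for r in residues:  # preserve structure order
        if r not in seen:
            seen.add(r)
            unique.append(r)
            values.append(atom_rmsf[residues == r].mean())
    return RmsfProfile(np.array(unique), np.array(values))
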