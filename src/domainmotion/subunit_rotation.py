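"""Rigid-body rotation angles of a body relative to a fitted core.

Used for ribosomal 30S body rotation and head swivel: the frame is first
fitted to a reference structure on a core selection (e.g., the 23S rRNA
for body rotation, or the 30S body for head swivel), which removes global
motion; the least-squares rotation mapping the reference body atoms onto
the fitted frame's body atoms is then extracted and reported as a single
signed angle.  The sign is the projection of the rotation axis onto a
user-declared reference axis (positive = counterclockwise about that axis
viewed from its positive end).  The 0° origin is whatever reference
structure is supplied (conventionally the classical, unrotated state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import Selection, Structure, Trajectory
from .superpose import fit as _fit

__all__ = ["RotationDefinition", "AngleSeries", "rotation_angle", "angle_histogram"]


@dataclass(frozen=True)
class RotationDefinition:
    """Core (fit target), body (rotating part), reference state and axis."""

    core_selection: Selection
    body_selection: Selection
    reference: Structure
    reference_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    label: str = "rotation"

    def __post_init__(self) -> None:
        if np.intersect1d(
            self.core_selection.atom_indices, self.body_selection.atom_indices
        ).size:
            raise ValueError("core and body selections must be disjoint")
        axis = np.asarray(self.reference_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("reference_axis must be non-zero")
        object.__setattr__(self, "reference_axis", axis / norm)


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame signed rotation angles in degrees, in (−180, 180]."""

    values: np.ndarray
    label: str = ""

    def __len__(self) -> int:
        return len(self.values)


def rotation_angle(
    frames: Trajectory | Structure, definition: RotationDefinition
) -> AngleSeries:
    """Signed body-rotation angle per frame relative to the reference.

    Per frame: (1) fit to the reference on the core selection; (2) Kabsch
    rotation R mapping the reference body coordinates onto the fitted
    frame's body coordinates; (3) angle θ from trace(R) = 1 + 2cos θ,
    signed by the rotation axis' projection onto the declared axis.
    """
    if isinstance(frames, Structure):
        coords = frames.coordinates[None, :, :]
    else:
        coords = frames.frame_coordinates
    body_idx = definition.body_selection.atom_indices
    ref_body = definition.reference.coordinates[body_idx]
    ref_body_centered = ref_body - ref_body.mean(axis=0)
    angles = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        res = _fit(coords[f], definition.reference, definition.core_selection)
        fitted_body = res.transform(coords[f])[body_idx]
        fitted_centered = fitted_body - fitted_body.mean(axis=0)
        rot, _ = Rotation.align_vectors(fitted_centered, ref_body_centered)
        rotvec = rot.as_rotvec(degrees=True)
        magnitude = np.linalg.norm(rotvec)
        if magnitude == 0:
            angles[f] = 0.0
            continue
        sign = np.sign(np.dot(rotvec / magnitude, definition.reference_axis))
        angles[f] = (sign if sign != 0 else 1.0) * magnitude
    # rotvec magnitudes are in [0, 180], so signed angles lie in (−180, 180]
    return AngleSeries(angles, definition.label)


def angle_histogram(
    series: AngleSeries, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-density histogram of angles.

    Returns (bin_edges, density); densities integrate to 1 over the bins.
    Bin edges are aligned to multiples of ``bin_width``.
    """
    values = np.asarray(series.values, dtype=float)
    if values.size == 0:
        raise ValueError("angle series is empty")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    return edges, density
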