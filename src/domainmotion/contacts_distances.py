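"""Contact occupancy, residue-distance series and running averages.

The contact criterion follows the common occupancy definition: a frame
counts as a contact iff the minimum distance between any (heavy) atom of
the residue and any (heavy) atom of the target group is strictly below the
cutoff (default 5 Å).  Coordinates are assumed to be whole/unwrapped
molecules: no minimum-image or periodic-boundary treatment is applied, so
trajectories straight out of a periodic simulation box must be unwrapped
first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import SelectionError
from .model_io import Selection, Structure, Trajectory
from .pca_landscape import ProjectionSeries

__all__ = [
    "ContactSeries",
    "DistanceSeries",
    "contact_occupancy",
    "residue_distance",
    "elbow_distance",
    "running_average",
]


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame contact booleans and their mean (the occupancy)."""

    pair_label: str
    per_frame: np.ndarray  # bool
    occupancy: float
    cutoff: float = 5.0


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distances in Å between one fixed atom pair."""

    label: str
    values: np.ndarray
    atom_pair: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path, times=None) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tdistance_A\n" if times is None else "time_ps\tdistance_A\n")
            keys = range(len(self.values)) if times is None else times
            for k, v in zip(keys, self.values):
                fh.write(f"{k}\t{v:.6f}\n")


def _heavy_filter(selection: Selection, topology: Structure, heavy_only: bool):
    idx = selection.atom_indices
    if heavy_only:
        idx = idx[~topology.is_hydrogen[idx]]
    if len(idx) == 0:
        raise SelectionError(
            f"selection '{selection.label}' is empty after hydrogen filtering"
        )
    return idx


def contact_occupancy(
    trajectory: Trajectory,
    residue: Selection,
    target_group: Selection,
    cutoff: float = 5.0,
    heavy_only: bool = True,
) -> ContactSeries:
    """Fraction of frames with min inter-group (heavy-atom) distance < cutoff."""
    idx_a = _heavy_filter(residue, trajectory.topology, heavy_only)
    idx_b = _heavy_filter(target_group, trajectory.topology, heavy_only)
    per_frame = np.empty(trajectory.n_frames, dtype=bool)
    for f in range(trajectory.n_frames):
        coords = trajectory.frame_coordinates[f]
        per_frame[f] = cdist(coords[idx_a], coords[idx_b]).min() < cutoff
    return ContactSeries(
        pair_label=f"{residue.label}|{target_group.label}",
        per_frame=per_frame,
        occupancy=float(per_frame.mean()),
        cutoff=cutoff,
    )


def _locate_atom(
    topology: Structure, chain: str, residue_number: int, atom_name: str
) -> int:
    mask = (
        (topology.chain_ids == chain)
        & (topology.residue_numbers == residue_number)
        & (topology.atom_names == atom_name)
    )
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        residue_mask = (topology.chain_ids == chain) & (
            topology.residue_numbers == residue_number
        )
        available = sorted(set(topology.atom_names[residue_mask]))
        raise SelectionError(
            f"atom {atom_name!r} not found in chain {chain} residue "
            f"{residue_number}; available atoms: {available}"
        )
    return int(indices[0])


def residue_distance(
    frames: Trajectory | Structure,
    residue_a: tuple[str, int, str],
    residue_b: tuple[str, int, str],
    label: str = "",
) -> DistanceSeries:
    """Euclidean distance per frame between two named atoms.

    No fitting is applied — pairwise distances are invariant under rigid
    transformations of a frame.  Each residue is given as
    (chain_id, residue_number, atom_name), e.g., ("A", 124, "CA").
    """
    if isinstance(frames, Structure):
        topology = frames
        coords = frames.coordinates[None, :, :]
    else:
        topology = frames.topology
        coords = frames.frame_coordinates
    ia = _locate_atom(topology, *residue_a)
    ib = _locate_atom(topology, *residue_b)
    values = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=1)
    if not label:
        label = (
            f"{residue_a[0]}:{residue_a[1]}:{residue_a[2]}"
            f"-{residue_b[0]}:{residue_b[1]}:{residue_b[2]}"
        )
    return DistanceSeries(label, values, (ia, ib))


_O3_PRIME_ALIASES = ("O3'", "O3′", "O3*")


def elbow_distance(
    frames: Trajectory | Structure,
    a_site: tuple[str, int],
    p_site: tuple[str, int],
) -> DistanceSeries:
    """tRNA elbow distance: O3′–O3′ between an A-site and a P-site nucleotide.

    Conventionally measured between U60 of the A-site tRNA and U8 of the
    P-site tRNA; it decreases from ~50 to ~30 Å as the elbow accommodates.
    Both the ASCII (O3') and typographic (O3′) atom-name dialects are
    accepted.
    """
    if isinstance(frames, Structure):
        topology = frames
    else:
        topology = frames.topology

    def resolve(chain, number):
        last_error = None
        for name in _O3_PRIME_ALIASES:
            try:
                _locate_atom(topology, chain, number, name)
                return name
            except SelectionError as exc:
                last_error = exc
        raise last_error

    name_a = resolve(*a_site)
    name_p = resolve(*p_site)
    series = residue_distance(
        frames, (a_site[0], a_site[1], name_a), (p_site[0], p_site[1], name_p)
    )
    return replace(series, label="R_elbow")


def running_average(series, window: int):
    """Centered moving mean; edge values use the truncated window.

    ``window`` must be odd so the window is symmetric about each frame.
    Accepts a DistanceSeries, ProjectionSeries, or plain array and returns
    the same type.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if isinstance(series, (DistanceSeries, ProjectionSeries)):
        values = series.values
    else:
        values = np.asarray(series, dtype=float)
    n = len(values)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    averaged = sums / counts
    if isinstance(series, DistanceSeries):
        return replace(series, values=averaged)
    if isinstance(series, ProjectionSeries):
        return ProjectionSeries(averaged, series.component_index, series.label)
    return averaged
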