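"""Monte Carlo van der Waals volumes and steric-overlap statistics.

Each atom is a sphere of its van der Waals radius.  The volume of a union
of spheres is estimated by uniform random points in an axis-aligned
bounding box: V = (points inside ≥1 sphere)/(total points) × (box volume).
The overlap between two groups A and B is

    V_overlap = V_A + V_B − V_AB

where V_AB is the volume of the combined set.  By default a single common
random point stream is used for all three estimates; the identity then
holds exactly per point (a point inside both groups is inside each), the
overlap estimator is lower-variance, and V_overlap ≥ 0 always.  An
independent-stream mode is available for literal replication of the
three-independent-runs protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Selection, Structure, Trajectory
from .superpose import fit as _fit

__all__ = ["MCVolumeConfig", "VolumeResult", "mc_volume", "volume_overlap", "clash_scan"]

_CHUNK = 262_144  # points per evaluation chunk; bounds peak memory


@dataclass(frozen=True)
class MCVolumeConfig:
    """Settings for MC volume integration.

    ``box_padding`` (Å) pads the coordinate extent on every side; the
    default (None) uses the maximum vdW radius of the integrated atoms, so
    no sphere is truncated by the box.  ``neighbor_cutoff`` (Å) preselects
    receptor atoms near the probe in :func:`clash_scan`.
    """

    n_points: int = 20_000_000
    seed: int = 0
    box_padding: float | None = None
    neighbor_cutoff: float = 10.0
    common_stream: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.box_padding is not None and self.box_padding < 0:
            raise ValueError("box_padding must be >= 0")


@dataclass(frozen=True)
class VolumeResult:
    """MC-integrated volumes in Å³ and their overlap."""

    v_a: float
    v_b: float
    v_ab: float
    v_overlap: float
    mc_standard_error: float
    n_points: int
    box_volume: float
    seed: int
    time_ps: float | None = None


def _bounding_box(centers: np.ndarray, radii: np.ndarray, padding: float | None):
    if padding is None:
        padding = float(radii.max())
    lo = np.minimum(centers.min(axis=0) - padding, (centers - radii[:, None]).min(axis=0))
    hi = np.maximum(centers.max(axis=0) + padding, (centers + radii[:, None]).max(axis=0))
    return lo, hi


def _inside_any(points: np.ndarray, centers: np.ndarray, radii_sq: np.ndarray):
    """Boolean mask: point lies inside at least one sphere."""
    inside = np.zeros(len(points), dtype=bool)
    # Loop over atoms keeps memory at O(n_points); atom counts are modest
    # after neighbor preselection.
    for c, r2 in zip(centers, radii_sq):
        outside = ~inside
        if not outside.any():
            break
        d2 = np.sum((points[outside] - c) ** 2, axis=1)
        inside[np.flatnonzero(outside)[d2 <= r2]] = True
    return inside


def _group_arrays(structure: Structure, selection: Selection | None):
    if selection is None:
        idx = np.arange(structure.n_atoms)
    else:
        idx = selection.atom_indices
    centers = structure.coordinates[idx]
    radii = structure.vdw_radii(idx)
    return centers, radii


def mc_volume(
    structure: Structure,
    selection: Selection | None = None,
    config: MCVolumeConfig = MCVolumeConfig(),
) -> tuple[float, float]:
    """Volume (Å³) of the union of the selected atoms' vdW spheres.

    Returns (volume, binomial standard error).  Zero selected atoms give
    (0, 0) — an empty union has no volume.
    """
    centers, radii = _group_arrays(structure, selection)
    if len(centers) == 0:
        return 0.0, 0.0
    lo, hi = _bounding_box(centers, radii, config.box_padding)
    box_volume = float(np.prod(hi - lo))
    radii_sq = radii**2
    rng = np.random.default_rng(config.seed)
    hits = 0
    remaining = config.n_points
    while remaining > 0:
        m = min(_CHUNK, remaining)
        points = rng.uniform(lo, hi, size=(m, 3))
        hits += int(_inside_any(points, centers, radii_sq).sum())
        remaining -= m
    p = hits / config.n_points
    volume = p * box_volume
    se = box_volume * np.sqrt(p * (1.0 - p) / config.n_points)
    return float(volume), float(se)


def volume_overlap(
    structure_a: Structure,
    structure_b: Structure,
    selection_a: Selection | None = None,
    selection_b: Selection | None = None,
    config: MCVolumeConfig = MCVolumeConfig(),
    time_ps: float | None = None,
) -> VolumeResult:
    """Overlap volume between two sphere groups via V_A + V_B − V_AB."""
    centers_a, radii_a = _group_arrays(structure_a, selection_a)
    centers_b, radii_b = _group_arrays(structure_b, selection_b)
    centers = np.vstack([c for c in (centers_a, centers_b) if len(c)])
    if len(centers) == 0:
        return VolumeResult(0, 0, 0, 0, 0, config.n_points, 0.0, config.seed, time_ps)
    radii = np.concatenate([radii_a, radii_b])
    lo, hi = _bounding_box(centers, radii, config.box_padding)
    box_volume = float(np.prod(hi - lo))

    if not config.common_stream:
        # Literal three-independent-integrations mode (one box for all).
        volumes = []
        for k, (c, r) in enumerate(
            [(centers_a, radii_a), (centers_b, radii_b), (centers, radii)]
        ):
            sub = MCVolumeConfig(
                n_points=config.n_points,
                seed=config.seed + k,
                box_padding=config.box_padding,
                common_stream=False,
            )
            hits, rng = 0, np.random.default_rng(sub.seed)
            remaining = config.n_points
            while remaining > 0:
                m = min(_CHUNK, remaining)
                pts = rng.uniform(lo, hi, size=(m, 3))
                if len(c):
                    hits += int(_inside_any(pts, c, r**2).sum())
                remaining -= m
            volumes.append(hits / config.n_points * box_volume)
        v_a, v_b, v_ab = volumes
        p_ab = v_ab / box_volume
        se = box_volume * np.sqrt(p_ab * (1 - p_ab) / config.n_points)
        return VolumeResult(
            v_a, v_b, v_ab, v_a + v_b - v_ab, float(se),
            config.n_points, box_volume, config.seed, time_ps,
        )

    rng = np.random.default_rng(config.seed)
    hits_a = hits_b = hits_both = 0
    remaining = config.n_points
    ra2, rb2 = radii_a**2, radii_b**2
    while remaining > 0:
        m = min(_CHUNK, remaining)
        points = rng.uniform(lo, hi, size=(m, 3))
        in_a = (
            _inside_any(points, centers_a, ra2)
            if len(centers_a)
            else np.zeros(m, dtype=bool)
        )
        in_b = (
            _inside_any(points, centers_b, rb2)
            if len(centers_b)
            else np.zeros(m, dtype=bool)
        )
        hits_a += int(in_a.sum())
        hits_b += int(in_b.sum())
        hits_both += int((in_a & in_b).sum())
        remaining -= m
    n = config.n_points
    v_a = hits_a / n * box_volume
    v_b = hits_b / n * box_volume
    # hits in the union = hits_a + hits_b − hits in both, so the overlap
    # identity reduces to counting points inside both groups.
    v_ab = (hits_a + hits_b - hits_both) / n * box_volume
    v_overlap = hits_both / n * box_volume
    p = hits_both / n
    se = box_volume * np.sqrt(p * (1.0 - p) / n)
    return VolumeResult(
        float(v_a), float(v_b), float(v_ab), float(v_overlap), float(se),
        n, box_volume, config.seed, time_ps,
    )


def clash_scan(
    trajectory: Trajectory,
    fit_selection: Selection | None,
    probe: Structure,
    reference: Structure,
    receptor_selection: Selection | None = None,
    stride: int = 1,
    config: MCVolumeConfig = MCVolumeConfig(),
) -> list[VolumeResult]:
    """Per-snapshot probe/receptor vdW overlap along a trajectory.

    Every ``stride``-th frame is rigid-body fitted to ``reference`` on
    ``fit_selection`` (placing it in the frame of the probe pose, which
    must be in reference coordinates; pass None when the frames are
    already aligned to the reference), receptor atoms within
    ``neighbor_cutoff`` of any probe atom are preselected, and the volume
    overlap with the probe is integrated.  Results carry the snapshot time.
    """
    from scipy.spatial.distance import cdist

    if receptor_selection is None:
        receptor_idx = np.arange(trajectory.n_atoms)
    else:
        receptor_idx = receptor_selection.atom_indices
    probe_radii = probe.vdw_radii()
    results = []
    for f in range(0, trajectory.n_frames, stride):
        frame = trajectory.frame_coordinates[f]
        if fit_selection is None:
            fitted = frame
        else:
            res = _fit(frame, reference, fit_selection)
            fitted = res.transform(frame)
        receptor_coords = fitted[receptor_idx]
        near = (
            cdist(receptor_coords, probe.coordinates).min(axis=1)
            <= config.neighbor_cutoff
        )
        time_ps = float(trajectory.frame_times[f])
        if not near.any():
            results.append(
                VolumeResult(0, 0, 0, 0, 0, config.n_points, 0.0, config.seed, time_ps)
            )
            continue
        near_idx = receptor_idx[near]
        receptor_structure = trajectory.topology.with_coordinates(fitted)
        results.append(
            volume_overlap(
                receptor_structure,
                probe,
                selection_a=Selection(near_idx, "receptor-near-probe"),
                selection_b=None,
                config=config,
                time_ps=time_ps,
            )
        )
    return results
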