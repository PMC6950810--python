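"""Synthetic inputs with planted ground truth for every analysis stage.

The generators emulate the statistical structure the analyses assume — a
multi-domain toy protein with one planted hinge mode whose motion is
geometrically coupled to interface distances, exact Boltzmann samples from
1D potentials under harmonic umbrella biases, and rigid sphere pairs with
known analytic overlap volumes — without any pretension to physically
realistic protein models.  Each generator is deterministic for a given
spec+seed and records its full spec in a ground-truth sidecar, which is
what downstream tests check against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import kt_kj_per_mol
from .exceptions import DomainMotionError
from .model_io import AtomRecord, Selection, Structure, Trajectory
from .wham_pmf import UmbrellaWindow

__all__ = [
    "HingeSpec",
    "HingeGroundTruth",
    "generate_hinge_trajectory",
    "PotentialSpec",
    "sample_biased_windows",
    "generate_overlap_fixture",
    "OverlapFixture",
]

_BACKBONE_OFFSETS = {  # Å offsets of N/CA/C within a pseudo-residue
    "N": np.array([-1.2, -0.4, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.4, 0.0]),
}
_LATTICE_SPACING = 3.8  # Å, Cα–Cα
_DOMAIN_GAP = 12.0  # Å between domain bounding lattices


@dataclass(frozen=True)
class HingeSpec:
    """Toy multi-domain protein with one planted hinge mode on domain 1.

    Domains are cubic lattices of pseudo-backbone N/CA/C triplets with
    3.8 Å Cα spacing.  Domain 1 is displaced along a planted unit mode
    (a linearized rigid rotation about a hinge axis at the domain 1/2
    boundary) by ``mode_amplitude_series`` (Å); all atoms additionally
    receive isotropic Gaussian thermal noise.  ``coupled_distance_signs``
    plants one interface atom pair per entry whose distance series
    correlates with the mode amplitude with the requested sign, emulating
    one interface opening while another closes.
    """

    n_domains: int = 3
    residues_per_domain: int = 20
    n_frames: int = 500
    mode_amplitude_series: np.ndarray | None = None
    amplitude: float = 3.0  # Å, used when no explicit series is given
    thermal_noise_sigma: float = 0.03  # Å; mode-dominated regime (see docs)
    coupled_distance_signs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_noise_sigma < 0:
            raise ValueError("thermal_noise_sigma must be >= 0")
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains (one mobile, one core)")
        if self.mode_amplitude_series is not None:
            series = np.asarray(self.mode_amplitude_series, dtype=float)
            if len(series) < 2:
                raise ValueError("mode_amplitude_series must have >= 2 frames")
            object.__setattr__(self, "mode_amplitude_series", series)
            object.__setattr__(self, "n_frames", len(series))
        elif self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def amplitudes(self) -> np.ndarray:
        if self.mode_amplitude_series is not None:
            return self.mode_amplitude_series
        t = np.arange(self.n_frames)
        return self.amplitude * np.sin(2.0 * np.pi * 3.0 * t / self.n_frames)


@dataclass(frozen=True)
class HingeGroundTruth:
    """Planted quantities a test can check an analysis stage against."""

    mode_full: np.ndarray  # (3N,), unit; zero outside domain 1
    domain1_atom_indices: np.ndarray
    amplitudes: np.ndarray  # Å per frame
    coupled_pairs: tuple[tuple[int, int, int], ...]  # (atom_a, atom_b, sign)
    coupled_distances: np.ndarray  # (n_pairs, n_frames), noiseless analytic
    domain_residue_ranges: tuple[tuple[int, int], ...]
    seed: int
    spec_json: str

    def mode_for(self, selection: Selection) -> np.ndarray:
        """Planted mode restricted to a selection, renormalized to unit."""
        sub = self.mode_full.reshape(-1, 3)[selection.atom_indices].ravel()
        norm = np.linalg.norm(sub)
        if norm == 0:
            raise ValueError("planted mode vanishes on this selection")
        return sub / norm

    def write_sidecar(self, path) -> None:
        payload = {
            "spec": json.loads(self.spec_json),
            "seed": self.seed,
            "mode_full": self.mode_full.tolist(),
            "domain1_atom_indices": self.domain1_atom_indices.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "coupled_pairs": [list(p) for p in self.coupled_pairs],
            "coupled_distances": self.coupled_distances.tolist(),
            "domain_residue_ranges": [list(r) for r in self.domain_residue_ranges],
        }
        Path(path).write_text(json.dumps(payload))


def _build_domain_lattice(n_residues: int) -> np.ndarray:
    """Cα positions of one domain: a near-cubic lattice, 3.8 Å spacing."""
    side = int(np.ceil(n_residues ** (1.0 / 3.0)))
    points = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                points.append((i, j, k))
                if len(points) == n_residues:
                    return np.array(points, dtype=float) * _LATTICE_SPACING
    return np.array(points[:n_residues], dtype=float) * _LATTICE_SPACING


def _build_topology(spec: HingeSpec) -> tuple[Structure, list[tuple[int, int]]]:
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    residue_ranges: list[tuple[int, int]] = []
    residue_number = 0
    x_offset = 0.0
    side = _LATTICE_SPACING * int(np.ceil(spec.residues_per_domain ** (1 / 3)))
    for domain in range(spec.n_domains):
        ca = _build_domain_lattice(spec.residues_per_domain)
        ca[:, 0] += x_offset
        first_residue = residue_number + 1
        for r in range(spec.residues_per_domain):
            residue_number += 1
            for name in ("N", "CA", "C"):
                atoms.append(
                    AtomRecord(
                        atom_index=len(atoms),
                        atom_name=name,
                        element="N" if name == "N" else "C",
                        residue_number=residue_number,
                        residue_name="GLY",
                        chain_id="A",
                        is_hydrogen=False,
                    )
                )
                coords.append(ca[r] + _BACKBONE_OFFSETS[name])
        residue_ranges.append((first_residue, residue_number))
        x_offset += side + _DOMAIN_GAP
    return Structure(atoms, np.array(coords)), residue_ranges


def _planted_hinge_mode(
    base: np.ndarray, domain1_idx: np.ndarray, hinge_point: np.ndarray
) -> np.ndarray:
    """Unit 3N displacement field: rigid rotation of domain 1 about z."""
    mode = np.zeros_like(base)
    axis = np.array([0.0, 0.0, 1.0])
    for i in domain1_idx:
        mode[i] = np.cross(axis, base[i] - hinge_point)
    norm = np.linalg.norm(mode)
    if norm == 0:
        raise DomainMotionError("degenerate hinge geometry: planted mode is zero")
    return (mode / norm).ravel()


def generate_hinge_trajectory(
    spec: HingeSpec,
) -> tuple[Trajectory, HingeGroundTruth]:
    """Toy trajectory with domain 1 moving along a planted hinge mode.

    Frame f: ``base + a_f · mode + noise`` with isotropic Gaussian noise of
    ``thermal_noise_sigma`` on every coordinate.  The ground truth records
    the mode, the amplitudes and the noiseless distances of the planted
    coupled pairs.
    """
    topology, residue_ranges = _build_topology(spec)
    base = topology.coordinates
    lo1, hi1 = residue_ranges[0]
    domain1_idx = np.flatnonzero(
        (topology.residue_numbers >= lo1) & (topology.residue_numbers <= hi1)
    )
    other_idx = np.setdiff1d(np.arange(topology.n_atoms), domain1_idx)
    # Hinge at the face of domain 1 nearest to domain 2.
    hinge_point = np.array(
        [base[domain1_idx][:, 0].max(), *base[domain1_idx][:, 1:].mean(axis=0)]
    )
    mode_full = _planted_hinge_mode(base, domain1_idx, hinge_point)
    mode_vectors = mode_full.reshape(-1, 3)

    amplitudes = spec.amplitudes()
    rng = np.random.default_rng(spec.seed)

    # Plant coupled interface pairs: domain-1 atom with the largest mode
    # displacement paired with the other-domain atom whose direction best
    # matches (sign +1) or opposes (−1) that displacement.
    pairs: list[tuple[int, int, int]] = []
    if spec.coupled_distance_signs:
        move_norms = np.linalg.norm(mode_vectors[domain1_idx], axis=1)
        strong = domain1_idx[move_norms >= 0.5 * move_norms.max()]
        for sign in spec.coupled_distance_signs:
            if sign not in (-1, 1):
                raise ValueError("coupled distance signs must be ±1")
            # d/da |x_a + a·u_a − x_b| at a=0 is u_a·unit(x_a − x_b); pick
            # the (a, b) pair whose derivative best matches the sign.
            best, best_score = None, -np.inf
            for a in strong:
                u = mode_vectors[a] / np.linalg.norm(mode_vectors[a])
                away = base[a] - base[other_idx]
                away /= np.linalg.norm(away, axis=1)[:, None]
                scores = sign * (away @ u)
                k = int(np.argmax(scores))
                if scores[k] > best_score:
                    best_score = scores[k]
                    best = (int(a), int(other_idx[k]))
            pairs.append((*best, sign))

    frames = np.empty((spec.n_frames, topology.n_atoms, 3))
    coupled = np.empty((len(pairs), spec.n_frames))
    for f, a_f in enumerate(amplitudes):
        clean = base + a_f * mode_vectors
        for p, (ia, ib, _) in enumerate(pairs):
            coupled[p, f] = np.linalg.norm(clean[ia] - clean[ib])
        noise = (
            rng.normal(0.0, spec.thermal_noise_sigma, size=clean.shape)
            if spec.thermal_noise_sigma > 0
            else 0.0
        )
        frames[f] = clean + noise

    trajectory = Trajectory(
        frames, 5.0 * np.arange(spec.n_frames, dtype=float), topology
    )
    spec_json = json.dumps(
        {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(spec).items()
        }
    )
    truth = HingeGroundTruth(
        mode_full=mode_full,
        domain1_atom_indices=domain1_idx,
        amplitudes=amplitudes,
        coupled_pairs=tuple(pairs),
        coupled_distances=coupled,
        domain_residue_ranges=tuple(residue_ranges),
        seed=spec.seed,
        spec_json=spec_json,
    )
    return trajectory, truth


# ---------------------------------------------------------------------------
# Boltzmann samples from 1D potentials under harmonic biases


@dataclass(frozen=True)
class PotentialSpec:
    """1D potential U(x): flat, harmonic ½a x², quartic double well, or table.

    ``parameters`` by form — harmonic: {"a": kJ/mol/nm²}; double_well:
    {"barrier_height": kJ/mol, "well_position": nm, "tilt": kJ/mol/nm};
    table: {"x": [...nm], "u": [...kJ/mol]} (linear interpolation).
    """

    form: str = "flat"
    parameters: dict = field(default_factory=dict)
    temperature: float = 300.0
    seed: int = 0

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return 0.5 * self.parameters["a"] * x**2
        if self.form == "double_well":
            h = self.parameters["barrier_height"]
            w = self.parameters["well_position"]
            tilt = self.parameters.get("tilt", 0.0)
            return h * ((x / w) ** 2 - 1.0) ** 2 + tilt * x
        if self.form == "table":
            return np.interp(x, self.parameters["x"], self.parameters["u"])
        raise ValueError(f"unknown potential form {self.form!r}")

    def force(self, x: np.ndarray) -> np.ndarray:
        """−dU/dx (analytic where available, else finite differences)."""
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return -self.parameters["a"] * x
        if self.form == "double_well":
            h = self.parameters["barrier_height"]
            w = self.parameters["well_position"]
            tilt = self.parameters.get("tilt", 0.0)
            return -(4.0 * h * x * ((x / w) ** 2 - 1.0) / w**2 + tilt)
        eps = 1e-6
        return -(self.energy(x + eps) - self.energy(x - eps)) / (2 * eps)


def _brownian_window(
    spec: PotentialSpec,
    center: float,
    spring_constant: float,
    n_samples: int,
    rng: np.random.Generator,
    step: float | None = None,
    burn_in: int | None = None,
    subsample: int = 10,
) -> np.ndarray:
    """Overdamped Euler–Maruyama sampling of exp(−β(U + bias)).

    Step size defaults to 0.1/(max curvature) in reduced units (γ = 1);
    burn-in defaults to 10 bias relaxation times.  Moves with unphysical
    energy jumps (> 20 kT) are counted; more than 1% of them aborts with
    advice to reduce the step.
    """
    kt = kt_kj_per_mol(spec.temperature)

    def total_energy(x):
        return spec.energy(x) + 0.5 * spring_constant * (x - center) ** 2

    def total_force(x):
        return spec.force(x) - spring_constant * (x - center)

    # Curvature scale: spring plus an upper estimate of |U''| near the center.
    probe = center + np.linspace(-0.5, 0.5, 101)
    curvature = np.max(np.abs(np.gradient(-spec.force(probe), probe)))
    stiffness = spring_constant + max(curvature, 1.0)
    if step is None:
        step = 0.1 / stiffness  # γ = 1 reduced units; kΔt/γ ≤ 0.1
    if burn_in is None:
        relaxation = 1.0 / (spring_constant * step) if spring_constant > 0 else 1000
        burn_in = int(10 * max(relaxation, 100))

    x = center
    bad_moves = 0
    total_moves = burn_in + n_samples * subsample
    noise_scale = np.sqrt(2.0 * kt * step)
    samples = np.empty(n_samples)
    filled = 0
    for move in range(total_moves):
        x_new = x + step * total_force(x) + noise_scale * rng.normal()
        if total_energy(x_new) - total_energy(x) > 20.0 * kt:
            bad_moves += 1
        x = x_new
        if move >= burn_in and (move - burn_in) % subsample == 0 and filled < n_samples:
            samples[filled] = x
            filled += 1
    if bad_moves > 0.01 * total_moves:
        raise DomainMotionError(
            f"Brownian step {step:.2e} too large: {bad_moves}/{total_moves} "
            "moves failed the energy sanity check; reduce the step size"
        )
    return samples


def sample_biased_windows(
    spec: PotentialSpec,
    centers,
    spring_constant: float = 100.0,
    n_samples: int = 10_000,
) -> list[UmbrellaWindow]:
    """Umbrella windows sampled from exp(−β(U(x) + ½k(x−c)²)).

    For flat and harmonic potentials the biased density is Gaussian and is
    sampled exactly; double-well and tabulated potentials are sampled by
    overdamped Brownian dynamics with recorded step and burn-in.  Centers
    and samples are in nm, the spring constant in kJ/mol/nm².
    """
    if spring_constant < 0:
        raise ValueError("spring_constant must be >= 0")
    kt = kt_kj_per_mol(spec.temperature)
    rng = np.random.default_rng(spec.seed)
    windows = []
    for center in np.atleast_1d(np.asarray(centers, dtype=float)):
        if spec.form == "flat":
            if spring_constant == 0:
                raise ValueError("flat potential with zero spring is unnormalizable")
            sigma = np.sqrt(kt / spring_constant)
            samples = rng.normal(center, sigma, size=n_samples)
        elif spec.form == "harmonic":
            a = spec.parameters["a"]
            if a + spring_constant <= 0:
                raise ValueError("total curvature must be positive")
            mean = spring_constant * center / (a + spring_constant)
            sigma = np.sqrt(kt / (a + spring_constant))
            samples = rng.normal(mean, sigma, size=n_samples)
        else:
            samples = _brownian_window(
                spec, center, spring_constant, n_samples, rng
            )
        windows.append(UmbrellaWindow(float(center), spring_constant, samples))
    return windows


# ---------------------------------------------------------------------------
# Sphere-overlap fixtures


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * np.pi * radius**3


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Analytic intersection volume of two spheres at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


@dataclass(frozen=True)
class OverlapFixture:
    """Single-sphere probe vs a translating receptor sphere."""

    trajectory: Trajectory  # receptor sphere moving along x
    probe: Structure  # fixed at the origin
    separations: np.ndarray  # Å per frame
    analytic_overlaps: np.ndarray  # Å³ per frame

    def write_sidecar(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "separations_A": self.separations.tolist(),
                    "analytic_overlaps_A3": self.analytic_overlaps.tolist(),
                }
            )
        )


def _single_sphere_structure(
    radius: float, position, name: str, residue_number: int
) -> Structure:
    atom = AtomRecord(
        atom_index=0,
        atom_name=name,
        element="C",
        residue_number=residue_number,
        residue_name="SPH",
        chain_id="X",
        is_hydrogen=False,
        vdw_radius=radius,
    )
    return Structure([atom], np.array([position], dtype=float))


def generate_overlap_fixture(
    separation_series, r_probe: float = 2.0, r_receptor: float = 2.0
) -> OverlapFixture:
    """Receptor sphere translating along x past a fixed probe sphere.

    The analytic sphere–sphere lens volume per frame is the ground truth
    the MC integrator is checked against.
    """
    separations = np.asarray(separation_series, dtype=float)
    if r_probe <= 0 or r_receptor <= 0:
        raise ValueError("radii must be positive")
    probe = _single_sphere_structure(r_probe, (0.0, 0.0, 0.0), "PRB", 1)
    receptor_topology = _single_sphere_structure(
        r_receptor, (separations[0], 0.0, 0.0), "REC", 2
    )
    frames = np.zeros((len(separations), 1, 3))
    frames[:, 0, 0] = separations
    trajectory = Trajectory(
        frames, np.arange(len(separations), dtype=float), receptor_topology
    )
    overlaps = np.array([lens_volume(r_probe, r_receptor, d) for d in separations])
    return OverlapFixture(trajectory, probe, separations, overlaps)
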