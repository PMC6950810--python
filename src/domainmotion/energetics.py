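"""Pairwise nonbonded interaction enthalpies between atom groups.

Per frame, the group–group interaction enthalpy is the sum over cross
pairs (a ∈ A, b ∈ B) within a real-space cutoff of the Coulomb term
f·qₐq_b/(ε_r·r) and the Lennard-Jones term 4ε[(σ/r)¹² − (σ/r)⁶] with
Lorentz–Berthelot combination (σ: arithmetic mean, ε: geometric mean).
A plain cutoff sum is used — no Ewald summation and no switching
function — which is the standard group-decomposition approximation for
interaction enthalpies; long-range electrostatic corrections beyond the
cutoff are not included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import A_PER_NM, COULOMB_CONSTANT_KJ_NM_E2
from .contacts_distances import DistanceSeries
from .exceptions import ParameterError, SelectionError
from .model_io import Selection, Trajectory

__all__ = [
    "NonbondedParams",
    "EnthalpySeries",
    "CorrelationSummary",
    "interaction_enthalpy",
    "enthalpy_distance_correlation",
    "correlation_summary",
]

_SINGULARITY_A = 0.1  # Å; pairs closer than this indicate a broken input


@dataclass(frozen=True)
class NonbondedParams:
    """Cutoff (Å), Coulomb prefactor (kJ·mol⁻¹·nm·e⁻²) and dielectric."""

    cutoff: float = 10.0
    coulomb_constant: float = COULOMB_CONSTANT_KJ_NM_E2
    relative_dielectric: float = 1.0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")
        if self.relative_dielectric < 1:
            raise ValueError("relative_dielectric must be >= 1")


@dataclass(frozen=True)
class EnthalpySeries:
    """Per-frame interaction enthalpy (kJ/mol) split into components."""

    coulomb: np.ndarray
    lennard_jones: np.ndarray
    label_a: str = ""
    label_b: str = ""

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.lennard_jones

    @property
    def values(self) -> np.ndarray:  # series protocol used by correlations
        return self.total

    def __len__(self) -> int:
        return len(self.coulomb)

    def to_tsv(self, path, times=None) -> None:
        with open(path, "w") as fh:
            head = "frame" if times is None else "time_ps"
            fh.write(f"{head}\tcoulomb_kJmol\tlj_kJmol\ttotal_kJmol\n")
            keys = range(len(self)) if times is None else times
            for k, c, l in zip(keys, self.coulomb, self.lennard_jones):
                fh.write(f"{k}\t{c:.6f}\t{l:.6f}\t{c + l:.6f}\n")


def _gather_params(trajectory: Trajectory, selection: Selection, what: str):
    charges = np.empty(len(selection))
    sigmas = np.empty(len(selection))
    epsilons = np.empty(len(selection))
    for k, i in enumerate(selection.atom_indices):
        atom = trajectory.topology.atoms[int(i)]
        if atom.partial_charge is None or atom.lj_sigma is None or atom.lj_epsilon is None:
            raise ParameterError(
                f"atom {atom.atom_name} of {atom.residue_name}{atom.residue_number} "
                f"in group {what} lacks charge/LJ parameters"
            )
        charges[k] = atom.partial_charge
        sigmas[k] = atom.lj_sigma
        epsilons[k] = atom.lj_epsilon
    return charges, sigmas, epsilons


def interaction_enthalpy(
    trajectory: Trajectory,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams = NonbondedParams(),
) -> EnthalpySeries:
    """Cutoff Coulomb + LJ cross-group interaction enthalpy per frame.

    Groups must be disjoint molecules/moieties so that every cross pair is
    a valid nonbonded pair (no intramolecular exclusions are applied).
    """
    if np.intersect1d(group_a.atom_indices, group_b.atom_indices).size:
        raise SelectionError("groups overlap; interaction groups must be disjoint")
    labels = (group_a.label, group_b.label)
    # Canonical group order makes the pair sum bitwise symmetric in (A, B).
    if int(group_a.atom_indices.min()) > int(group_b.atom_indices.min()):
        group_a, group_b = group_b, group_a
    qa, sa, ea = _gather_params(trajectory, group_a, "A")
    qb, sb, eb = _gather_params(trajectory, group_b, "B")
    # Lorentz–Berthelot combination over all cross pairs.
    sigma = 0.5 * (sa[:, None] + sb[None, :])
    epsilon = np.sqrt(ea[:, None] * eb[None, :])
    qq = qa[:, None] * qb[None, :]
    f = params.coulomb_constant / params.relative_dielectric

    coulomb = np.empty(trajectory.n_frames)
    lj = np.empty(trajectory.n_frames)
    ia, ib = group_a.atom_indices, group_b.atom_indices
    for frame in range(trajectory.n_frames):
        coords = trajectory.frame_coordinates[frame]
        r = cdist(coords[ia], coords[ib])  # Å
        if (r < _SINGULARITY_A).any():
            i, j = np.unravel_index(np.argmin(r), r.shape)
            raise ParameterError(
                f"near-singular pair distance {r[i, j]:.4f} Å between group-A "
                f"atom {int(ia[i])} and group-B atom {int(ib[j])} at frame {frame}"
            )
        within = r <= params.cutoff
        r_nm = r / A_PER_NM
        with np.errstate(divide="ignore"):
            coulomb_terms = np.where(within, f * qq / r_nm, 0.0)
            sr6 = np.where(within, (sigma / r) ** 6, 0.0)
        lj_terms = 4.0 * epsilon * (sr6**2 - sr6)
        coulomb[frame] = coulomb_terms.sum()
        lj[frame] = np.where(within, lj_terms, 0.0).sum()
    return EnthalpySeries(coulomb, lj, *labels)


def enthalpy_distance_correlation(
    enthalpy: EnthalpySeries | np.ndarray,
    distance: DistanceSeries | np.ndarray,
) -> float:
    """Pearson correlation between an enthalpy series and a distance series."""
    x = np.asarray(getattr(enthalpy, "values", enthalpy), dtype=float)
    y = np.asarray(getattr(distance, "values", distance), dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CorrelationSummary:
    """Mean and sample SD of per-simulation correlation coefficients."""

    coefficients: np.ndarray
    mean: float
    sd: float  # NaN (flagged undefined) for a single coefficient

    @property
    def sd_defined(self) -> bool:
        return not np.isnan(self.sd)


def correlation_summary(coefficients) -> CorrelationSummary:
    """Mean and sample standard deviation (n−1) of correlation coefficients."""
    coeffs = np.asarray(list(coefficients), dtype=float)
    if coeffs.size == 0:
        raise ValueError("no correlation coefficients given")
    if np.any(np.abs(coeffs) > 1 + 1e-12):
        raise ValueError("correlation coefficients must lie in [-1, 1]")
    mean = float(coeffs.mean())
    sd = float(np.std(coeffs, ddof=1)) if coeffs.size > 1 else float("nan")
    return CorrelationSummary(coeffs, mean, sd)
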