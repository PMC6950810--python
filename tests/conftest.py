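"""Shared fixtures: tiny structures and synthetic trajectories."""

import numpy as np
import pytest

from domainmotion.model_io import AtomRecord, Selection, Structure, Trajectory
from domainmotion.synthetic_data import HingeSpec, generate_hinge_trajectory


def make_structure(positions, names=None, residues=None, chain="A",
                   elements=None, radii=None, charges=None, sigmas=None,
                   epsilons=None, residue_names=None):
    """Build a Structure from raw arrays with sensible defaults."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = names or ["CA"] * n
    residues = residues if residues is not None else list(range(1, n + 1))
    elements = elements or ["C"] * n
    residue_names = residue_names or ["GLY"] * n
    atoms = []
    for i in range(n):
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=names[i],
                element=elements[i],
                residue_number=residues[i],
                residue_name=residue_names[i],
                chain_id=chain,
                is_hydrogen=elements[i] in ("H", "D"),
                vdw_radius=None if radii is None else radii[i],
                partial_charge=None if charges is None else charges[i],
                lj_sigma=None if sigmas is None else sigmas[i],
                lj_epsilon=None if epsilons is None else epsilons[i],
            )
        )
    return Structure(atoms, positions)


def make_trajectory(frames, topology, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames, dt * np.arange(frames.shape[0]), topology)


def all_atoms(structure):
    return Selection(np.arange(structure.n_atoms), "all")


@pytest.fixture(scope="session")
def hinge():
    """Small planted-hinge fixture shared by PCA/RMSF/pipeline tests."""
    spec = HingeSpec(
        residues_per_domain=20, n_frames=300, seed=11,
        coupled_distance_signs=(1, -1),
    )
    return generate_hinge_trajectory(spec)


@pytest.fixture(scope="session")
def hinge_selections(hinge):
    from domainmotion.model_io import select_residues

    trajectory, truth = hinge
    ranges = truth.domain_residue_ranges
    fit_sel = select_residues(
        trajectory.topology, "A", [ranges[1], ranges[2]],
        atom_names={"N", "CA", "C"}, label="core",
    )
    analysis_sel = select_residues(
        trajectory.topology, "A", [ranges[0]], label="mobile-domain"
    )
    return fit_sel, analysis_sel
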