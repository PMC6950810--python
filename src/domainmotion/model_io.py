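"""Structures, trajectories, atom selections and file IO.

Lengths are Å throughout.  Residue numbers are 1-based as in PDB files;
atom indices are 0-based and internal.  PDB reading/writing is backed by
biotite; the plain per-frame coordinate-table dialect (see
:func:`read_trajectory`) is this package's own lightweight text format for
synthetic trajectories.
"""

from __future__ import annotations

import dataclasses
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import BONDI_RADII_A
from .exceptions import ParseError, SelectionError, ParameterError

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory_table",
    "select_residues",
    "load_parameter_table",
    "assign_parameters",
    "fetch_rcsb",
]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity and (optional) nonbonded parameters.

    ``vdw_radius`` and ``lj_sigma`` are Å, ``partial_charge`` elementary
    charges, ``lj_epsilon`` kJ/mol, ``mass`` u.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_hydrogen: bool
    vdw_radius: float | None = None
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.vdw_radius is not None and not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")


class Structure:
    """An ordered set of atoms with one coordinate per atom (Å)."""

    def __init__(self, atoms: Sequence[AtomRecord], coordinates: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinate array shape {coordinates.shape} does not match "
                f"{len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coordinates)):
            raise ValueError("coordinates contain non-finite values")
        indices = [a.atom_index for a in atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom_index values are not unique")
        self.atoms: list[AtomRecord] = list(atoms)
        self.coordinates = coordinates
        # Vectorized views used by selections and distance code.
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.residue_numbers = np.array(
            [a.residue_number for a in self.atoms], dtype=int
        )
        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.is_hydrogen = np.array([a.is_hydrogen for a in self.atoms], dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coordinates(self, coordinates: np.ndarray) -> "Structure":
        """New Structure sharing this topology with replaced coordinates."""
        return Structure(self.atoms, coordinates)

    def vdw_radii(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Radii for the given atoms; raises if any atom lacks one."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        radii = np.empty(len(idx), dtype=float)
        for k, i in enumerate(idx):
            r = self.atoms[int(i)].vdw_radius
            if r is None:
                a = self.atoms[int(i)]
                raise ParameterError(
                    f"atom {a.atom_name} of {a.residue_name}{a.residue_number} "
                    f"(chain {a.chain_id}) has no van der Waals radius"
                )
            radii[k] = r
        return radii


class Trajectory:
    """Frames × atoms × 3 coordinates (Å) over a shared topology."""

    def __init__(
        self,
        frame_coordinates: np.ndarray,
        frame_times: np.ndarray,
        topology: Structure,
    ):
        frame_coordinates = np.asarray(frame_coordinates, dtype=float)
        frame_times = np.asarray(frame_times, dtype=float)
        if frame_coordinates.ndim != 3 or frame_coordinates.shape[2] != 3:
            raise ValueError("frame_coordinates must have shape (F, N, 3)")
        if frame_coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frames carry {frame_coordinates.shape[1]} atoms but topology "
                f"has {topology.n_atoms}"
            )
        if frame_times.shape != (frame_coordinates.shape[0],):
            raise ValueError("frame_times length must equal frame count")
        if len(frame_times) > 1 and not np.all(np.diff(frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.frame_coordinates = frame_coordinates
        self.frame_times = frame_times
        self.topology = topology

    @property
    def n_frames(self) -> int:
        return self.frame_coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frame_coordinates.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frame_coordinates[i])


@dataclass(frozen=True)
class Selection:
    """Ordered 0-based atom indices with a human-readable label."""

    atom_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection contains duplicate atom indices")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def validate(self, structure: Structure) -> None:
        idx = self.atom_indices
        if len(idx) and (idx.min() < 0 or idx.max() >= structure.n_atoms):
            raise SelectionError(
                f"selection '{self.label}' has indices outside 0..{structure.n_atoms - 1}"
            )


# ---------------------------------------------------------------------------
# PDB IO


def _check_pdb_coordinate_lines(path: Path) -> None:
    """Pre-scan so a malformed ATOM/HETATM record is reported by line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}: line {lineno}: truncated ATOM/HETATM record"
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed coordinates in "
                        f"ATOM/HETATM record"
                    ) from exc


def _records_from_atom_array(array: struc.AtomArray) -> list[AtomRecord]:
    records = []
    for i in range(array.array_length()):
        element = str(array.element[i]).upper()
        records.append(
            AtomRecord(
                atom_index=i,
                atom_name=str(array.atom_name[i]),
                element=element,
                residue_number=int(array.res_id[i]),
                residue_name=str(array.res_name[i]),
                chain_id=str(array.chain_id[i]),
                is_hydrogen=element in _HYDROGEN_ELEMENTS,
            )
        )
    return records


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file; multi-model files yield the first model.

    Alternate locations keep the highest-occupancy conformer.  Hydrogens
    are flagged from the element column.
    """
    path = Path(path)
    _check_pdb_coordinate_lines(path)
    pdb = PDBFile.read(str(path))
    try:
        array = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises for empty/defective models
        raise ParseError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise ParseError(f"{path}: model contains no atoms")
    return Structure(_records_from_atom_array(array), np.asarray(array.coord, float))


def _atom_array_from_structure(structure: Structure) -> struc.AtomArray:
    n = structure.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(structure.coordinates, dtype=np.float32)
    array.chain_id = structure.chain_ids
    array.res_id = structure.residue_numbers
    array.res_name = structure.residue_names
    array.atom_name = structure.atom_names
    array.element = np.array([a.element for a in structure.atoms])
    array.hetero = np.zeros(n, dtype=bool)
    return array


def write_pdb(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Trajectory IO


def _read_coordinate_table(
    path: Path, topology: Structure
) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "#atoms" or header[2] != "dt_ps":
            raise ParseError(
                f"{path}: expected header '#atoms N dt_ps X', got {' '.join(header)!r}"
            )
        n_atoms = int(header[1])
        dt_ps = float(header[3])
        if n_atoms != topology.n_atoms:
            raise ParseError(
                f"{path}: header declares {n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
        frames = []
        for frame_index, line in enumerate(fh):
            if not line.strip():
                continue
            values = np.fromstring(line, sep=" ")
            if values.size != 3 * n_atoms:
                raise ParseError(
                    f"{path}: frame {frame_index} has {values.size // 3} atoms, "
                    f"expected {n_atoms}"
                )
            frames.append(values.reshape(n_atoms, 3))
    if not frames:
        raise ParseError(f"{path}: no frames")
    coords = np.stack(frames)
    times = dt_ps * np.arange(len(frames), dtype=float)
    return coords, times


def _read_multimodel_pdb(
    path: Path, topology: Structure, stride_ps: float
) -> tuple[np.ndarray, np.ndarray]:
    # Count atoms per model first so mismatches name the frame.
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model = True
                current = 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM", "HETATM")):
                current += 1
    if not counts:  # single-model file without MODEL records
        counts = [current]
    for frame_index, c in enumerate(counts):
        if c != topology.n_atoms:
            raise ParseError(
                f"{path}: frame {frame_index} has {c} atoms, expected "
                f"{topology.n_atoms}"
            )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(altloc="occupancy")
    if isinstance(stack, struc.AtomArray):
        coords = np.asarray(stack.coord, float)[None, :, :]
    else:
        coords = np.asarray(stack.coord, float)
    times = stride_ps * np.arange(coords.shape[0], dtype=float)
    return coords, times


def read_trajectory(
    path: str | Path, topology: Structure, stride_ps: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB or a coordinate-table file as a Trajectory.

    The coordinate-table dialect is: a header line ``#atoms N dt_ps X``
    followed by one whitespace-separated line of 3N floats per frame.
    Multi-model PDB frames are assigned times 0, Δt, 2Δt … with
    Δt = ``stride_ps``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#atoms"):
        coords, times = _read_coordinate_table(path, topology)
    else:
        coords, times = _read_multimodel_pdb(path, topology, stride_ps)
    return Trajectory(coords, times, topology)


def write_trajectory_table(trajectory: Trajectory, path: str | Path) -> None:
    """Write the coordinate-table dialect (times must be evenly strided)."""
    times = trajectory.frame_times
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    with open(path, "w") as fh:
        fh.write(f"#atoms {trajectory.n_atoms} dt_ps {dt:g}\n")
        for frame in trajectory.frame_coordinates:
            fh.write(" ".join(f"{v:.6f}" for v in frame.ravel()) + "\n")


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    pdb = PDBFile()
    n = trajectory.n_atoms
    stack = struc.AtomArrayStack(trajectory.n_frames, n)
    template = _atom_array_from_structure(trajectory.topology)
    for name in template.get_annotation_categories():
        stack.set_annotation(name, template.get_annotation(name))
    stack.coord = np.asarray(trajectory.frame_coordinates, dtype=np.float32)
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections


def select_residues(
    structure: Structure,
    chain: str,
    residue_ranges: Iterable[tuple[int, int]],
    atom_names: Iterable[str] | None = None,
    heavy_only: bool = False,
    label: str = "",
) -> Selection:
    """Select atoms by chain, inclusive 1-based residue ranges and name.

    Output order is structure order regardless of the order the ranges are
    given in.  An empty result raises, preventing silent no-op selections.
    """
    ranges = list(residue_ranges)
    if not ranges:
        raise SelectionError("residue_ranges must be non-empty")
    mask = structure.chain_ids == chain
    in_range = np.zeros(structure.n_atoms, dtype=bool)
    for lo, hi in ranges:
        in_range |= (structure.residue_numbers >= lo) & (
            structure.residue_numbers <= hi
        )
    mask &= in_range
    if atom_names is not None:
        mask &= np.isin(structure.atom_names, list(atom_names))
    if heavy_only:
        mask &= ~structure.is_hydrogen
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(
            f"selection matched no atoms (chain {chain!r}, ranges {ranges}, "
            f"atom_names {None if atom_names is None else sorted(atom_names)})"
        )
    if not label:
        label = f"{chain}:" + ",".join(f"{lo}-{hi}" for lo, hi in ranges)
    return Selection(indices, label)


# ---------------------------------------------------------------------------
# Parameter tables

PARAMETER_COLUMNS = [
    "residue_name",
    "atom_name",
    "element",
    "vdw_radius_A",
    "charge_e",
    "sigma_A",
    "epsilon_kJmol",
]


def load_parameter_table(path: str | Path) -> pd.DataFrame:
    """Load a TSV parameter table (vdW radius, charge, LJ per atom type)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PARAMETER_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: parameter table lacks columns {missing}")
    return table


def assign_parameters(
    structure: Structure, table: pd.DataFrame | None = None
) -> Structure:
    """Return a copy with radii/charges/LJ filled from a parameter table.

    Lookup is by (residue_name, atom_name); atoms without a table entry fall
    back to the element-keyed Bondi radius (charge and LJ left unset).
    """
    by_key: dict[tuple[str, str], pd.Series] = {}
    if table is not None:
        for _, row in table.iterrows():
            by_key[(str(row.residue_name), str(row.atom_name))] = row
    new_atoms = []
    for atom in structure.atoms:
        row = by_key.get((atom.residue_name, atom.atom_name))
        if row is not None:
            new_atoms.append(
                dataclasses.replace(
                    atom,
                    vdw_radius=float(row.vdw_radius_A),
                    partial_charge=float(row.charge_e),
                    lj_sigma=float(row.sigma_A),
                    lj_epsilon=float(row.epsilon_kJmol),
                )
            )
        else:
            radius = BONDI_RADII_A.get(atom.element)
            new_atoms.append(dataclasses.replace(atom, vdw_radius=radius))
    return Structure(new_atoms, structure.coordinates)


def fetch_rcsb(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry from RCSB (requires network access)."""
    dest = Path(dest_dir) / f"{pdb_id.lower()}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=30) as response:
        dest.write_bytes(response.read())
    return dest
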