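"""End-to-end analysis pipeline driven by a single YAML config.

One config = one manifest = one reproducible run: every enabled stage
writes its TSV outputs into the output directory and the manifest records
package version, seeds, parameters and input checksums.  Stage order
follows the analysis flow: contacts → rmsf → pca → landscape → distance →
overlap → enthalpy → wham.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contacts_distances import contact_occupancy, residue_distance
from .exceptions import ConfigError
from .mc_volume import MCVolumeConfig, clash_scan
from .model_io import (
    Selection,
    Structure,
    assign_parameters,
    load_parameter_table,
    read_pdb,
    read_trajectory,
    select_residues,
)
from .pca_landscape import build_pca, density_landscape, project
from .superpose import rmsf
from .wham_pmf import bootstrap_errors, read_window_metadata

STAGE_ORDER = [
    "contacts",
    "rmsf",
    "pca",
    "distance",
    "landscape",
    "overlap",
    "enthalpy",
    "wham",
]


def parse_selection_string(text: str) -> dict:
    """Parse ``chain:start-end[,start-end][:NAME,NAME]`` selection syntax."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ConfigError(f"bad selection string {text!r}")
    chain = parts[0]
    ranges = []
    for chunk in parts[1].split(","):
        if "-" in chunk:
            lo, hi = chunk.split("-")
        else:
            lo = hi = chunk
        ranges.append((int(lo), int(hi)))
    atom_names = parts[2].split(",") if len(parts) == 3 else None
    return {"chain": chain, "residue_ranges": ranges, "atom_names": atom_names}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    trajectory: str
    topology: str
    output_dir: str
    stages: list[str]
    selections: dict[str, str] = field(default_factory=dict)
    reference: str | None = None
    stride_ps: float = 5.0
    seed: int = 0
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"trajectory", "topology", "output_dir", "stages", "selections",
                 "reference", "stride_ps", "seed"}
        stage_params = {k: v for k, v in raw.items() if k not in known}
        config = cls(
            trajectory=raw.get("trajectory", ""),
            topology=raw.get("topology", ""),
            output_dir=raw.get("output_dir", "."),
            stages=list(raw.get("stages", [])),
            selections=dict(raw.get("selections", {})),
            reference=raw.get("reference"),
            stride_ps=float(raw.get("stride_ps", 5.0)),
            seed=int(raw.get("seed", 0)),
            stage_params=stage_params,
        )
        config.validate()
        return config

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGE_ORDER:
                raise ConfigError(f"unknown stage {stage!r}")
        for stage, needed in {
            "rmsf": ["fit", "analysis"],
            "pca": ["fit", "analysis"],
        }.items():
            if stage in self.stages:
                for label in needed:
                    if label not in self.selections:
                        raise ConfigError(
                            f"stage {stage!r} references undefined selection "
                            f"label {label!r}"
                        )
        for stage in self.stages:
            params = self.stage_params.get(stage, {})
            for key, value in params.items():
                if key.endswith("_selection") and value not in self.selections:
                    raise ConfigError(
                        f"stage {stage!r} references undefined selection "
                        f"label {value!r}"
                    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_selection(structure: Structure, config: PipelineConfig, label: str) -> Selection:
    if label not in config.selections:
        raise ConfigError(f"undefined selection label {label!r}")
    spec = parse_selection_string(config.selections[label])
    return select_residues(structure, label=label, **spec)


class _StageRunner:
    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.topology = read_pdb(config.topology)
        self.trajectory = read_trajectory(
            config.trajectory, self.topology, config.stride_ps
        )
        self.reference = (
            read_pdb(config.reference) if config.reference else self.topology
        )
        self.pca_model = None
        self.projection = None
        self.distance = None
        self.outputs: list[str] = []

    def _write(self, name: str, writer) -> None:
        final = self.outdir / name
        partial = final.with_suffix(final.suffix + ".partial")
        writer(partial)
        partial.rename(final)
        self.outputs.append(name)

    def run_stage(self, stage: str) -> None:
        getattr(self, f"stage_{stage}")(self.config.stage_params.get(stage, {}))

    def stage_contacts(self, params: dict) -> None:
        residue_sel = _resolve_selection(
            self.topology, self.config, params.get("residue_selection", "contact_residues")
        )
        target_sel = _resolve_selection(
            self.topology, self.config, params.get("target_selection", "contact_target")
        )
        series = contact_occupancy(
            self.trajectory, residue_sel, target_sel,
            cutoff=float(params.get("cutoff", 5.0)),
        )

        def write(path):
            with open(path, "w") as fh:
                fh.write("pair\toccupancy\tcutoff_A\n")
                fh.write(f"{series.pair_label}\t{series.occupancy:.6f}\t{series.cutoff}\n")

        self._write("contacts.tsv", write)

    def stage_rmsf(self, params: dict) -> None:
        fit_sel = _resolve_selection(self.topology, self.config, "fit")
        analysis_sel = _resolve_selection(self.topology, self.config, "analysis")
        profile = rmsf(self.trajectory, fit_sel, analysis_sel)
        self._write("rmsf.tsv", profile.to_tsv)

    def stage_pca(self, params: dict) -> None:
        fit_sel = _resolve_selection(self.topology, self.config, "fit")
        analysis_sel = _resolve_selection(self.topology, self.config, "analysis")
        model = build_pca(self.trajectory, self.reference, fit_sel, analysis_sel)
        self.pca_model = model
        component = int(params.get("component", 0))
        self.projection = project(model, self.trajectory, component)

        def write_eigenvalues(path):
            with open(path, "w") as fh:
                fh.write("component\teigenvalue_A2\n")
                for k, v in enumerate(model.eigenvalues[:20]):
                    fh.write(f"{k}\t{v:.8f}\n")

        self._write("pca_eigenvalues.tsv", write_eigenvalues)
        self._write(
            "projection.tsv",
            lambda p: self.projection.to_tsv(p, self.trajectory.frame_times),
        )

    def stage_distance(self, params: dict) -> None:
        a = params.get("a")
        b = params.get("b")
        if not a or not b:
            raise ConfigError("distance stage needs 'a' and 'b' atoms 'chain:res:name'")

        def atom(text):
            chain, number, name = text.split(":")
            return (chain, int(number), name)

        self.distance = residue_distance(self.trajectory, atom(a), atom(b))
        self._write(
            "distance.tsv",
            lambda p: self.distance.to_tsv(p, self.trajectory.frame_times),
        )

    def stage_landscape(self, params: dict) -> None:
        if self.projection is None or self.distance is None:
            raise ConfigError(
                "landscape stage needs the pca and distance stages enabled first"
            )
        bins = int(params.get("bins", 50))
        landscape = density_landscape(self.projection, self.distance, bins, bins)
        self._write("landscape.tsv", landscape.to_tsv)

    def stage_overlap(self, params: dict) -> None:
        probe_path = params.get("probe")
        if not probe_path:
            raise ConfigError("overlap stage needs a 'probe' PDB path")
        table = (
            load_parameter_table(params["parameter_table"])
            if "parameter_table" in params
            else None
        )
        probe = assign_parameters(read_pdb(probe_path), table)
        receptor = assign_parameters(self.topology, table)
        trajectory = self.trajectory
        trajectory = type(trajectory)(
            trajectory.frame_coordinates, trajectory.frame_times, receptor
        )
        fit_sel = _resolve_selection(
            self.topology, self.config, params.get("fit_selection", "fit")
        )
        config = MCVolumeConfig(
            n_points=int(params.get("n_points", 200_000)), seed=self.config.seed
        )
        results = clash_scan(
            trajectory, fit_sel, probe, self.reference,
            stride=int(params.get("stride", 1)), config=config,
        )

        def write(path):
            with open(path, "w") as fh:
                fh.write("time_ps\tv_a_A3\tv_b_A3\tv_ab_A3\tv_overlap_A3\tse_A3\n")
                for r in results:
                    fh.write(
                        f"{r.time_ps}\t{r.v_a:.4f}\t{r.v_b:.4f}\t{r.v_ab:.4f}"
                        f"\t{r.v_overlap:.4f}\t{r.mc_standard_error:.4f}\n"
                    )

        self._write("overlap.tsv", write)

    def stage_enthalpy(self, params: dict) -> None:
        from .energetics import NonbondedParams, interaction_enthalpy

        table = load_parameter_table(params["parameter_table"])
        topology = assign_parameters(self.topology, table)
        trajectory = type(self.trajectory)(
            self.trajectory.frame_coordinates, self.trajectory.frame_times, topology
        )
        group_a = _resolve_selection(topology, self.config, params.get("group_a", "group_a"))
        group_b = _resolve_selection(topology, self.config, params.get("group_b", "group_b"))
        series = interaction_enthalpy(
            trajectory, group_a, group_b,
            NonbondedParams(cutoff=float(params.get("cutoff", 10.0))),
        )
        self._write(
            "enthalpy.tsv", lambda p: series.to_tsv(p, self.trajectory.frame_times)
        )

    def stage_wham(self, params: dict) -> None:
        meta = params.get("meta")
        if not meta:
            raise ConfigError("wham stage needs a 'meta' window-metadata path")
        windows = read_window_metadata(meta, discard=int(params.get("discard", 0)))
        profile = bootstrap_errors(
            windows,
            n_bootstrap=int(params.get("bootstrap", 300)),
            seed=self.config.seed,
            temperature=float(params.get("temperature", 300.0)),
            n_bins=int(params.get("bins", 100)),
        )
        self._write("pmf.tsv", profile.to_tsv)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(config, outdir)
    manifest = {
        "package": "domainmotion",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "parameters": {
            "selections": config.selections,
            "stride_ps": config.stride_ps,
            **config.stage_params,
        },
        "inputs": {},
        "outputs": [],
    }
    for path in [config.trajectory, config.topology, config.reference]:
        if path:
            manifest["inputs"][str(path)] = _sha256(Path(path))
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        try:
            runner.run_stage(stage)
        except Exception as exc:
            raise ConfigError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    manifest["outputs"] = runner.outputs
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
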