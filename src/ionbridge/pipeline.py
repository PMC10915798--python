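"""Configuration, manifest bookkeeping and stage orchestration.

A single YAML config drives the full chain.  Stages run in dependency order
(simulate feeds everything else); each output table carries the config hash
so reruns are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adsorption import (
    average_contacts,
    bai_distribution,
    compute_bai,
    contact_count_matrix,
    species_average_bai,
    surface_rdf,
)
from .core_model import (
    ExperimentManifest,
    MolecularSystem,
    SelectionGroup,
    Trajectory,
    read_manifest,
    read_structure,
    read_trajectory,
)
from .dimer_analysis import distance_timeseries, profile_from_runs
from .electrostatics import detect_overscreening, fit_screening_length, profile_from_rdfs
from .kinetics import bridge_lifetimes, build_contact_series, survival_probability
from .structure_metrics import time_averaged_sasa
from .synthetic_data import (
    IonSpeciesSpec,
    SyntheticSpec,
    generate_equilibrium_system,
    generate_two_protein_system,
    sample_equilibrium_frames,
    simulate_two_protein_system,
    write_fixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "summarize_manifest",
    "reference_manifest",
    "run_pipeline",
    "load_selections",
]

STAGES = ("simulate", "rdf", "bai", "zeff", "survival", "bridges", "dimer", "manifest")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Validated run configuration (paths, physical parameters, stages)."""

    stages: list[str] = field(default_factory=list)
    structure: str | None = None
    trajectory: str | None = None
    selections: str | None = None
    manifest: str | None = None
    out_dir: str = "ionbridge_out"
    temperature: float = 300.0
    contact_cutoff: float = 0.4
    rdf_bin_width: float = 0.005
    rdf_r_max: float = 2.5
    dimer_bin_width: float = 0.025
    dimer_r_max: float = 3.0
    z_protein: float | None = None
    seed: int = 0
    skip: int | None = None
    gap_tolerance: int = 0
    max_lag_ps: float | None = None
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("contact_cutoff", "rdf_bin_width", "rdf_r_max", "dimer_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; expected a subset of {STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {k: v for k, v in self.__dict__.items()}

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Manifest bookkeeping
# ---------------------------------------------------------------------------

def summarize_manifest(manifest: ExperimentManifest) -> tuple[int, float]:
    """(total number of runs, cumulative simulated time in ns)."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    total_runs = sum(row.n_runs for row in manifest.rows)
    cumulative_ns = float(sum(row.n_runs * row.run_ns for row in manifest.rows))
    return total_runs, cumulative_ns


def reference_manifest() -> ExperimentManifest:
    """The packaged simulation-campaign manifest (20 systems)."""
    with resources.as_file(
        resources.files("ionbridge").joinpath("data/reference_manifest.tsv")
    ) as path:
        return read_manifest(path)


# ---------------------------------------------------------------------------
# Selection loading
# ---------------------------------------------------------------------------

def load_selections(
    path: str | Path, system: MolecularSystem
) -> tuple[dict[str, SelectionGroup], dict[str, dict[str, list[int]]]]:
    """Load a selections YAML (1-based atom ids on disk -> 0-based groups)."""
    raw = yaml.safe_load(Path(path).read_text())
    groups: dict[str, SelectionGroup] = {}
    for entry in raw.get("groups", []):
        group = SelectionGroup(
            name=entry["name"],
            atom_ids=frozenset(i - 1 for i in entry["atom_ids"]),
            role=entry["role"],
        )
        group.validate_against(system)
        groups[group.name] = group
    ion_molecules = {
        species: {ion: [i - 1 for i in atoms] for ion, atoms in molecules.items()}
        for species, molecules in raw.get("ion_molecules", {}).items()
    }
    return groups, ion_molecules


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# config={config_hash}\n")
        df.to_csv(handle, sep="\t", index=False)


class _RunContext:
    """Lazily loaded inputs shared between stages."""

    def __init__(self, config: AnalysisConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self._system: MolecularSystem | None = None
        self._trajectory: Trajectory | None = None
        self._selections: tuple[dict, dict] | None = None

    def _structure_path(self) -> Path:
        if self.config.structure:
            return Path(self.config.structure)
        candidate = self.out_dir / "fixture" / "structure.pdb"
        if candidate.exists():
            return candidate
        raise PipelineError(
            "stage needs a structure: set 'structure' in the config or run 'simulate' first"
        )

    def _trajectory_path(self) -> Path:
        if self.config.trajectory:
            return Path(self.config.trajectory)
        candidate = self.out_dir / "fixture" / "trajectory.txt"
        if candidate.exists():
            return candidate
        raise PipelineError(
            "stage needs a trajectory: set 'trajectory' in the config or run 'simulate' first"
        )

    def _selections_path(self) -> Path:
        if self.config.selections:
            return Path(self.config.selections)
        candidate = self.out_dir / "fixture" / "selections.yaml"
        if candidate.exists():
            return candidate
        raise PipelineError(
            "stage needs selections: set 'selections' in the config or run 'simulate' first"
        )

    @property
    def system(self) -> MolecularSystem:
        if self._system is None:
            self._system = read_structure(self._structure_path())
        return self._system

    @property
    def trajectory(self) -> Trajectory:
        if self._trajectory is None:
            self._trajectory = read_trajectory(self._trajectory_path(), self.system)
        return self._trajectory

    @property
    def selections(self) -> tuple[dict[str, SelectionGroup], dict]:
        if self._selections is None:
            self._selections = load_selections(self._selections_path(), self.system)
        return self._selections

    def protein_group(self) -> SelectionGroup:
        groups, _ = self.selections
        if "protein_A" not in groups:
            raise PipelineError("selections define no protein_A group")
        return groups["protein_A"]

    def ion_groups(self) -> dict[str, SelectionGroup]:
        groups, _ = self.selections
        return {
            name: g
            for name, g in groups.items()
            if g.role in ("buffer_state", "cation", "anion")
        }


def _spec_from_config(config: AnalysisConfig) -> SyntheticSpec:
    raw = dict(config.simulate)
    species = tuple(
        IonSpeciesSpec(**entry) for entry in raw.pop("ion_species", [])
    )
    raw.setdefault("seed", config.seed)
    return SyntheticSpec(ion_species=species, **raw)


def _stage_simulate(ctx: _RunContext) -> None:
    spec = _spec_from_config(ctx.config)
    if spec.mode == "equilibrium":
        system = generate_equilibrium_system(spec)
        trajectory = sample_equilibrium_frames(spec, system)
    elif spec.mode == "two_protein":
        system = generate_two_protein_system(spec)
        trajectory = simulate_two_protein_system(spec, system)
    else:
        raise PipelineError("simulate: telegraph mode produces no trajectory; use the API")
    write_fixture(system, trajectory, ctx.out_dir / "fixture")


def _stage_rdf(ctx: _RunContext) -> None:
    cfg = ctx.config
    protein = ctx.protein_group()
    for name, group in ctx.ion_groups().items():
        profile = surface_rdf(
            ctx.trajectory,
            protein,
            group,
            ctx.system.box_length,
            bin_width=cfg.rdf_bin_width,
            r_max=cfg.rdf_r_max,
            skip=cfg.skip,
        )
        df = pd.DataFrame(
            {"r_nm": profile.bin_edges[:-1], "density_per_nm": profile.density}
        )
        _write_tsv(df, ctx.out_dir / f"rdf_{name}.tsv", cfg.config_hash())


def _stage_bai(ctx: _RunContext) -> None:
    cfg = ctx.config
    protein = ctx.protein_group()
    residue_atoms = ctx.system.residue_atom_indices(protein.indices())
    residue_names = {
        ctx.system.atoms[int(v[0])].residue_index: ctx.system.atoms[int(v[0])].residue_name
        for v in residue_atoms.values()
    }
    tables = []
    for name, group in ctx.ion_groups().items():
        matrix = contact_count_matrix(
            ctx.trajectory,
            residue_atoms,
            residue_names,
            group,
            ctx.system.box_length,
            cutoff=cfg.contact_cutoff,
            skip=cfg.skip or 0,
        )
        n_avg = average_contacts([matrix.counts])
        tables.append(
            pd.DataFrame(
                {
                    "residue_index": matrix.residue_indices,
                    "residue_name": matrix.residue_names,
                    "state": name,
                    "n_avg": n_avg,
                }
            )
        )
    if not tables:
        raise PipelineError("bai: no ion groups in the selections")
    bai = compute_bai(pd.concat(tables, ignore_index=True), temperature=cfg.temperature)
    _write_tsv(bai.table, ctx.out_dir / "bai_per_residue.tsv", cfg.config_hash())
    prot_idx = protein.indices()
    sub_atoms = [ctx.system.atoms[int(i)] for i in prot_idx]
    sub_system = MolecularSystem(atoms=sub_atoms, box_length=ctx.system.box_length)
    sub_traj = Trajectory(
        times=ctx.trajectory.times,
        coordinates=ctx.trajectory.coordinates[:, prot_idx, :],
    )
    sasa = time_averaged_sasa(sub_traj, sub_system, stride=max(1, sub_traj.n_frames // 5))
    species = species_average_bai(bai, sasa)
    _write_tsv(species, ctx.out_dir / "bai_per_species.tsv", cfg.config_hash())
    edges, p = bai_distribution(bai)
    _write_tsv(
        pd.DataFrame({"bai_kT": edges[:-1], "p": p}),
        ctx.out_dir / "bai_distribution.tsv",
        cfg.config_hash(),
    )


def _stage_zeff(ctx: _RunContext) -> None:
    cfg = ctx.config
    protein = ctx.protein_group()
    z_protein = (
        cfg.z_protein
        if cfg.z_protein is not None
        else float(sum(ctx.system.atoms[int(i)].formal_charge for i in protein.indices()))
    )
    species_rdfs = {}
    for name, group in ctx.ion_groups().items():
        charge = ctx.system.atoms[int(group.indices()[0])].formal_charge
        profile = surface_rdf(
            ctx.trajectory,
            protein,
            group,
            ctx.system.box_length,
            bin_width=cfg.rdf_bin_width,
            r_max=cfg.rdf_r_max,
            skip=cfg.skip,
        )
        species_rdfs[name] = (profile, charge)
    if not species_rdfs:
        raise PipelineError("zeff: no ion groups in the selections")
    charge_profile = profile_from_rdfs(z_protein, species_rdfs)
    df = pd.DataFrame({"r_nm": charge_profile.r_grid, "Z_eff_e": charge_profile.z_eff})
    for name, term in charge_profile.species_terms.items():
        df[f"term_{name}_e"] = term
    _write_tsv(df, ctx.out_dir / "zeff.tsv", cfg.config_hash())
    summary: dict[str, Any] = {"z_protein": z_protein}
    over = detect_overscreening(charge_profile)
    summary["overscreening"] = over.present
    if over.present:
        summary["overscreening_r_nm"] = over.r_min
        summary["overscreening_depth_e"] = over.depth
    try:
        fit = fit_screening_length(charge_profile)
        summary.update(
            {"a_e": fit.a, "xi_nm": fit.xi, "window": list(fit.window), "rms_e": fit.rms_residual}
        )
    except (ValueError, RuntimeError) as exc:
        summary["fit_error"] = str(exc)
    (ctx.out_dir / "zeff_fit.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _stage_survival(ctx: _RunContext) -> None:
    cfg = ctx.config
    protein = ctx.protein_group()
    _, ion_molecules = ctx.selections
    flat = {
        f"{species}:{ion}": atoms
        for species, molecules in ion_molecules.items()
        for ion, atoms in molecules.items()
    }
    if not flat:
        raise PipelineError("survival: no ion molecules in the selections")
    series = build_contact_series(
        ctx.trajectory,
        flat,
        protein,
        ctx.system.box_length,
        cutoff=cfg.contact_cutoff,
    )
    dt = series.frame_spacing
    max_lag = cfg.max_lag_ps or (ctx.trajectory.n_frames - 1) * dt / 2
    curve = survival_probability(series, max_lag, gap_tolerance=cfg.gap_tolerance)
    _write_tsv(
        pd.DataFrame({"lag_ps": curve.lags, "S": curve.S}),
        ctx.out_dir / "survival.tsv",
        cfg.config_hash(),
    )


def _stage_bridges(ctx: _RunContext) -> None:
    cfg = ctx.config
    groups, ion_molecules = ctx.selections
    if "protein_B" not in groups:
        raise PipelineError("bridges: selections define no protein_B group")
    flat = {
        f"{species}:{ion}": atoms
        for species, molecules in ion_molecules.items()
        for ion, atoms in molecules.items()
    }
    if not flat:
        raise PipelineError("bridges: no ion molecules in the selections")
    residue_of_atom = {i: a.residue_index for i, a in enumerate(ctx.system.atoms)}
    records, curve = bridge_lifetimes(
        ctx.trajectory,
        flat,
        groups["protein_A"],
        groups["protein_B"],
        residue_of_atom,
        ctx.system.box_length,
        cutoff=cfg.contact_cutoff,
        gap_tolerance=cfg.gap_tolerance,
        max_lag_ps=cfg.max_lag_ps,
    )
    dt = ctx.trajectory.frame_spacing or 1.0
    rows = []
    for record in records:
        mid = (record.start_frame + record.end_frame) // 2
        res_a, res_b = record.anchors[mid - record.start_frame]
        rows.append(
            {
                "ion_id": record.ion_id,
                "t_start_ps": record.start_frame * dt,
                "t_end_ps": record.end_frame * dt,
                "residue_A": res_a,
                "residue_B": res_b,
            }
        )
    _write_tsv(pd.DataFrame(rows), ctx.out_dir / "bridge_records.tsv", cfg.config_hash())
    _write_tsv(
        pd.DataFrame({"lag_ps": curve.lags, "S": curve.S}),
        ctx.out_dir / "bridge_survival.tsv",
        cfg.config_hash(),
    )


def _stage_dimer(ctx: _RunContext) -> None:
    cfg = ctx.config
    groups, _ = ctx.selections
    if "protein_B" not in groups:
        raise PipelineError("dimer: selections define no protein_B group")
    d = distance_timeseries(
        ctx.trajectory, groups["protein_A"], groups["protein_B"], ctx.system.box_length
    )
    profile = profile_from_runs(
        [d],
        bin_width=cfg.dimer_bin_width,
        r_max=cfg.dimer_r_max,
        temperature=cfg.temperature,
    )
    _write_tsv(
        pd.DataFrame(
            {
                "d_nm": profile.bin_edges[:-1],
                "p_per_nm": profile.p,
                "F_kT": np.where(np.isfinite(profile.F), profile.F, np.nan),
            }
        ),
        ctx.out_dir / "dimer_profile.tsv",
        cfg.config_hash(),
    )


def _stage_manifest(ctx: _RunContext) -> None:
    cfg = ctx.config
    manifest = (
        read_manifest(cfg.manifest) if cfg.manifest else reference_manifest()
    )
    total_runs, cumulative_ns = summarize_manifest(manifest)
    df = pd.DataFrame(
        [{"total_runs": total_runs, "cumulative_ns": cumulative_ns}]
    )
    _write_tsv(df, ctx.out_dir / "manifest_summary.tsv", cfg.config_hash())


_STAGE_FUNCTIONS = {
    "simulate": _stage_simulate,
    "rdf": _stage_rdf,
    "bai": _stage_bai,
    "zeff": _stage_zeff,
    "survival": _stage_survival,
    "bridges": _stage_bridges,
    "dimer": _stage_dimer,
    "manifest": _stage_manifest,
}


def run_pipeline(config: AnalysisConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the output directory.  A run log (versions, seed, parameters,
    config hash) is always written; reruns with an identical config produce
    byte-identical outputs.
    """
    ctx = _RunContext(config)
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCTIONS[stage](ctx)
        except PipelineError:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(f"{stage}: missing input file ({exc})") from exc
    log = {
        "ionbridge_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "parameters": config.to_dict(),
    }
    (ctx.out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return ctx.out_dir
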