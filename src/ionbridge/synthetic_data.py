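"""Generators with known ground truth for exercising every analysis stage.

Three modes:

* ``equilibrium`` -- independent Metropolis-sampled ion configurations around
  a fixed bead protein with residue-class square wells and screened-Coulomb
  interactions (structural estimators: rdf, BAI, Z_eff).
* ``telegraph`` -- two-state Markov contact channels with known on/off rates
  (survival kinetics).
* ``two_protein`` -- two bead proteins with ions hopping between a bridging
  site and bulk, or the proteins on a designed double-well distance process
  (bridges, dimer free energy).

All randomness flows through a single mandatory seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core_model import (
    Atom,
    MolecularSystem,
    SelectionGroup,
    Trajectory,
    minimum_image_displacement,
    wrap_coordinates,
    write_structure,
    write_trajectory,
)
from .kinetics import ContactSeries

__all__ = [
    "IonSpeciesSpec",
    "SyntheticSpec",
    "generate_toy_protein",
    "generate_equilibrium_system",
    "sample_equilibrium_frames",
    "simulate_telegraph_contacts",
    "generate_two_protein_system",
    "simulate_two_protein_system",
    "write_fixture",
    "default_selections",
    "metropolis_transition_matrix",
]

CLASS_RESNAMES = {"positive": "LYS", "negative": "ASP", "hydrophobic": "LEU"}
DEFAULT_CLASS_CHARGES = {"positive": 1.0, "negative": -1.0, "hydrophobic": 0.0}


@dataclass(frozen=True)
class IonSpeciesSpec:
    name: str
    count: int
    charge: float
    radius: float = 0.15

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"ion species {self.name}: count must be nonnegative")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic fixture; (spec, seed) is reproducible."""

    mode: str = "equilibrium"  # equilibrium | telegraph | two_protein
    box_length: float = 6.0
    seed: int = 0
    # protein layout
    n_beads: int = 16
    shell_radius: float = 1.0
    bead_radius: float = 0.15
    bead_classes: tuple[str, ...] = ("positive", "hydrophobic")
    class_charges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CHARGES)
    )
    net_charge: float | None = None  # default: whatever the classes give
    # ions
    ion_species: tuple[IonSpeciesSpec, ...] = ()
    # interaction model
    well_depths: dict[str, float] = field(default_factory=dict)  # k_BT per class
    contact_range: float = 0.4  # nm
    screening_length: float = 0.8  # nm
    bjerrum_length: float = 0.7  # nm (water, ~300 K)
    # sampling
    n_frames: int = 100
    frame_spacing: float = 10.0  # ps
    step_size: float = 0.6  # nm, MC displacement half-width
    burn_in_sweeps: int = 100
    thin_sweeps: int = 3
    # kinetics
    k_on: float = 1.0  # ns^-1
    k_off: float = 1.0  # ns^-1
    # two-protein geometry
    separation: float = 0.7  # nm, center-to-center of the two bead proteins
    double_well: tuple[float, float, float, float] | None = None
    # (d_low, d_high, delta_f_kT, well_width)

    def __post_init__(self) -> None:
        if self.mode not in ("equilibrium", "telegraph", "two_protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for depth in self.well_depths.values():
            if not math.isfinite(depth):
                raise ValueError("well depths must be finite")


def _fibonacci_shell(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    unit = np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
    return center + radius * unit


def _bead_atoms(
    spec: SyntheticSpec,
    positions: np.ndarray,
    chain: str,
    first_atom_id: int,
    first_residue: int,
) -> tuple[list[Atom], list[str]]:
    classes = [spec.bead_classes[i % len(spec.bead_classes)] for i in range(len(positions))]
    charges = np.array([spec.class_charges.get(c, 0.0) for c in classes], dtype=float)
    if spec.net_charge is not None:
        # distribute the residual in +/-1 increments so each bead stays small
        residual = int(round(spec.net_charge - charges.sum()))
        step = 1 if residual > 0 else -1
        for k in range(abs(residual)):
            charges[k % len(charges)] += step
    atoms = [
        Atom(
            atom_id=first_atom_id + i,
            atom_name="BB",
            element="C",
            residue_index=first_residue + i,
            residue_name=CLASS_RESNAMES.get(classes[i], "LEU"),
            chain_id=chain,
            formal_charge=float(charges[i]),
            radius=spec.bead_radius,
        )
        for i in range(len(positions))
    ]
    return atoms, classes


def _check_overlaps(positions: np.ndarray, radii: np.ndarray, box: float) -> None:
    n = len(positions)
    for i in range(n):
        delta = minimum_image_displacement(positions[i + 1 :], positions[i], box)
        d = np.linalg.norm(delta, axis=1)
        too_close = d < radii[i + 1 :] + radii[i]
        if np.any(too_close):
            j = int(np.flatnonzero(too_close)[0]) + i + 1
            raise ValueError(f"beads {i} and {j} overlap (closer than the sum of radii)")


def generate_toy_protein(spec: SyntheticSpec) -> MolecularSystem:
    """Deterministic bead cluster on a spherical shell at the box center.

    Bead residue classes cycle through ``spec.bead_classes``; formal charges
    follow ``class_charges``, with any residual against ``net_charge``
    distributed in unit increments.  The generated coordinates are stored on
    ``reference_coordinates``.
    """
    if spec.n_beads < 1:
        raise ValueError("need at least one bead")
    center = np.full(3, spec.box_length / 2.0)
    positions = _fibonacci_shell(spec.n_beads, spec.shell_radius, center)
    atoms, _ = _bead_atoms(spec, positions, chain="A", first_atom_id=1, first_residue=1)
    radii = np.full(spec.n_beads, spec.bead_radius)
    _check_overlaps(positions, radii, spec.box_length)
    return MolecularSystem(
        atoms=atoms,
        box_length=spec.box_length,
        reference_coordinates=positions,
    )


def _ion_atoms(
    spec: SyntheticSpec, first_atom_id: int, first_residue: int
) -> list[Atom]:
    atoms: list[Atom] = []
    atom_id, residue = first_atom_id, first_residue
    for species in spec.ion_species:
        for _ in range(species.count):
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    atom_name="ION",
                    element="C",
                    residue_index=residue,
                    residue_name=species.name[:3].upper(),
                    chain_id="I",
                    formal_charge=species.charge,
                    radius=species.radius,
                )
            )
            atom_id += 1
            residue += 1
    return atoms


def generate_equilibrium_system(spec: SyntheticSpec) -> MolecularSystem:
    """Bead protein plus one single-atom residue per ion molecule."""
    protein = generate_toy_protein(spec)
    ions = _ion_atoms(
        spec,
        first_atom_id=spec.n_beads + 1,
        first_residue=spec.n_beads + 1,
    )
    return MolecularSystem(
        atoms=protein.atoms + ions,
        box_length=spec.box_length,
        reference_coordinates=protein.reference_coordinates,
    )


class _IonField:
    """Energy model (k_BT) for mobile ions around fixed beads."""

    def __init__(self, spec: SyntheticSpec, bead_pos: np.ndarray, bead_classes: list[str], bead_charges: np.ndarray):
        self.spec = spec
        self.bead_pos = bead_pos
        self.bead_charges = bead_charges
        self.bead_radii = np.full(len(bead_pos), spec.bead_radius)
        self.bead_depths = np.array(
            [spec.well_depths.get(c, 0.0) for c in bead_classes], dtype=float
        )
        self.ion_charges = np.concatenate(
            [[s.charge] * s.count for s in spec.ion_species]
        ) if spec.ion_species else np.zeros(0)
        self.ion_radii = np.concatenate(
            [[s.radius] * s.count for s in spec.ion_species]
        ) if spec.ion_species else np.zeros(0)

    @property
    def n_ions(self) -> int:
        return len(self.ion_charges)

    def ion_energy(self, i: int, pos_i: np.ndarray, ion_pos: np.ndarray) -> float:
        spec = self.spec
        box = spec.box_length
        d_bead = np.linalg.norm(
            minimum_image_displacement(self.bead_pos, pos_i, box), axis=1
        )
        if np.any(d_bead < self.bead_radii + self.ion_radii[i]):
            return math.inf
        energy = -float(self.bead_depths[d_bead <= spec.contact_range].sum())
        qi = self.ion_charges[i]
        if qi != 0.0:
            mask = self.bead_charges != 0.0
            if np.any(mask):
                d = d_bead[mask]
                energy += float(
                    spec.bjerrum_length
                    * qi
                    * np.sum(
                        self.bead_charges[mask] * np.exp(-d / spec.screening_length) / d
                    )
                )
        others = np.delete(np.arange(self.n_ions), i)
        if others.size:
            d_ion = np.linalg.norm(
                minimum_image_displacement(ion_pos[others], pos_i, box), axis=1
            )
            if np.any(d_ion < self.ion_radii[others] + self.ion_radii[i]):
                return math.inf
            if qi != 0.0:
                qo = self.ion_charges[others]
                mask = qo != 0.0
                if np.any(mask):
                    d = d_ion[mask]
                    energy += float(
                        spec.bjerrum_length
                        * qi
                        * np.sum(qo[mask] * np.exp(-d / spec.screening_length) / d)
                    )
        return energy


def _initial_ion_positions(
    field_model: _IonField, rng: np.random.Generator
) -> np.ndarray:
    box = field_model.spec.box_length
    positions = np.zeros((field_model.n_ions, 3))
    for i in range(field_model.n_ions):
        for _ in range(10000):
            candidate = rng.uniform(0.0, box, size=3)
            if math.isfinite(field_model.ion_energy(i, candidate, positions)):
                positions[i] = candidate
                break
        else:
            raise RuntimeError("could not place ions without hard-core overlap")
    return positions


def sample_equilibrium_frames(
    spec: SyntheticSpec, system: MolecularSystem | None = None
) -> Trajectory:
    """Independent equilibrium configurations by Metropolis sampling.

    Single-ion displacement moves (uniform cube of half-width ``step_size``)
    against the screened-Coulomb plus square-well field of the fixed
    protein.  Frames are recorded every ``thin_sweeps`` sweeps after
    ``burn_in_sweeps``; the acceptance rate is checked against (0.1, 0.9).
    """
    if spec.mode != "equilibrium":
        raise ValueError("spec.mode must be 'equilibrium'")
    if system is None:
        system = generate_equilibrium_system(spec)
    bead_pos = system.reference_coordinates
    if bead_pos is None:
        raise ValueError("system carries no reference bead coordinates")
    classes = [spec.bead_classes[i % len(spec.bead_classes)] for i in range(spec.n_beads)]
    bead_charges = np.array(
        [a.formal_charge for a in system.atoms[: spec.n_beads]], dtype=float
    )
    model = _IonField(spec, np.asarray(bead_pos, float), classes, bead_charges)
    if model.n_ions == 0:
        raise ValueError("equilibrium mode needs at least one ion")
    rng = np.random.default_rng(spec.seed)
    ion_pos = _initial_ion_positions(model, rng)
    frames = np.empty((spec.n_frames, system.n_atoms, 3))
    accepted = proposed = 0
    total_sweeps = spec.burn_in_sweeps + spec.n_frames * spec.thin_sweeps
    recorded = 0
    for sweep in range(total_sweeps):
        for i in range(model.n_ions):
            old = ion_pos[i].copy()
            new = np.mod(
                old + rng.uniform(-spec.step_size, spec.step_size, size=3),
                spec.box_length,
            )
            e_old = model.ion_energy(i, old, ion_pos)
            e_new = model.ion_energy(i, new, ion_pos)
            proposed += 1
            if e_new <= e_old or rng.random() < math.exp(e_old - e_new):
                ion_pos[i] = new
                accepted += 1
        if sweep >= spec.burn_in_sweeps and (sweep - spec.burn_in_sweeps + 1) % spec.thin_sweeps == 0:
            frames[recorded, : spec.n_beads] = bead_pos
            frames[recorded, spec.n_beads :] = ion_pos
            recorded += 1
            if recorded == spec.n_frames:
                break
    if recorded < spec.n_frames:
        raise RuntimeError("sweep budget exhausted before recording all frames")
    rate = accepted / proposed
    if not (0.1 < rate < 0.9):
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside (0.1, 0.9); "
            f"tune step_size (currently {spec.step_size} nm)",
            stacklevel=2,
        )
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_spacing
    return Trajectory(times=times, coordinates=frames)


def simulate_telegraph_contacts(
    k_on: float,
    k_off: float,
    dt_ns: float,
    n_channels: int,
    n_frames: int,
    seed: int,
) -> ContactSeries:
    """Independent two-state Markov chains sampled on a regular grid.

    Per-step switching probabilities are ``1 - exp(-k dt)`` so the discrete
    survival matches the continuous exponential law exactly.  Initial states
    are drawn from the stationary occupancy ``k_on / (k_on + k_off)``.
    """
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be nonnegative")
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    if dt_ns * max(k_on, k_off) > 0.1:
        raise ValueError(
            f"dt * max(k) = {dt_ns * max(k_on, k_off):.3f} > 0.1; refine the time step"
        )
    rng = np.random.default_rng(seed)
    p_on = 1.0 - math.exp(-k_on * dt_ns)
    p_off = 1.0 - math.exp(-k_off * dt_ns)
    stationary = k_on / (k_on + k_off) if (k_on + k_off) > 0 else 0.0
    occ = np.zeros((n_channels, n_frames), dtype=bool)
    occ[:, 0] = rng.random(n_channels) < stationary
    for t in range(1, n_frames):
        u = rng.random(n_channels)
        occ[:, t] = np.where(occ[:, t - 1], u >= p_off, u < p_on)
    entities = [(f"ch{c}", "site") for c in range(n_channels)]
    return ContactSeries(entities=entities, occupancy=occ, frame_spacing=dt_ns * 1000.0)


def generate_two_protein_system(spec: SyntheticSpec) -> MolecularSystem:
    """Two single-bead proteins on the x axis plus single-atom ions.

    Protein A sits at the box center minus separation/2, protein B at plus
    separation/2; residue indices continue from A to B so anchors are
    unambiguous.
    """
    if spec.mode != "two_protein":
        raise ValueError("spec.mode must be 'two_protein'")
    center = np.full(3, spec.box_length / 2.0)
    offset = np.array([spec.separation / 2.0, 0.0, 0.0])
    pos_a, pos_b = center - offset, center + offset
    spec_one = replace(spec, n_beads=1, net_charge=None)
    atoms_a, _ = _bead_atoms(spec_one, pos_a[None, :], "A", first_atom_id=1, first_residue=1)
    atoms_b, _ = _bead_atoms(spec_one, pos_b[None, :], "B", first_atom_id=2, first_residue=2)
    ions = _ion_atoms(spec, first_atom_id=3, first_residue=3)
    coords = np.vstack([pos_a[None, :], pos_b[None, :]])
    return MolecularSystem(
        atoms=atoms_a + atoms_b + ions,
        box_length=spec.box_length,
        reference_coordinates=coords,
    )


def _bulk_positions(
    n: int, box: float, exclude_center: np.ndarray, min_distance: float
) -> np.ndarray:
    """Deterministic lattice of bulk parking spots away from the proteins."""
    per_axis = int(np.ceil(n ** (1.0 / 3.0))) + 2
    grid = (np.arange(per_axis) + 0.5) * (box / per_axis)
    candidates = np.array(np.meshgrid(grid, grid, grid)).T.reshape(-1, 3)
    d = np.linalg.norm(
        minimum_image_displacement(candidates, exclude_center, box), axis=1
    )
    far = candidates[d > min_distance]
    if len(far) < n:
        raise ValueError("box too small to park all ions away from the proteins")
    return far[:n]


def simulate_two_protein_system(
    spec: SyntheticSpec, system: MolecularSystem | None = None
) -> Trajectory:
    """Trajectory for the two-protein fixture.

    Default behaviour: each ion independently alternates between a bridging
    site (within ``contact_range`` of both bead surfaces) and a bulk parking
    spot, with telegraph rates ``k_on``/``k_off`` (ns^-1).  When
    ``spec.double_well`` is set, protein B instead moves on a designed
    two-level distance process with the stated free-energy difference and
    the ions stay in bulk.
    """
    if spec.mode != "two_protein":
        raise ValueError("spec.mode must be 'two_protein'")
    if system is None:
        system = generate_two_protein_system(spec)
    if spec.separation / 2.0 >= spec.contact_range and spec.double_well is None:
        raise ValueError(
            f"separation {spec.separation} nm leaves no bridge geometry "
            f"(need separation/2 < {spec.contact_range} nm)"
        )
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box_length / 2.0)
    n_ions = sum(s.count for s in spec.ion_species)
    bulk = _bulk_positions(max(n_ions, 1), spec.box_length, center, min_distance=2.0)
    pos_a = np.asarray(system.reference_coordinates[0])
    pos_b0 = np.asarray(system.reference_coordinates[1])
    frames = np.empty((spec.n_frames, system.n_atoms, 3))
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_spacing

    if spec.double_well is not None:
        d_low, d_high, delta_f, width = spec.double_well
        p_high = math.exp(-delta_f) / (1.0 + math.exp(-delta_f))
        in_high = rng.random(spec.n_frames) < p_high
        d = np.where(in_high, d_high, d_low) + rng.uniform(
            -width / 2.0, width / 2.0, size=spec.n_frames
        )
        for f in range(spec.n_frames):
            frames[f, 0] = pos_a
            frames[f, 1] = pos_a + np.array([d[f], 0.0, 0.0])
            if n_ions:
                frames[f, 2:] = bulk[:n_ions]
        return Trajectory(times=times, coordinates=frames)

    if n_ions == 0:
        raise ValueError("bridge mode needs at least one ion")
    dt_ns = spec.frame_spacing / 1000.0
    series = simulate_telegraph_contacts(
        spec.k_on, spec.k_off, dt_ns, n_ions, spec.n_frames, seed=spec.seed
    )
    midpoint = (pos_a + pos_b0) / 2.0
    # small fixed per-ion lateral offsets keep bridging ions distinct while
    # staying inside the contact range of both beads
    angles = 2.0 * np.pi * np.arange(n_ions) / max(n_ions, 1)
    offsets = 0.04 * np.column_stack(
        (np.zeros(n_ions), np.cos(angles), np.sin(angles))
    )
    for f in range(spec.n_frames):
        frames[f, 0] = pos_a
        frames[f, 1] = pos_b0
        occupied = series.occupancy[:, f]
        frames[f, 2:] = np.where(
            occupied[:, None], midpoint + offsets, bulk[:n_ions]
        )
    return Trajectory(times=times, coordinates=frames)


def default_selections(
    system: MolecularSystem,
) -> tuple[dict[str, SelectionGroup], dict[str, dict[str, list[int]]]]:
    """Standard groups for a synthetic system.

    Returns ``(groups, ion_molecules)``: chain A -> protein_A, chain B ->
    protein_B, one group per ion residue name (role by charge sign), and a
    per-species mapping of ion molecule id -> 0-based atom indices.
    """
    groups: dict[str, SelectionGroup] = {}
    by_chain: dict[str, list[int]] = {}
    for i, atom in enumerate(system.atoms):
        by_chain.setdefault(atom.chain_id, []).append(i)
    if "A" in by_chain:
        groups["protein_A"] = SelectionGroup("protein_A", frozenset(by_chain["A"]), "protein_A")
    if "B" in by_chain:
        groups["protein_B"] = SelectionGroup("protein_B", frozenset(by_chain["B"]), "protein_B")
    ion_molecules: dict[str, dict[str, list[int]]] = {}
    by_species: dict[str, list[int]] = {}
    for i in by_chain.get("I", []):
        atom = system.atoms[i]
        by_species.setdefault(atom.residue_name, []).append(i)
        ion_molecules.setdefault(atom.residue_name, {}).setdefault(
            str(atom.residue_index), []
        ).append(i)
    for name, indices in by_species.items():
        charge = system.atoms[indices[0]].formal_charge
        role = "cation" if charge > 0 else "anion" if charge < 0 else "buffer_state"
        groups[name] = SelectionGroup(name, frozenset(indices), role)
    return groups, ion_molecules


def write_fixture(
    system: MolecularSystem,
    trajectory: Trajectory,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write structure.pdb, trajectory.txt and selections.yaml for a fixture.

    Deterministic bytes for identical inputs; read-back reproduces the
    coordinates to the dialect precision (1e-6 nm traj, 1e-4 nm PDB).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure_path = out / "structure.pdb"
    trajectory_path = out / "trajectory.txt"
    selections_path = out / "selections.yaml"
    write_structure(structure_path, system, trajectory.coordinates[0])
    write_trajectory(trajectory_path, trajectory, system)
    groups, ion_molecules = default_selections(system)
    payload = {
        "groups": [
            {
                "name": g.name,
                "role": g.role,
                "atom_ids": [i + 1 for i in sorted(g.atom_ids)],  # 1-based on disk
            }
            for g in groups.values()
        ],
        "ion_molecules": {
            species: {ion: [i + 1 for i in atoms] for ion, atoms in molecules.items()}
            for species, molecules in ion_molecules.items()
        },
    }
    selections_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return {
        "structure": structure_path,
        "trajectory": trajectory_path,
        "selections": selections_path,
    }


def metropolis_transition_matrix(energies: Sequence[float]) -> np.ndarray:
    """Transition matrix of uniform-proposal Metropolis on discrete states.

    Used to verify detailed balance of the sampler's acceptance rule on tiny
    state spaces: ``pi_i P_ij == pi_j P_ji`` with Boltzmann weights.
    """
    e = np.asarray(energies, dtype=float)
    n = len(e)
    if n < 2:
        raise ValueError("need at least two states")
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                p[i, j] = (1.0 / (n - 1)) * min(1.0, math.exp(e[i] - e[j]))
        p[i, i] = 1.0 - p[i].sum()
    return p
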