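"""Shared fixtures: session-scoped synthetic datasets with known ground truth."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ionbridge.core_model import Atom
from ionbridge.kinetics import bridge_lifetimes, survival_probability
from ionbridge.synthetic_data import (
    IonSpeciesSpec,
    SyntheticSpec,
    default_selections,
    generate_equilibrium_system,
    generate_two_protein_system,
    sample_equilibrium_frames,
    simulate_telegraph_contacts,
    simulate_two_protein_system,
)


def make_atom(
    atom_id: int,
    residue_index: int,
    residue_name: str = "LYS",
    element: str = "C",
    chain: str = "A",
    charge: float = 0.0,
    radius: float = 0.17,
    name: str = "X",
) -> Atom:
    return Atom(
        atom_id=atom_id,
        atom_name=name,
        element=element,
        residue_index=residue_index,
        residue_name=residue_name,
        chain_id=chain,
        formal_charge=charge,
        radius=radius,
    )


@pytest.fixture(scope="session")
def equilibrium_recovery():
    """2,000 independent frames, two uncharged residue classes, dG = 1 kT."""
    spec = SyntheticSpec(
        mode="equilibrium",
        box_length=6.0,
        n_beads=16,
        bead_classes=("positive", "hydrophobic"),
        class_charges={"positive": 0.0, "hydrophobic": 0.0},
        net_charge=0,
        ion_species=(IonSpeciesSpec("ION", 24, 0.0),),
        well_depths={"positive": 2.0, "hydrophobic": 1.0},
        n_frames=2000,
        seed=0,
    )
    system = generate_equilibrium_system(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # dilute fixture: acceptance rate ~0.95
        trajectory = sample_equilibrium_frames(spec, system)
    return spec, system, trajectory


@pytest.fixture(scope="session")
def charged_equilibrium():
    """+7 bead protein neutralized by 7 monovalent anions, 200 frames."""
    spec = SyntheticSpec(
        mode="equilibrium",
        box_length=6.0,
        n_beads=7,
        bead_classes=("positive",),
        class_charges={"positive": 1.0},
        net_charge=7,
        ion_species=(IonSpeciesSpec("CLA", 7, -1.0),),
        well_depths={},
        n_frames=200,
        seed=2,
    )
    system = generate_equilibrium_system(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trajectory = sample_equilibrium_frames(spec, system)
    return spec, system, trajectory


@pytest.fixture(scope="session")
def telegraph_survival():
    """10^4 channels, k_on = k_off = 2 ns^-1, dt = 0.01 ns, S up to 0.5 ns."""
    series = simulate_telegraph_contacts(
        k_on=2.0, k_off=2.0, dt_ns=0.01, n_channels=10_000, n_frames=151, seed=7
    )
    curve = survival_probability(series, max_lag_ps=500.0)
    return series, curve


@pytest.fixture(scope="session")
def bridge_recovery():
    """Two-protein fixture, 150 bridging ions with k_off = 0.5 ns^-1."""
    spec = SyntheticSpec(
        mode="two_protein",
        box_length=6.0,
        separation=0.7,
        ion_species=(IonSpeciesSpec("PHO", 150, -2.0),),
        k_on=0.5,
        k_off=0.5,
        n_frames=201,
        frame_spacing=50.0,
        seed=11,
    )
    system = generate_two_protein_system(spec)
    trajectory = simulate_two_protein_system(spec, system)
    groups, ion_molecules = default_selections(system)
    residue_of_atom = {i: a.residue_index for i, a in enumerate(system.atoms)}
    records, curve = bridge_lifetimes(
        trajectory,
        ion_molecules["PHO"],
        groups["protein_A"],
        groups["protein_B"],
        residue_of_atom,
        spec.box_length,
        max_lag_ps=3000.0,
    )
    return spec, records, curve


@pytest.fixture(scope="session")
def double_well_distance():
    """5,000 frames of a designed two-level distance process, dF = 2 kT."""
    spec = SyntheticSpec(
        mode="two_protein",
        box_length=8.0,
        separation=0.3,
        ion_species=(),
        double_well=(0.3, 1.5, 2.0, 0.2),
        n_frames=5000,
        frame_spacing=10.0,
        seed=5,
    )
    system = generate_two_protein_system(spec)
    trajectory = simulate_two_protein_system(spec, system)
    groups, _ = default_selections(system)
    return spec, system, trajectory, groups
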