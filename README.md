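# ionbridge

Analysis toolkit for buffer-ion/protein interactions in MD-style trajectory
data: charge-state speciation of polyprotic buffers, surface radial
distributions, per-residue adsorption indices, effective-charge and
screening-length profiles, contact and ionic-bridge survival kinetics, and
dimer distance free-energy profiles.  A synthetic trajectory generator with
known ground truth (equilibrium Metropolis sampling, telegraph contact
kinetics, two-protein bridge/double-well fixtures) makes every analysis
stage testable without running MD.

## Package layout

| module | contents |
| --- | --- |
| `ionbridge.core_model` | domain types, PDB/plain-text trajectory IO, manifest TSV, minimum-image distance engine |
| `ionbridge.protonation` | Henderson–Hasselbalch two-state speciation, ion counts, largest-remainder apportionment |
| `ionbridge.structure_metrics` | Shrake–Rupley per-residue SASA (golden-spiral quadrature), radius of gyration |
| `ionbridge.adsorption` | surface rdfs, cumulative ion counts, atomic-pair contact counting, adsorption index (−ln N/N_max in k_BT), per-species averages and distributions |
| `ionbridge.electrostatics` | Z_eff(r) charge-compensation profiles, a·exp(−r/ξ) screening fits, overscreening detection |
| `ionbridge.kinetics` | contact occupancy series, pooled-origin survival probabilities with gap tolerance, bridge detection/lifetimes/anchor residues |
| `ionbridge.dimer_analysis` | minimum interprotein distance series, run-averaged histograms, Boltzmann-inverted free-energy profiles |
| `ionbridge.synthetic_data` | seeded generators for all of the above with designed well depths, rates and free-energy differences |
| `ionbridge.pipeline` / `ionbridge.cli` | YAML-config stage orchestration, manifest bookkeeping, TSV reports with config hashes |

Conventions: lengths in nm, times in ps, charges in elementary-charge units,
energies in k_BT (default 300 K).  Atom ids are 1-based on file interfaces
and 0-based internally.  Cubic periodic boxes only.

## CLI

```bash
ionbridge simulate|rdf|bai|zeff|survival|bridges|dimer|manifest --config FILE [--seed N] [--out DIR]
ionbridge run --config FILE        # every stage listed in the config
ionbridge manifest                 # summary of the packaged campaign manifest
```

Example config driving a full synthetic chain:

```yaml
stages: [simulate, rdf, bai, zeff, survival]
seed: 1
rdf_bin_width: 0.05
simulate:
  mode: equilibrium
  n_beads: 16
  ion_species: [{name: ION, count: 24, charge: 0.0}]
  well_depths: {positive: 2.0, hydrophobic: 1.0}
  n_frames: 500
```

Outputs are TSV tables (each stamped with the config hash) plus a
`run_log.json`; reruns with the same config are byte-identical.

## Trajectory dialect

Besides fixed-column PDB structures, trajectories use a plain-text format:
per frame a header `natoms time_ps box_nm` followed by `natoms` lines of
`x y z` in nm.  `write_fixture` emits structure + trajectory + a selections
YAML consumed by every stage.

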