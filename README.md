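# prkap

Coarse-grained (one bead per amino acid) simulation and contact analysis of
arginine-rich proline–arginine dipeptide repeat chains, (PR)n, binding
β-karyopherin-like nuclear transport receptors.

The package provides:

* **`prkap.cg_builder`** — construction of CG chain models: Cα traces parsed
  from PDB structures (with disordered completion of crystallographically
  missing regions and a stiff elastic network over the structured core),
  (PR)n chains built from a repeat count, charge/aromatic bead decoration and
  net-charge-per-residue (NCPR) computation.
* **`prkap.forcefield`** — implicit-solvent energy/force terms:
  Debye-screened electrostatics (truncated–shifted), cation-π attraction
  between R/K and F/Y/W beads, purely repulsive excluded volume, a
  hydrophobicity-scaled chain–chain attraction, residue-class (G/P/other)
  bending/torsion patterning of disordered stretches, and backbone/elastic
  harmonics.  Numba-compiled kernels; all well depths and ranges are
  documented configuration defaults.
* **`prkap.simulator`** — NVT Langevin dynamics (BAOAB splitting) in a cubic
  periodic box at 300 K, dt = 0.02 ps, γ = 0.02 ps⁻¹ by default; deterministic
  given (seed, config, parameters); lossless binary trajectory I/O.
* **`prkap.contact_analysis`** — the contact statistics: time-averaged
  contact count Ct (and Ct normalised by both chain lengths), binding
  probability Pb (strictly more than 10 % of probe residues within 1 nm),
  per-residue contact probability profiles, contact sites (probability
  strictly > 0.10), region-resolved contact counts over A-helix/B-helix/linker
  annotations, overlap with native binding-site classes (Nshared), half-σ
  block uncertainties, and NCPR↔Ct regression.
* **`prkap.synthetic_data`** — toy HEAT-repeat solenoids with tunable
  inner/outer-surface charge decoration, an acidic H8-like linker and toy
  binding sites, plus scripted fixture trajectories whose statistics are
  known in closed form.
* **`prkap.pipeline`** — length × salt sweeps and fixed-mass comparisons with
  TSV/JSON outputs, and the CLI.

## CLI

```bash
prkap make-toy --out toy/                         # toy receptor + annotations
prkap build --polypr 25 --out pr25.json           # (PR)25 model
prkap build --pdb receptor.pdb --chain A --out receptor.json
prkap simulate --config run.yaml --out run.traj --log run.log
prkap analyze --traj run.traj --regions toy/regions.tsv \
              --sites toy/sites.tsv --out results.json
prkap sweep --config experiment.yaml --out sweepdir/
```

`run.yaml` for `simulate` takes a receptor model path, `polypr` repeat count,
`copies`, `salt_mM` and any simulation field (box, n_steps, save_interval,
seed, …).  `experiment.yaml` for `sweep` mirrors
`prkap.pipeline.ExperimentConfig` (solenoid spec or receptor files,
`pr_lengths`, `salts_mM`, `seeds`, simulation settings).

## Notes

* Units: nm, ps, Da, kJ/mol (1 Da·nm²/ps² = 1 kJ/mol); charges in units of e.
* Residue indexing is 0-based in memory and 1-based in all TSV annotation
  files.
* The published force-field parameterisation is not reproduced; functional
  forms are implemented as documented and every numeric constant lives in
  `ForceFieldParams` (YAML round-trippable).
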