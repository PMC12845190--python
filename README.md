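# ligdyn

Comparative protein–ligand trajectory analysis at desk scale. `ligdyn`
re-implements, as a tested and fully seeded pipeline, the standard in-silico
workflow for comparing two protein–ligand systems:

- **structure_model** — domain types for atoms/residues/frame series,
  multi-model PDB read/write (fixed columns), chemical-role annotation
  (H-bond donors/acceptors, charged groups, aromatic rings, apolar atoms)
  from per-residue templates.
- **superposition** — Kabsch least-squares fitting, plain RMSD, and
  iterative pruned-pair RMSD (re-fit, drop pairs beyond a cutoff, repeat).
- **trajectory_descriptors** — per-frame RMSD series against a reference
  frame, per-residue RMSF about the time-average structure, radius of
  gyration; mean ± sample-SD summaries (nm).
- **flexibility_analysis** — three-class RMSF taxonomy (low < 0.1 nm,
  medium 0.1–0.3 nm, high > 0.3 nm), count/percentage summaries, extrema,
  and a sliding-window (5-residue) differential-flexibility detector with
  a 0.2 nm threshold on window-maximum differences.
- **interaction_fingerprints** — geometric detection of hydrogen bonds,
  salt bridges, face-to-face π-stacking and hydrophobic contacts per frame;
  trajectory fingerprint matrices with per-contact persistence; mean
  donor–acceptor distance tables; green/yellow contact classing of pocket
  residues.
- **energetics_bookkeeping** — MM/PBSA-style component aggregation:
  per-frame VDWAALS/EEL/EPB/ENPOLAR → GGAS/GSOLV/TOTAL with exact
  additivity at the mean level, plus system-vs-system deltas.
- **library_design_adme** — combinatorial R-group enumeration with the
  `{r2}.{r1}` naming scheme, five drug-likeness rule sets (thresholds in
  `src/ligdyn/data/rules.yaml`), a consensus-logP CNS window (2.0–3.5), and
  optional Pgp/CYP flag screens.
- **synthetic_data** — seeded generators that stand in for docking/MD
  engines: toy complexes, fluctuation trajectories with prescribed
  per-residue amplitudes (expected RMSF = σ√3), planted interaction
  snapshots built to exact geometries (verified to 0.01 Å at
  construction), Gaussian energy series, and RMSF profile pairs with
  planted differential segments.
- **pipeline_cli** — orchestrates the full two-system comparison and writes
  deterministic TSV/JSON report tables.

## CLI

```bash
ligdyn synth --outdir fixtures --seed 7          # generate a two-system fixture set
ligdyn compare --config fixtures/compare.yaml --outdir run   # full comparison
ligdyn analyze --pdb fixtures/systemA.pdb --template-tsv fixtures/ligand_template_A.tsv --outdir an
ligdyn fingerprint --pdb fixtures/systemA.pdb --template-tsv fixtures/ligand_template_A.tsv --out fp.tsv
ligdyn energetics --table fixtures/energyA.tsv --out energy.json
ligdyn libgen --out library.tsv                  # 180-compound default library
ligdyn adme-filter --descriptors desc.tsv --out adme.json
```

`compare` reads a YAML config naming the two systems (multi-model PDB,
ligand residue code, optional role-template TSV and per-frame energy TSV)
and writes flexibility tables, RMSF profiles, differential segments,
fingerprint persistence, H-bond distance tables, energy summaries and a
JSON mirror under one run directory. Identical config + seed gives
byte-identical outputs.

## Notes

- Coordinates are Ångström internally (PDB native); descriptor reports are
  in nm. Energies are kcal/mol.
- All generators take explicit seeds; there is no hidden global RNG state.
- Multi-model PDB is the only trajectory format (no DCD/XTC, no mmCIF);
  fixtures are plain text by design.
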