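# peptidome

Analysis pipeline for paired-biofluid (serum / bronchoalveolar lavage)
endogenous peptidomics from data-independent, ion-mobility-enabled mass
spectrometry:

1. **simulate** — synthetic paired serum/BALF ion-event tables, study-design
   tables and noisy b/y fragment spectra with fully known ground truth
   (planted dose effects, exposure-exclusive and lost features, below-LOD
   censoring, controllable serum–BALF correlation).
2. **cluster** — greedy seeded clustering of ion events across all samples of
   both fluids within retention-time (±2 min), drift (±4 bins) and mass
   (±12 ppm) tolerances, followed by a two-thirds reproducibility filter per
   (fluid × dose) group and a serum/BALF overlap report.
3. **quantify** — group-wise limit-of-quantification estimation, imputation of
   feature × group cells with zero detections (truncated normal at the group
   LOQ), per-sample median centering on the log2 scale, fold change versus the
   dose-0 vehicle group, and single-point concentration approximation.
4. **stats** — per-feature one-way ANOVA across dose groups, Benjamini–
   Hochberg step-up FDR control, exposure-exclusive / lost / modulated / null
   classification, and pooled serum-on-BALF regression per dose group.
5. **identify** — no-enzyme peptide-spectrum matching of MGF spectra against a
   substrate-restricted FASTA (MEROPS/SignalP-tagged) at 6/12 ppm precursor/
   product tolerances, with a seeded shuffled-decoy database and target-decoy
   FDR thresholding at 10%.

A bundled reference peptide table (sequences with printed monoisotopic
masses) and a toy substrate database ship as plain-text package data; the
`validate-table1` command recomputes every reference mass (fixed
carbamidomethyl-Cys, +57.02146 Da) and checks it to ±0.001 Da.

## CLI

```sh
peptidome simulate --seed 1 --n-features 2000 --out-dir run/
peptidome cluster run/ion_events.tsv run/design.tsv --out-dir run/
peptidome quantify run/feature_matrix.tsv run/design.tsv --out-dir run/
peptidome stats run/normalized_matrix.tsv run/feature_matrix.tsv run/design.tsv --out-dir run/
peptidome identify run/spectra.mgf src/peptidome/data/substrate_db.fasta --out run/ids.tsv
peptidome run --seed 1 --out-dir run/          # all stages, one master seed
peptidome validate-table1                      # reference-mass batch check
```

`peptidome run` writes every stage output plus `report.json` and the
effective `config.yaml` into the run directory; identical seeds give
byte-identical outputs. A YAML config (same field names as
`peptidome.pipeline.RunConfig`) can be passed with `--config`.

## Layout

```
src/peptidome/
  mass.py        residue masses, MH+, ppm errors, b/y ladders
  io.py          TSV / MGF / FASTA readers and writers
  simulate.py    synthetic-data generator (ground truth kept)
  clustering.py  ion-event clustering + reproducibility filter
  quantify.py    LOQ imputation, normalization, fold change
  stats.py       ANOVA, BH, exclusivity classes, cross-fluid fit
  identify.py    no-enzyme search, decoy FDR, annotation
  pipeline.py    stage orchestration, seeds, reference validator
  cli.py         click entry points
  data/          reference_peptides.tsv, substrate_db.fasta
```
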