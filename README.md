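# polarscreen

Hidden-target screening for polarity-extended LC-MS metabolomics.

`polarscreen` implements an end-to-end annotation pipeline for untargeted
liquid chromatography–mass spectrometry (LC-MS) data acquired on a
serially coupled reversed-phase / hydrophilic-interaction (RPLC–HILIC)
column system. In this "polarity-extended" setup a single run covers
very polar to nonpolar analytes: hydrophilic compounds (LogD(pH 7) < 0)
elute on the HILIC segment before the 15-minute column switch, and
hydrophobic compounds (LogD ≥ 0) elute on the RPLC segment after it.

The pipeline turns raw per-injection feature tables (m/z, retention
time, intensity) into confident compound annotations:

1. **QC** against a spiked internal-standard mixture (mass accuracy,
   RT stability).
2. **Replicate consensus** — a feature is accepted only if found in all
   three replicate injections within 5 ppm and 0.3 min.
3. **Blank subtraction** — features also present in the solvent blank
   are removed.
4. **Column partition** at the 15-min switch (HILIC vs. RPLC) inside
   the 5–34 min usable window.
5. **RT/LogD calibration** — ordinary least squares on RPLC standards
   of known LogD turns retention time into a predicted LogD (the
   retention time index, RTI).
6. **Successive-elimination screening** against a compound database:
   mass window (±5 ppm) → RTI agreement (RPLC only) → MS/MS fragment
   matching → composite score and a single `look_at` flag per feature →
   LogD-sign plausibility filter → chemotaxonomy filter (candidate's
   source plant family must match the studied taxon).
7. **Identification levels** 1–5: level 1 requires agreement with an
   injected reference standard (|ΔRT| ≤ 0.5 min, |Δppm| ≤ 5, at least
   one shared MS/MS fragment).
8. **OPLS-DA statistics** — orthogonal partial least squares
   discriminant analysis across solvents/instruments with R²X, R²Y,
   cross-validated Q², and the S-plot (p1 vs. p(corr)) for selecting
   features common across classes.

A deterministic synthetic-study generator with full ground truth
(compound database, decoys, internal standards, contaminants, MS/MS
spectra, two instrument profiles) supports benchmarking every stage.

## Notation

- **ppm deviation**: `(reference − observed)/reference × 1e6` — signed,
  positive when the observed mass reads low.
- **ΔRT**: `rt_standard − rt_measured` (minutes), signed.
- **LogD(pH 7)**: octanol–water distribution coefficient; negative =
  hydrophilic.
- **Composite score**: HILIC = ½ mass + ½ MS/MS; RPLC = ⅓ mass + ⅓ RTI
  + ⅓ MS/MS (each subscore in [0, 1], scores reported ×100; absent
  subscores contribute 0 unless renormalization is enabled).
- **Q²**: 1 − PRESS/SS under class-stratified k-fold cross-validation.

## Worked example

Simulate a small study (20 truth compounds annotated to Lemnaceae, 40
mass/LogD-matched decoys from a disallowed family, 3 solvents × 2
instruments × triplicate injections) and run the full pipeline:

```bash
polarscreen simulate --out demo/study --seed 7 --n-compounds 20 --n-decoys 40
polarscreen -v run-all --study-dir demo/study --out demo/out --seed 7
```

The stage log (stderr) shows the successive elimination:

```
stage=qc standards=12 passed=1
stage=consensus features=229
stage=blank_subtraction features=83
stage=partition hilic=15 rplc=68
stage=calibration n_points=12 r_squared=1.0
stage=screening candidates=246 look_at=82 after_logd_filter=82 after_chemotaxonomy=82
stage=identification records=20 level1=20
stage=statistics models=2
```

229 consensus features shrink to 83 after blank subtraction (the blank
carries the 15 contaminants per solvent plus the 12 internal
standards); 246 database candidates collapse to 82 `look_at` features,
and all 20 truth compounds are confirmed at level 1 — no decoy
survives the chemotaxonomy filter. `demo/out/manifest.json` records
every count; `deviation_table.csv` lists the standard-vs-measured
agreement per confirmed compound:

```
name           delta_rt_min  delta_ppm  fragments_matched  column  level
compound-0018  -0.0          -0.5       5/5                HILIC   1
compound-0001   0.0           0.0       3/3                HILIC   1
...
```

The OPLS-DA instrument contrast separates the two mass-spectrometer
profiles almost perfectly (R²Y = 0.996, Q² = 0.993), while the solvent
contrast is weaker (R²Y = 0.493) — abundances differ by solvent but
most compounds appear in all three extracts. `s_plot.csv` holds the
p1/p(corr) coordinates for common-feature selection.

The same stages are available as individual subcommands
(`simulate`, `qc`, `consensus`, `calibrate`, `screen`, `identify`,
`stats`), and as a Python API:

```python
from polarscreen import PipelineConfig, run_pipeline, simulate_study_to_disk

simulate_study_to_disk("demo/study", seed=7)
manifest = run_pipeline(PipelineConfig(study_dir="demo/study", out_dir="demo/out"))
print(manifest["identification"])   # {'records': 50, 'level1': 50}
```

## Reference panel

`polarscreen.reference_data.lemna_reference_panel()` ships a
42-compound validated standard panel (duckweed metabolites) with
standard and measured RT/mass coordinates. Recomputed from it:

- signed ΔRT examples: vitexin 0.2 min, niacin −0.2 min, tryptophan 0.0;
- signed Δppm examples: phenylalanine 2.0, norwogonin 1.8, flavone 3.6,
  aspartic acid 0.0;
- the 15-min partition yields **16 HILIC / 26 RPLC** compounds;
- every self-consistent row satisfies |Δppm| < 5 (one row, serine,
  carries a transcription artifact in its measured mass and is
  excluded; see `MASS_DISCREPANT`).

## Layout

```
src/polarscreen/
  records.py         core dataclasses (compounds, instruments, spectra)
  synthetic.py       ground-truth study generator
  features.py        ppm/QC/consensus/blank-subtraction/partition
  rti.py             RT -> LogD calibration and RTI subscore
  scoring.py         candidate scoring and successive elimination
  identify.py        standard confirmation, 5-level scheme
  opls.py            OPLS-DA, Q2 cross-validation, S-plot
  reference_data.py  42-compound validated panel
  io.py              CSV/JSON/MGF/MSP readers and writers
  pipeline.py        orchestration and study layout
  cli.py             click-based command line
docs/methods.md      methods note: model, assumptions, defaults
scripts/acceptance.py  headline-quantity recomputation
```
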