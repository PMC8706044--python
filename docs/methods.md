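# Methods note

This note records the modelling assumptions, parameter defaults, and
numerical choices behind `polarscreen`, including decisions that a user
may want to revisit for their own instrument setup.

## 1. Separation model

The pipeline assumes a serial RPLC–HILIC column coupling with a column
switch at **15 min** and a usable elution window of **5–34 min**
(features outside the window are discarded before partitioning).
Features with RT < 15 min are assigned to HILIC, RT ≥ 15 min to RPLC;
the boundary itself goes to RPLC. The physical premise is that
hydrophilic analytes (LogD(pH 7) < 0) are retained by the HILIC
segment and hydrophobic analytes (LogD ≥ 0) by the RPLC segment, which
the LogD-sign plausibility filter exploits: a candidate with LogD > 0
cannot legitimately explain a HILIC feature, and one with LogD ≤ 0
cannot explain an RPLC feature.

## 2. Feature-level processing

- **ppm deviation** is signed, `(reference − observed)/reference × 1e6`,
  positive when the observed mass reads low.
- **Replicate consensus** requires a feature in *all* injections
  (default 3) within **5 ppm / 0.3 min**; grouping is greedy from the
  most intense seed, each injection contributing its closest-m/z
  unused candidate. Features below the **50-count** noise threshold
  are dropped first. The greedy procedure is validated against an
  exhaustive enumeration oracle on random tables.
- **Blank subtraction** defaults to coordinate mode: any consensus
  feature matching a blank feature within the same tolerances is
  removed regardless of intensity. A ratio mode (keep features whose
  intensity exceeds `blank_factor ×` the blank intensity) is available
  for setups where trace carry-over of genuine analytes into blanks is
  expected.
- **QC**: each internal standard (12 spiked compounds) is located in
  every table by nearest coordinate; the report fails if the mean
  absolute mass deviation exceeds 5 ppm, the RT standard deviation
  exceeds 0.3 min, or a standard is missing from more than half of the
  tables.

## 3. RT/LogD calibration (RTI)

Calibration fits `LogD = slope · RT + intercept` by ordinary least
squares (`scipy.stats.linregress`) on RPLC-eluting standards of known
LogD; HILIC-eluting standards (RT < 15) are excluded because the HILIC
segment follows a different, non-collinear retention mechanism. The
fit refuses fewer than 3 points, degenerate RT spread, and non-positive
slopes (on RPLC, retention must increase with hydrophobicity).
Predictions outside the calibrated RT range are flagged as
extrapolated. The RTI subscore is a bounded linear ramp,
`max(0, 1 − |ΔLogD|/scale)` with **scale = 2.0** LogD units — the
underlying database scoring function of the original online tools is
unpublished, so a transparent monotone penalty is used and the scale is
configurable.

## 4. Candidate scoring and successive elimination

Database candidates within **±5 ppm** receive subscores in [0, 1]:

- mass: linear in |ppm| over the window;
- RTI: the ramp above (RPLC only);
- MS/MS: fraction of database fragments explained by the measured
  spectrum at **0.05 m/z** tolerance, with one-to-one closest-m/z
  assignment and a 50-count intensity floor; `None` when the database
  entry has no fragment list or no spectrum is available.

Composite weights: HILIC ½ mass + ½ MS/MS; RPLC ⅓ each. An absent
subscore contributes 0 by default (configurable renormalization over
present subscores). Per feature, exactly one candidate is flagged
`look_at` — the highest composite, ties broken by smaller |ppm| then
lexicographic compound id, making the choice deterministic.

Elimination stages annotate rather than delete candidates
(`eliminated_by` tags), so the audit counts
(candidates → look_at → after LogD filter → after chemotaxonomy) can be
recomputed independently from the hit list. The chemotaxonomy filter
retains a candidate only if at least one of its source families is in
the allowed set (default `{Lemnaceae}`).

## 5. Identification levels

Level 1 requires an injected reference standard agreeing within
**0.5 min RT** (a permissive 1.0-min preset exists for drifting
gradients), **5 ppm**, and at least **one shared MS/MS fragment**;
failures stay at level 2 evidence. Levels 2–5 grade down from
annotation (mass + RT behavior + fragments + chemotaxonomy) through
fragments/formula to mass-only recognition. Deviations are reported
signed (standard − measured), rounded to one decimal in the report
table only.

## 6. OPLS-DA

Multi-class discriminant analysis uses a single model with a centered
class-indicator dummy Y rather than pairwise models. Before each
predictive extraction, orthogonal components are removed: the weight
`w_o` is the X-loading `p` minus its projection onto an orthonormal
basis of the Y-predictive weight space (SVD of X'Y). The predictive
part is NIPALS PLS2, implemented directly and converged to machine
precision; at zero orthogonal components the model coincides with
standard PLS to < 1e-8 against an independently converged reference
implementation. Defaults: unit-variance scaling after log10(1+x)
transformation of intensities, 1 predictive + 1 orthogonal component,
**7-fold** class-stratified cross-validation for Q² (folds reduce with
a warning when the smallest class is smaller). Constant columns are
dropped with a warning under UV/Pareto scaling.

The S-plot reports `p1 = cov(t1, x_j)/sd(t1)` and
`p(corr)1 = corr(t1, x_j)` on the scaled training data; zero-variance
features are flagged instead of producing NaN. "Common" features are
selected by `|p(corr)1| ≤ 0.1`, optionally requiring the class-wise
p(corr) values to agree within 0.05.

## 7. Synthetic ground-truth generator

The generator emulates the *statistical shape* of a polarity-extended
duckweed screening study, not any instrument physics:

- LogD values are drawn from a bimodal mixture: polar uniform
  [−5.5, −0.2], nonpolar uniform [0.1, 4.6], default weight ½.
- Elution is a deterministic piecewise-linear function of LogD: HILIC
  slope 10/6 min per LogD unit mapping [−6, 0) onto [5, 15) min; RPLC
  4 min per LogD unit mapping [0, 4.75] onto [15, 34] min. The RPLC
  branch is exactly invertible, so a noise-free calibration recovers
  slope 0.25 LogD/min with r² = 1 — a designed round-trip oracle.
- Abundances are log-normal per solvent (σ = 1) with medians 5000 /
  3500 / 2500 for 100% MeOH / 50% MeOH / 100% H₂O, emulating
  extraction-efficiency differences.
- Two instrument profiles: **A** (detection probability 0.85, 2 ppm
  mass noise, no MS/MS — a single-TOF-like screening instrument) and
  **B** (0.95, 1.5 ppm, MS/MS-capable — a QTOF-like instrument).
- Blanks carry 15 contaminants per solvent plus the 12 internal
  standards (spiked at 10 000 counts), so blank subtraction has real
  work to do.
- Adducts are [M+H]⁺ only (proton mass 1.00728); isotopologues,
  in-source fragments, multimers, and RT drift between runs are *not*
  modelled.
- Decoys copy truth masses and LogD but belong to a disallowed family
  (default Fabaceae) and, by default, re-draw their fragment lists;
  `same_fragments=True` produces harder decoys distinguishable only by
  taxonomy.

Default problem sizes (50 truth compounds, 100 decoys, 3 solvents ×
2 instruments × 3 injections) are the package's own choice: large
enough that rates (detection, recovery, elimination) are meaningful,
small enough that the full pipeline runs in seconds on one CPU.

## 8. Numerical choices

- Exhaustive oracles (itertools enumeration for consensus grouping,
  double loops for blank subtraction and mass screening, direct
  covariance/correlation for the S-plot) live in the test suite and
  bound the implementations' behavior instead of golden files.
- NIPALS convergence is checked on the relative change of the score
  vector at 1e-12; regression coefficients use a pseudoinverse of
  `P'W` to survive early termination on rank-deficient deflated data.
- The run manifest contains no timing or host information, so repeated
  runs on the same inputs are byte-identical; timings go to the log.
- All randomness flows through `numpy.random.default_rng` with
  explicit seeds; sub-seeds are derived arithmetically and kept below
  2³¹.

## 9. Known limitations

- Negative ionization mode, adducts beyond [M+H]⁺, and isotope
  patterns are unsupported.
- The RTI calibration is strictly linear; real RPLC gradients can
  curve at the extremes (extrapolation is at least flagged).
- MS/MS scoring is fragment-presence based; no intensity-weighted or
  neutral-loss similarity.
- The chemotaxonomy filter is binary on family membership; no
  taxonomic distance.
- OPLS-DA assumes complete data matrices (missing values must be
  imputed — the matrix builder inserts 0 for absent features).
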