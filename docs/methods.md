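# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `halovalid`. It is the package's own account of its
science; every number quoted here is computed by the code or its tests.

## Scope and data model

The pipeline covers the computational side of an in-house validation of a
targeted GC–MS/MS (MRM) method for eight organochlorines and six PBDEs in
fish homogenate: quantification, matrix-effect evaluation, validation
metrics, a top-down combined-uncertainty budget, and Eco-Scale greenness
scoring. Wet-lab steps (extraction, clean-up, chromatography, peak
integration) are out of scope; MRM transitions, retention times and
collision energies travel as metadata only.

Measurements are long/tidy: one peak area per row, tagged with analyte,
batch/run identifiers, sample type (blank, solvent standard,
matrix-matched standard, spiked sample, standard addition, QC, SRM),
spike and addition concentrations, and matrix descriptors (lipid %,
moisture %). All concentrations are wet-weight µg/kg. Each analyte is
tied to one of two internal standards (tetrachloro-*m*-xylene for the
organochlorines at 10 µg/kg, BDE-77 for the PBDEs at 20 µg/kg), and every
quantity derived from signal is a blank-corrected analyte/IS response
ratio from a single injection.

## Quantification

**Calibration and linearity.** Matrix-matched standards at seven levels
(0.1, 0.5, 1, 5, 15, 30, 60 µg/kg) give response-ratio vs concentration
points. Linearity is assessed two ways: the coefficient of determination
of an unweighted ordinary-least-squares line (a 1/x² weighted fit is
available behind a flag; the default follows common practice when no
weighting is specified), and the across-level RSD of the relative
response factor RRF = ((A_i − A_blank)/A_IS)·(c_IS/c_i). The RRF
definition makes the factor dimensionless and level-comparable, which is
what reporting its RSD across levels presumes.

**Concentration read-out.** Samples quantified "against the calibration"
(QC, limits and SRM replicates) use the mean RRF: c = ratio·c_IS/RRF̄.
This is exact under the proportional response the calibration verifies
and, unlike inverting the fitted line, does not let the intercept — whose
estimate is dominated by the 60 µg/kg level under proportional noise —
leak top-level noise into low-concentration results. The fitted line
remains the linearity diagnostic.

**Single-point standard addition.** c_i = c_ad·r_u/(r_a − r_u) with r_u,
r_a the response ratios of the unknown and the addition analysis and
c_ad = 10 µg/kg. The estimator is scale-invariant in the two ratios, so
proportional matrix effects and lipid suppression cancel by construction;
a non-positive denominator (the addition did not increase the response)
raises a non-quantifiable error rather than returning an infinite or
negative concentration. Recovery experiments are quantified this way.

**Matrix effect.** ME% = (matrix − solvent)/matrix × 100, averaged over
replicates paired by order (unequal replicate lists fall back to
comparing each matrix replicate with the solvent mean, logged as unpaired
mode). The matrix-matched denominator is the reporting convention of the
validated method; a conventional solvent-denominator variant is selectable.
The dispersion attached to ME is the SD of the per-replicate ME values in
percentage points — ME itself averages near zero, so a ratio-to-mean RSD
would be unstable.

## Validation metrics

* **Limits**: LOD = 3·SD, LOQ = 10·SD of the determined concentrations of
  ten replicates spiked at 0.1 µg/kg (sample SD, n−1). The identity
  LOQ/LOD = 10/3 is exact. Fewer than ten replicates warns; fewer than
  two is an error.
* **Recovery**: mean determined / spike × 100 with replicate RSD; the
  SANTE acceptability flag is set when recovery ∈ [30, 140] % and
  RSD ≤ 20 %.
* **Precision**: intra-day RSD of ten same-day QC replicates; inter-day
  precision defaults to the pooled RSD over the 4-days × 4-replicates
  design (the pooled estimator is what a single total-RSD figure reports);
  a one-way random-effects (ANOVA) intermediate-precision estimator is
  available behind a flag, with the between-day variance clipped at zero.
* **Trueness**: recovery = c_m/c_ref × 100 and B_r = recovery − 100,
  evaluated on the intra-day replicate mean; the identity is exact by
  construction.
* **SRM comparison**: trueness and RSD of replicate determinations of a
  certified reference material, plus an in-range flag. With only the mean
  available the check is mean ∈ [c − U, c + U] (inclusive, with a 1e-9
  relative guard so a mean sitting exactly on a bound is "at the border",
  not outside); when the determined expanded uncertainty is supplied the
  check is interval overlap.
* Sub-LOQ results are rendered as "<LOQ" strings at reporting time
  (two significant figures); numeric fields are never substituted.

## Top-down uncertainty budget

Four relative components, all on the same reference concentration
(the 5 µg/kg QC level; mixing bases raises an error):

* u_r,repro — RSD of ≥ 20 consecutive QC-chart determinations (10–19
  values warn);
* B_r — relative bias of the n ≥ 10 repeatability replicates, entered
  squared and *uncorrected*: bias is reported inside the uncertainty, not
  corrected out of the results;
* u_r,cm = (SD/√n)/c_ref × 100 — uncertainty of the systematic error;
* u_r,ref — certificate expanded uncertainty divided by its coverage
  factor (default k = 2) when a certificate exists, otherwise the
  rectangular-distribution estimate 0.5·(100 − y)/√3 from the purity y.
  The certificate route takes precedence.

u_r,tot is the root sum of squares; U_r,tot = 2·u_r,tot (~95 %
confidence; the factor is configurable). The combination is symmetric in
the sign of B_r and monotone in every component's magnitude.

## Eco-Scale

Score = 100 − Σ penalty points. Penalty values are data, supplied in the
method definition (the bundled ledger lists the reagents, instruments,
occupational hazard and waste of the DLLME + H₂SO₄ clean-up procedure and
totals 32 points, score 68); deriving penalties from hazard databases is
out of scope. Classification thresholds 75/50 follow the Eco-Scale scheme
and are configurable.

## Synthetic batch generator

The generator emulates a spiked fish-homogenate validation batch so that
every stage has a ground truth:

    area = base_scale · rrf_true · c_extract · (1 + ME/100)
           · exp(−k_lipid · (lipid% − lipid_ref)) · noise

* **Response and matrix effect.** Per-analyte `rrf_true` (0.26–5.3) and
  signed `me_true_pct` (−5.1 to +11) mirror the validated method's
  figures. The lipid factor (k_lipid = 0.04 per % lipid) is anchored at
  `lipid_ref` = 5.2 % — the matrix of the matrix-effect study — so
  `me_true_pct` is the total area effect of that matrix vs neat solvent,
  and fattier matrices only attenuate further. The factor applies equally
  to analytes and internal standards: real high-fat samples attenuate the
  IS peak, and equal application preserves response ratios, which is
  precisely why ratio-based quantification tolerates it.
* **Recovery.** The process-recovery factor `recovery_true_pct` (87–107)
  applies to analyte present in the homogenate (incurred content and
  validation spikes). The standard-addition spike is modelled as
  quantitatively recovered, i.e. a matrix-matched post-extraction
  addition. If the addition suffered the identical proportional loss, the
  single-point estimator would always return the true content and no
  recovery experiment could ever measure anything but 100 %; anchoring
  the addition makes the injected recovery identifiable, which is the
  behaviour the validation design assumes.
* **Noise.** The IS area carries the injection-level noise
  (truncated-normal multiplicative, CV = `noise_cv_pct`); each analyte
  area is its true analyte/IS ratio times the realised IS area with an
  independent error of SD = √((cv·ratio)² + (floor·∂ratio/∂c)²). The
  response ratio therefore has CV equal to `noise_cv_pct` — the quantity
  every validation RSD measures — plus an additive concentration-
  equivalent floor (`noise_floor_conc` = 0.009 µg/kg) that dominates near
  the limits and makes LOD/LOQ spike-level dependent. Defaults
  cv = 2 %, floor = 0.009 µg/kg jointly reproduce the two headline
  features of the validated method: calibration R² ≥ 0.999 over
  0.1–60 µg/kg *and* LOQ ≈ 0.1 µg/kg from replicates spiked at
  0.1 µg/kg. (A single multiplicative CV cannot do both: 5 % ratio noise
  already drives E[1 − R²] to ≈ 1.6·cv² ≈ 0.004.)
* **Blanks** emit exactly zero analyte area — a clean blank has no
  detected peak to integrate. Applying the floor at zero concentration
  with the area ≥ 0 truncation would make blank means half-normal
  positive and the mean-blank correction would then bias the mean RRF by
  ≈ −0.7 %, propagating +0.7 % into every determination.
* **Batch plan** (defaults): 3 blanks; 7-level calibration; 5 + 5
  matrix-vs-solvent standards at 5 µg/kg; recovery spikes at 1, 5, 15,
  30, 60 µg/kg (n = 5, each with a paired addition analysis); 10
  limit replicates at 0.1 µg/kg; 10 intra-day and 4 × 4 inter-day QC
  replicates and a 24-point QC chart at 5 µg/kg; 3 SRM replicates at the
  certified concentrations. All randomness flows from a single seed;
  batches are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic peak shape, retention drift and
integration errors; carryover; between-day drift of the QC chart (the
simulated chart behaves like consecutive runs under repeatability-like
conditions, so simulated u_r,repro at the default 2 % CV sits below the
6–10 % a chart spanning weeks accumulates); matrix-specific losses that
hit one analyte in one matrix (the kind of effect that puts an SRM result
far outside its certified range while spiked recoveries look fine); and
heteroscedasticity beyond the single additive floor.

## Numerical and design choices

* All RSDs use the n−1 sample SD; degenerate inputs (zero mean, < 2
  values, non-positive references) raise rather than return NaN.
* r_a = r_u in standard addition raises (non-quantifiable) instead of
  returning infinity.
* Response ratios may legitimately be negative when the blank exceeds the
  signal; they are returned as-is with a warning.
* Reported tables round to reporting style (two significant figures for
  limits, whole percent for recoveries); JSON carries full precision.
* Pipeline runs are deterministic given seed and inputs; reports embed
  provenance (input hashes, seed, version, timestamp).

## Problem sizes

The bundled defaults run the full 16-member panel. The repeated-batch
parameter-recovery study uses 200 seeded batches with a thinned plan
(recovery at 1 and 5 µg/kg, 20-point QC chart, 2 × 2 inter-day design,
no SRM block), which keeps the whole suite in the ten-second range while
leaving every estimator's sampling distribution visible.
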