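# Methods

This note documents the models, conventions and numerical choices behind
glycomody, and what the synthetic-data layer does and does not emulate.

## The measurement model

A HILIC-UHPLC fluorescence chromatogram of procainamide-labelled plasma
N-glycans is modeled as a sum of Gaussian peaks over a linearly drifting
baseline with additive white Gaussian noise, sampled uniformly on a
retention-time axis in minutes. Real traces deviate from this in known
ways — tailing/fronting peak shapes, correlated detector noise,
nonlinear baseline excursions, co-eluting shoulders — none of which the
renderer reproduces. The quantification chain is therefore validated
here for the idealized shape it assumes; on real data the GPQ gate is
exactly the mechanism that flags peaks violating that assumption.

### Peak detection

Local maxima of the moving-average-smoothed (default 5 points),
minimum-subtracted trace above `min_intensity` (default 0.001) times the
global maximum. The threshold is interpreted as *relative* to the base
peak: an absolute threshold would be meaningless across detectors with
arbitrary intensity units. Plateaus of exactly equal samples are
assigned to their earliest time point; single-sample apexes are refined
to sub-sample precision by a parabola through the apex triplet, the
standard apex-interpolation used by chromatography software. Peak width
is estimated as the half-height width divided by 2.355 (FWHM → σ for a
Gaussian).

### Retention-time calibration

Each calibrant feature is matched to the nearest detected apex within
its window; with ≥ 2 matches a least-squares polynomial from observed to
expected apex times remaps the axis (degree 1 for two calibrants, degree
2 for three or more — enough to correct constant shifts and smooth
gradient-composition drifts without risking oscillation). Calibration is
refused, never silently skipped, when fewer than two calibrants match or
the fitted map is non-monotone on the axis. A quadratic warp of the form
t + 1e-3·t² is corrected to well under one sampling interval at the
calibrants; warps whose inverse deviates from a quadratic by more than
the sampling interval across the elution window (very strong late-run
warps) are out of reach of the degree-2 map by construction.

### Quantification

For each feature window (expected rt ± width):

- **Background / noise**: flanking windows one feature-width wide on each
  side, excluding neighbouring feature windows. Background is the mean of
  the lowest-mean contiguous run of half the flank points; noise is the
  standard deviation of that run. Taking the lowest run makes the
  estimate robust to a shoulder intruding into one flank, at the cost of
  a slight downward bias of the background under pure noise.
- **Fit**: least-squares Gaussian (height, μ, σ) on the
  background-subtracted window, seeded from the apex and half-height
  width, with σ bounded by the window. Non-finite parameters or σ beyond
  twice the window half-width mark the quantification failed — flagged,
  never raised, so one bad peak cannot abort a 96-sample batch.
- **Area**: trapezoidal integral of the background-subtracted *raw*
  signal over μ ± 2σ of the fit (endpoints interpolated). Integrating
  the raw signal rather than the fitted model keeps the area robust to
  mild asymmetry; the analytic model area h·σ·√(2π)·erf(2/√2) is exposed
  as a diagnostic. Negative integrals are clamped to zero and fail QC.
- **GPQ**: squared Pearson correlation between the observed and fitted
  window, clamped to [0, 1]. r² is the conventional bounded
  goodness-of-fit measure consistent with a 0.8 acceptance threshold.
- **SN**: fitted height over the flank noise SD.

The analyte gate is inclusive: GPQ ≥ 0.8 **and** SN ≥ 9 **and** a
successful fit. Gating flags results; it removes nothing.

## Traits

Raw areas are normalized per sample to the summed area of the eleven
analysis peaks (the six antennary-fucosylated peaks p29, p35, p42, p44,
p48, p49 and their non-fucosylated counterparts). The fucosylation index
fuc/(fuc + nonfuc) is the only ratio of the pair that is bounded in
[0, 1], scale-invariant, and strictly increasing in the fucosylated
peak's area. Counterpart assignments (p25, p32, p38, p41, p47) follow
composition — the same structure minus the antennary fucose — and are
config-overridable, because peak assignment is column- and
study-specific. The two A4FG4S4 sialic-acid-linkage isomers share the
single A4G4S4 counterpart by default; isomer-specific counterparts are
expressible through the same config. The derived trait is the arithmetic
mean of its five default members; A2FG2S2 is computed but excluded from
the derived trait by default and includable via config. A missing member
poisons the derived value for that sample, keeping the derived trait's
definition constant across samples.

## Statistics

- **Outliers**: Tukey fences at k = 1.5 IQR, quartiles by linear
  interpolation between order statistics. The quartile convention is
  pinned because flags differ between conventions near the fences.
  Screening is per (trait, group); exclusion is per trait, not listwise.
  Groups smaller than 4 are not screened.
- **Mann-Whitney**: U counts case-over-control pairs plus half-ties.
  Exact enumeration when the smaller group has ≤ 8 observations and the
  pooled sample is tie-free; otherwise the normal approximation with tie
  and continuity corrections. Two-sided throughout.
- **Bonferroni**: min(1, m·p) with m defaulting to the number of tests
  of the run — the family is always the explicit trait × comparison grid
  actually computed, never an implicit external count.
- **ROC**: trapezoidal AUC over all distinct thresholds; ties produce
  diagonal segments, so the AUC equals the tie-corrected U/(n₁n₂)
  identity exactly. Direction is auto-detected (oriented so training
  AUC ≥ 0.5) and overridable; the biology fixes the expected direction
  to lower-indicates-case.
- **Cutpoint**: maximize sensitivity + specificity (Youden's J) over
  midpoints between adjacent distinct scores plus one candidate beyond
  each extreme; J-ties break toward higher specificity (a screening
  test confirms positives downstream, so false positives are the
  costlier error). Reported cutoffs are midpoints, never observed
  values.
- **Repeatability QC**: intra-plate CV per peak is the mean over plates
  of the within-plate sd/mean; inter-plate CV is the sd/mean of plate
  means. Summary averages cover only peaks with mean relative intensity
  above 1 %, mirroring the convention of reporting repeatability for
  non-trace peaks. With triplicates the within-plate SD estimate is
  biased low by the small-sample factor c₄(3) ≈ 0.886, so a generator
  set to 5 % intra-plate CV is recovered near 4.4 %; the inter-plate
  estimate absorbs part of the within-plate variance (≈ √(7² + 5²/3) %
  at the default settings). Both effects are visible in the acceptance
  output and are properties of the estimator, not defects.
- **Covariates**: per-trait Spearman against age and Mann-Whitney
  between sexes are exposed as descriptive utilities only; no adjusted
  model is fitted, since a defensible adjustment family cannot be
  specified from the available description.

## The synthetic cohort

Group sizes default to 18 (likely) damaging / 5 VUS / 8 (likely) benign
/ 289 no-mutation, the structure of the motivating study. Trait values
are truncated-normal on [0, 1] per group — the simplest bounded model
with directly controllable separation. Group-wise means and SDs are
**illustrative**: the source material shows trait distributions only as
dot plots, so defaults were chosen once to give a ~2 SD damaging-vs-rest
separation (binormal AUC ≈ 0.92, within the reported performance range)
with control-group means above the reported cutoffs, and are not
measured clinical values. Benign and VUS groups share the control
distribution.

Within a sample, traits load on a shared latent factor (default share
0.6 of latent variance), and hsCRP couples to that factor through a
Gaussian copula with a log-normal marginal parameterized from the
clinical characteristics table (e.g. 3.79 ± 6.97 mg/L in the no-mutation
group). The copula correlation is set to 2·sin(π·ρₛ/6)/√share so the
rank correlation between CRP and the traits approaches the configured
target (default 0.3 — a positive association is reported but not
quantified).

The peak table inverts the trait construction: for a pair with an
unshared counterpart the template's combined pair abundance is split as
(index, 1 − index); when two traits share one counterpart peak the
counterpart keeps its template abundance and the fucosylated side is
solved as nonfuc·index/(1 − index). Either way the index recomputed from
the noiseless table equals the drawn value to machine precision, and
row renormalization cannot change it because the index is a within-row
ratio. Measurement noise is multiplicative Gaussian per cell; after
renormalization the effective CV of a peak with weight w shrinks by
√(1 − 2w + Σw²) — negligible for minor peaks, ≈ 25 % relative for the
dominant peak.

What the generator does **not** emulate: between-batch drift,
plate-position effects, missing peaks, censored CRP values, age/sex
structure in the traits, or realistic inter-trait correlation beyond the
single shared factor. Tests passing on this generator therefore
demonstrate the correctness of the computational chain under its stated
model, not clinical performance on real cohorts.

## Problem sizes and determinism

Every generator is a pure function of its parameters and one seed; the
pipeline derives per-stage seeds from the master seed by hashing, so
stages can be re-run in isolation and identical configs give
byte-identical outputs. Monte-Carlo checks use 200 replicate cohorts at
the study's 18-vs-289 group sizes (mean-AUC standard errors ≈ 0.004,
comfortably inside the ±0.02 assertion bands); the null-calibration
check draws six mutually independent traits per cohort so the type-I
error estimate rests on 1200 effective tests rather than 200. The
quantification check uses 100 rendered chromatograms of eight
well-separated peaks at a 0.005-min sampling interval, where the
trapezoid-vs-closed-form discrepancy is dominated by Gaussian tail
truncation at the window edges (< 0.05 %). The interlaboratory noise
calibration bisects on common random numbers, making the mean Spearman
correlation a monotone function of the noise level.

## Known limitations

- Overlapping peaks are quantified by independent windowed fits; heavily
  co-eluting structures need deconvolution this package does not do.
- The degree-≤2 calibration map cannot follow locally irregular
  retention shifts; sparse calibrants late in the run limit accuracy
  there.
- Confidence intervals on AUC are not computed.
- The exact Mann-Whitney switches to the asymptotic path whenever ties
  are present, even in tiny samples, where the normal approximation is
  rough; with the study's group sizes this is immaterial.
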