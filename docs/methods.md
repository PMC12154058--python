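# Methods

`fritqc` implements a handheld-NIR quality-control workflow for powdered
*Fritillaria* bulbs: geographical-origin identification of four species
(*F. cirrhosa*, *F. ussuriensis*, *F. pallidiflora*, *F. thunbergii*) and
quantification of *F. ussuriensis* adulteration blended into *F. cirrhosa*.
All computation is on absorbance spectra sampled on a fixed 900–1700 nm grid
at 1 nm spacing (801 points).  This note records the models, the synthetic
data they are exercised on, and the numerical and design choices that were
genuinely open.

## Synthetic spectrum generator

The instrument data the workflow was designed for are not publicly
deposited, so the package ships a generator
(`fritqc.simulate`) that emulates the statistical structure the analysis
assumes rather than the radiative physics of powders.

A spectrum is

```
A(λ) = m · Σ_b g(λ; c_b, w_b, a_b · (1 + δ)) + β(λ) + o + ε(λ)
```

* `g` — Gaussian bands with centre `c_b`, FWHM `w_b`, peak amplitude `a_b`
  (absorbance units).  Gaussian rather than Voigt line shapes: for testing
  preprocessing and attribution only the band location/width/height matter.
* Shared backbone in all classes: 970 nm (O–H second overtone, a=0.45),
  1190 nm (C–H second overtone, a=0.35), 1450 nm (O–H first overtone,
  a=1.0) and 1650 nm (C–H first overtone, a=0.40).  The 1450 nm water band
  dominates, as it does in real plant powders — this is what makes the raw
  mean spectrum (and hence PC1) peak in the 1400–1500 nm region.
* One marker band per species (FWHM 30 nm, amplitude 0.1): cirrhosa
  1575 nm, ussuriensis 1460 nm, pallidiflora 1100 nm, thunbergii 1200 nm —
  the regions the attribution analysis is expected to recover.
* `δ ~ N(0, 0.05)` — one relative amplitude perturbation per
  (class, batch): batch-to-batch variation, drawn once per batch of 45
  acquisitions.
* `m = exp(N(0, 0.05))`, `o ~ N(0, 0.02)` — multiplicative scatter gain and
  additive offset.  This is deliberately the exact generative inverse of
  SNV, so SNV's effect can be asserted quantitatively.
* `β` — per-spectrum random polynomial baseline of degree ≤ 2 on
  t = (λ−900)/800 with offset ≤ 0.05, slope ≤ 0.1 across the grid,
  curvature ≤ 0.02.
* `ε ~ N(0, 0.005)` iid per point.

Defaults (noise 0.005 AU, marker amplitude 0.1, shared amplitudes 0.3–1.0,
baseline slope ≤ 0.1) are fixed once; the study's design counts are the
generator's defaults: 4 origins × 4 batches × 45 acquisitions = 720 spectra;
29 mixture levels (every 0.5% from 0.1–10%, every 5% from 10–50%) × 20
replicates = 580 spectra.  Mixtures are Beer–Lambert linear combinations of
the two pure band sums formed *before* the nuisance effects.

What the generator does **not** emulate: instrument response functions,
wavelength-dependent noise, Voigt/asymmetric line shapes, nonlinear
detector effects, or chemical correlations between constituents.  Passing
tests on this data therefore demonstrate that the pipeline recovers
structure it was built to recover under its own noise model — not
field performance on real powders.

## Preprocessing

* **Savitzky–Golay** — window 51, cubic polynomial; derivatives scaled to
  per-nm units.  Edges use polynomial-fit extension, which preserves exact
  reproduction of polynomials up to the filter order.
* **SNV** — per-spectrum centring/scaling with the sample (n−1) standard
  deviation (fixed so results are bit-stable).
* **Derivative** — S–G derivative; order 1 in the classification pipeline,
  order 2 where mixture spectra are displayed/processed.
* **airPLS** — Whittaker smoother (second-difference penalty, banded
  Cholesky solve) with adaptive weights: w=0 on points at/above the
  baseline, exp(t·|d|/|d−|) below it; endpoints anchored; stops when the
  negative-residual mass falls below 1e−3 of total signal or at 50
  iterations, returning a convergence flag rather than raising.  λ = 1e5 by
  default.
* Composition order in the combined pipeline is S–G smoothing first, then
  SNV (smoothing before normalisation); the reverse order is not offered.

## Chemometric models

PCA is the mean-centred SVD; the sign of each loading is fixed by forcing
its largest-magnitude element positive.  PLS (regression and one-hot
discriminant) uses NIPALS with deflation; with all components on full-rank
data it reproduces ordinary least squares, which the tests assert against a
normal-equations oracle.  Component counts are selected by 10-fold
cross-validation with a one-standard-error rule (smallest k within one SE
of the optimum) — deterministic given the fold seed and biased toward
parsimony.  PCA-reduced models use the first 10 components.  PCA for the
PCA–CNN/PCA–PLSR is fitted on the training block only (leakage-safe).

## The 1-D CNN

Five convolutional blocks (16/32/64/128/256 filters, kernel length 3, each
conv → batch-norm → ReLU), implemented in NumPy (`fritqc.nn`) with
hand-derived backward passes, im2col GEMM convolutions, and a seeded Adam
optimizer; training is single-precision and fully deterministic on one
device (one integer seed controls initialisation and shuffling).

Open architecture details were fixed as follows: length-2 max pooling after
the first four blocks for 801-point input and no pooling for 10-point PCA
input; global average pooling before a 64-unit dense layer and the output
(4-way softmax or one linear unit).  These choices are isolated in
`CNNSpec` so they can be swapped.

The reference optimisation schedule is Adam at 1e−4 decayed ×0.8 every 50
epochs, batch 10, up to 1500 epochs.  Training at that schedule is far
outside a desk-scale CPU budget, so the packaged experiment runners use
shortened schedules with a proportionally larger initial rate and the same
stepped-decay form; the schedule arithmetic itself (lr(e) = lr0·0.8^⌊e/50⌋)
is unchanged and tested in closed form.  Desk-scale schedules:

| task | input | norm | lr0 | decay | epochs |
|------|-------|------|-----|-------|--------|
| origin classification (per MC repeat) | 1st derivative | global | 3e−3 | ×0.8/50 | 15 |
| attribution model (Grad-CAM) | airPLS-corrected | global | 3e−3 | ×0.8/50 | 30 |
| adulteration regression | S–G+SNV | global | 1e−3 | ×0.8/30 | 300 |
| PCA–CNN regression | 10 PCA scores | per-feature | 3e−3 | ×0.8/50 | 300 |

The attribution model is trained on airPLS-corrected spectra deliberately:
baseline removal leaves band positions untouched, so the CAM maps cleanly
back to marker wavelengths.  SNV is avoided for this model because its
per-spectrum renormalisation couples all wavelengths — adding a marker band
changes the normalised intensity everywhere — which smears the class
signature across the spectrum and delocalises the attribution.

Two stabilisers make short-schedule training reproducible across seeds,
neither touching validation or test data.  First, the returned parameters
are those of the epoch with the lowest mean training loss (metrics are
monitored after every epoch; mini-batch Adam keeps bouncing near
convergence, so the final epoch is frequently not the best one).  Second,
after training, batch-norm running statistics are recalibrated with one
full pass over the training set, so eval-mode inference is exactly
consistent with the kept weights rather than with exponentially smoothed
statistics that lag them.

Input normalisation: spectra use **global** standardisation (one mean/SD
from the whole training matrix), which preserves relative band structure;
per-wavelength z-scoring is available but amplifies noise-only wavelengths
on scatter-corrected spectra and destabilised regression in pilot property
tests.  PCA-score inputs are standardised per component (their scales
differ by orders of magnitude).  Regression targets are standardised
internally and predictions mapped back (clipped to [0, 1] for reporting;
raw values retained).

## Grad-CAM

Attribution targets the output of the fifth convolutional block.  Channel
weights are position-averaged gradients of the class logit w.r.t. that
feature map; the CAM is the rectified weighted channel sum, linearly
interpolated to the 801-point grid and max-normalised per curve (all-zero
maps are returned flagged, not normalised).  The class-average protocol
computes one mean spectrum per origin, classifies it, and refuses to
attribute a mispredicted mean (returning the predicted class instead),
since the attribution would explain the wrong decision.

## Evaluation

Origin identification uses Monte Carlo resampling: per class, one third of
the spectra (60 of 180) drawn without replacement as the test set,
independently per repeat, 20 repeats; metrics reported as mean ± SD.
Splits are spectrum-level, which matches the acquisition protocol literally
but lets replicates of one batch appear on both sides; a batch-stratified
mode is provided for leakage-safe evaluation.  The mixture set is split 13
train / 7 test within each of the 29 levels (the explicit counts are
followed where the stated 1:2 ratio conflicts with them).

Accuracy is the overall fraction correct (trace of the confusion matrix
over its total); precision, recall and F1 are one-vs-rest per class and
macro-averaged — the symmetric default for a 4-class task reported with
single values.  R² = 1 − SS_res/SS_tot; RMSE is reported in percent for
fraction targets (RMSECV on the training/CV side, RMSEP on the test set).

## Degenerate inputs and numerical conventions

Non-canonical wavelength grids are rejected, never resampled.  SNV raises
on constant spectra.  R² raises on zero-variance targets.  airPLS
non-convergence is a flag, not an exception.  Divergent CNN training
(non-finite loss) aborts with the epoch and learning rate.  CSV output uses
17 significant digits so write→read round trips are bit-exact.

## Known limitations

* The CNN engine is CPU-only and desk-scale; the reference 1500-epoch
  schedule is supported but impractical here.
* Synthetic-data results bound what the tests can show (see above); the
  printed figures of merit on real instrument data are not reproducible
  without the original spectra.
* PCA–CNN inherits whatever nuisance variance the leading PCA components
  carry; on synthetic data with multiplicative scatter its accuracy sits
  below the scatter-corrected full-spectrum CNN.
* Grad-CAM resolution at the fifth block is ~16 nm per position before
  upsampling; peak localisation tighter than that is not meaningful.
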