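# Methods

## Signal model and ADC estimation

The DWI generator and the quantification layer share one signal model:
per voxel, `S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]`, the standard
two-compartment intravoxel-incoherent-motion decay in which a
microvascular pseudo-diffusion compartment (`f`, `D*`) adds fast signal
loss at low b-values on top of true tissue diffusion (`D`).  The
acquisition emulated is a 10-point protocol at
b = 0, 50, 100, 150, 200, 250, 300, 500, 750, 1000 s/mm².

ADC maps are fitted by ordinary least squares of `ln S` against `b` with
a free intercept, i.e. "aggregating" the b-values of a subset means one
joint log-linear fit, not an average of pairwise two-point ADCs.  The
choice is exact on monoexponential data and is cross-checked in the test
suite against an independent normal-equations oracle to 1e−12 relative.
`ADC_diff` uses {500, 750, 1000}; `ADC_low` uses {50, 100, 150};
`ADC_perf = ADC_low − ADC_diff`.  b = 0 and b = 200–300 are carried but
enter neither fit: including b = 0 in the low-b fit would not change the
slope on exact exponentials, and excluding it keeps the two subsets
symmetric three-point fits.  Voxels with any non-positive signal in a fit
subset are marked invalid rather than clamped, and invalid voxels are
excluded from ROI statistics.  Negative `ADC_perf` (possible under noise)
is clipped to 0 by default; a raw mode is kept for diagnostics.

Registration to a reference grid is metadata-driven resampling only
(linear for values, nearest-neighbour for contour masks, conservative
propagation of invalidity); no intensity-based registration is attempted
because the phantoms share grids by construction, so the identity path is
the one exercised in anger.

## CE-CT quantification

Mean HU is measured inside the tumour contour separately on the
unenhanced and post-contrast series, each restricted to
−50 ≤ HU ≤ +350 with inclusive bounds.  The relative necrotic volume is
the fraction of contour voxels whose *post-contrast* density lies below a
hypodensity threshold (default 50 HU, always configurable and passed
explicitly by the tests so the default is not load-bearing).  A fraction
of exactly 1 sets a total-necrosis flag; downstream correlation analyses
then rerun with the flagged case excluded and report both variants, so an
implausible 100% reading can never silently dominate a correlation.

## Histology quantification

A stained structure is one connected component (8-connectivity default)
of the thresholded stain channel, after removing components below a
minimum area (default 3 px, a single-pixel-noise guard).  Microvessel
density is count divided by section area from the pixel size; bead
counting applies the same machinery with bright-on-dark polarity
(fluorescence).  Non-overlapping placement in the generator keeps these
counts exact, which is what makes the counting path testable; an overlap
mode exists but is off by default.

## Statistics

Each group sample passes a Kolmogorov–Smirnov normality gate with the
Lilliefors correction, because the normal's moments are estimated from
the sample and the uncorrected KS p-value would be anti-conservative;
both samples normal routes to the equal-variance two-sample t test
(Welch selectable), anything else to the two-sided Mann–Whitney U
(exact null up to n = 20 without ties, tie-corrected normal
approximation otherwise, mid-ranks throughout).  Samples below n = 4
cannot be gated and route to the U test, recorded as `too-small`.
Forced modes (`always-t` / `always-u`) are available and recorded so
gate flakiness never silently changes a published table.  Spearman
correlations use average ranks; exclusions are applied before ranking
and echoed in the result.  The ordinal 0/1/2 vessel scores are compared
with a Pearson χ² on the group × score table, dropping empty score
columns with degrees of freedom adjusted; the scores themselves are
inputs (human scoring is not automated) and are summarised mean ± SD
while every other variable is reported median (IQR) with linear
quantile interpolation (Q3 − Q1), the rule the spread values depend on.
Merged-column tests pool the animals of both cell lines.  Alpha is
0.050 and no multiple-testing correction is applied, matching the
emulated workflow.

## The synthetic cohort

The generators define the study conditions rather than merely feeding
the tests:

- **Tissue classes.** Each tumour is an ellipsoid with a necrotic core
  grown voxel-by-voxel to the animal's target fraction (innermost voxels
  first, so the realised count is exact to rounding), a perfused stromal
  shell and a dense viable rim.  Group-level diffusion coefficients put
  the viable rim at 166 (co) / 346 (non-co) ×10⁻⁶ mm²/s and the necrotic
  core at 1695 / 1320 ×10⁻⁶ mm²/s; the co group carries the higher
  perfusion fractions (0.10/0.22 rim/stroma vs 0.06/0.12), the higher
  necrotic fraction (0.40 vs 0.18) and larger tumours.
- **CT calibration.** The reported whole-tumour HU means (pre/post
  30.5/120 co, 32/111 non-co) are measured over the entire contour,
  hypodense lacunas included, so the class means are calibrated such that
  the necrosis/parenchyma mixture at the group's necrotic fraction
  reproduces them (e.g. post-contrast parenchyma 186.7 HU with necrosis
  20 HU at fraction 0.40 gives a whole-tumour mean of 120 HU).
- **Noise.** DWI uses Rician (magnitude-MR) noise; per-acquisition sigma
  is `S0/SNR` with a default SNR of 50 at b = 0, and the delivered image
  averages six acquisitions — three orthogonal diffusion directions
  trace-averaged, two signal averages — which is how a clinical DWI
  protocol of this length delivers its images.  CT uses additive Gaussian
  noise (default 2 HU).  Defaults of 0 noise elsewhere keep
  exact-recovery tests the baseline.
- **Inter-animal variability.** Multiplicative lognormal jitter
  (CV 8%) on diffusion coefficients, perfusion fractions, necrotic
  fraction and tumour size; microvessel counts drawn normal
  (171 ± 19 vs 111 ± 11 per mm²), bead counts Poisson (mean 1.3 vs 1.1
  per field of view), ordinal vessel scores from group-specific
  categorical distributions.
- **Seeding.** One root seed per spec, split with `SeedSequence.spawn`
  per animal and per b-value, so outputs are byte-reproducible and
  partial regeneration is stable.

What the phantoms do **not** emulate: scanner physics (EPI distortion,
eddy currents, partial volume at tissue interfaces), irregular tumour
geometry, perfusion heterogeneity within a class, chromatic variation of
real immunostains, or overlapping microvessels.  Passing tests therefore
demonstrate correctness of the computation chain under the stated model,
not robustness to every artefact of real acquisitions.

## Problem sizes

Default analysis grids are deliberately small — DWI 12×12×6 voxels at
1.8 mm, CT 24×24×12 at 0.42×0.42×0.75 mm, histology 512×512 px covering
1 mm² — sizes at which the ellipsoidal phantoms still contain all three
tissue classes and the replicate-level statistical checks (100 seeded
cohorts of 15 animals per group) complete quickly on a single core.  All
generators accept larger grids unchanged.

## Known limitations

- The perfusion parameters `f` and `D*` are generator-side ground truth
  only; no full IVIM inversion is attempted (the pipeline needs only the
  two-ADC separation).
- The necrotic-volume criterion (post-contrast hypodensity below a
  threshold) is one reasonable operationalisation of "relative necrotic
  volume"; the flag-and-exclude mechanism, not the threshold value, is
  the load-bearing part.
- CT volumes are assumed to already be in HU; a reader applying clinical
  slope/intercept rescaling is an extension point, not core.
- The 8-bit map rendering fixes round-half-away-from-zero and a
  configurable colormap; published figures' exact palette is unknowable
  and irrelevant to the quantitative chain.
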