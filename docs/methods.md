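# Methods

This note documents the models, numerical choices and known limitations of
phenospec, in the package's own terms.

## Problem setting

Three leaf states are discriminated from mean reflectance spectra:
unstressed plants (BH), heat-stressed resistant varieties (AR) and a
heat-stressed susceptible variety (AS). Spectra come from two push-broom
imager ranges, Vis/NIR (400–1000 nm) and SWIR (1000–1800 nm), each
resolved to 128 bands; wavelengths beyond 1800 nm are cropped as noisy.
Each leaf contributes one sample: the band-wise mean over its segmented
pixels. Calibration/validation splits are stratified by group at a 2/3
fraction (rounding half-up per stratum, remainder to validation), which at
group totals 377/192/144 reproduces the published accounting of 251/128/96
calibration and 126/64/48 validation samples.

## Class-code encodings

PLS-DA on three or more groups needs scalar reference codes. Linear
discriminant analysis supplies them: the within-class scatter is shrunk as
`(1 − γ)·S_W + γ·diag(S_W)` with γ = 0.1 by default (128 strongly
correlated bands make the raw scatter ill-conditioned; γ is exposed), the
discriminant axes solve the generalized eigenproblem against the
between-class scatter, and each axis is unit-normalized and sign-fixed so
the reference group's centre is the axis minimum. The *best projection
value* (BPV) of a sample is its coordinate on the leading axis (the axis
choice is configurable because a 2-D discriminant plot leaves it
ambiguous). Group centres are the means of Gaussian fits to the per-group
BPV histograms — identical to the group sample means, which is why the
"central value of the normal distribution" is implemented as the mean
(the histograms are unimodal; mean and mode coincide under normality).
Codes rescale the centres so BH → 0 and the farthest group → 100, rounded
to integers; SPRI instead keeps only the centre *order* and places codes
at 0, 50, 100. The SPRI order is always derived from the BPV centre
order, never hard-coded, so each region's ordering (AR between BH and AS
in the Vis/NIR; AR farthest in the SWIR) emerges from the data.

## PLS1, classification and accuracy accounting

The discriminant model is single-response PLS1 via NIPALS on mean-centered
X and y (one scalar code per sample, not one-hot multi-response; the
package deliberately models one Y per scheme). Scores are mutually
orthogonal; the collapsed regression vector `β = W (PᵀW)⁻¹ q` reproduces
the factorization path to 1e-10 and reaches the ordinary-least-squares
solution at full rank. Components are chosen as the smallest count whose
k-fold cross-validated RMSEP is within 2 % of the global minimum (plus a
~1e-12 absolute slack so exactly low-rank data do not make the rule
chase machine noise); folds are a seeded permutation assigned round-robin.

Classification assigns a predicted score to the nearest class code, ties
breaking toward the lower code. Accuracy tables list per-group
`100·correct/total`; the overall figure is the **macro** (unweighted) mean
of per-group accuracies, computed on unrounded values and displayed with
half-up rounding to one decimal. The macro convention was fixed by a
consistency check against the published accounting (87.3/89.1/45.8 →
74.1 overall, where pooling would give 79.4); all sixteen published rows
are regression-tested.

VIP uses the standard form `VIP_j = sqrt(J · Σ_f (w_jf/‖w_f‖)² · SSY_f /
Σ_f SSY_f)` with unit-norm weight columns, which guarantees
`mean(VIP²) = 1` — the identity is asserted to 1e-10 in the tests. No
spectral preprocessing (SNV, derivatives) is applied by default; none is
part of the modelled workflow.

## Band selection

The ensemble selector first fits full-spectrum PLS1 and keeps bands with
VIP ≥ 1.0 (the conventional cut, since the mean squared VIP is 1). SPA
then builds a chain from every candidate start: at each step all
unselected candidate columns are projected onto the orthogonal complement
of the span of the selected ones and the column of maximal projected norm
is appended (exact duplicates project to zero and are never chosen; rank
exhaustion truncates the chain with a flag). Every chain prefix between
`m_min` and `m_max` bands is scored by refitting PLS1 (components =
min(m, 10)) and counting validation misclassifications under the active
encoding — classification error, not RMSE, because classification is the
endpoint. The winner minimizes errors, ties broken by smaller size then
smaller start index, for full reproducibility. `m_max` is capped at 20
(the workflow's "fewer than 20 wavebands" budget) and `m_min` defaults
to 8; when VIP filtering leaves fewer than `m_min` candidates, `m_min`
clamps down to the candidate count.

## Synthetic data: what it emulates and what it does not

No spectra from the original experiment were released, so the generator
produces stand-ins with known ground truth. Archetypes are smooth
leaf-like baselines — a green-peak/chlorophyll-trough/red-edge shape in
the Vis/NIR, an NIR plateau with the 1450 nm water band in the SWIR —
plus Gaussian absorption features at fixed centres whose amplitude is
`effect_size · level_g`. The group levels default to the geometry the
real data exhibited: (0, 0.74, 1.0) for (BH, AR, AS) in the Vis/NIR and
(0, 1.0, 0.89) in the SWIR, so the BPV encoding recovers ≈0/74/100 and
≈0/89/100 by construction and the SWIR region is intrinsically harder
(AR and AS nearly coincide). Features of width 0 plant single-band
deltas, making `informative_bands` an exact 6-element ground truth for
recovery studies.

Samples are `a·archetype + b + ε` with `a ~ N(1, 0.04)`,
`b ~ N(0, 0.008)` and ε Gaussian-smoothed white noise (kernel width 5
bands) rescaled to marginal SD 0.006; cube pixels add i.i.d. noise of SD
0.02. The smoothing matters: spectra are smooth, and white spectral noise
would make band selection unrealistically easy. These magnitudes were
fixed once so that full-spectrum synthetic validation accuracy spans
roughly 82–100 % across regions and schemes — the same range the real
study reported — and are all config-exposed. Default group sizes
(377, 192, 144) match the study's accounting.

What the generator does **not** emulate: radiative-transfer leaf optics
(no PROSPECT-style physics), variety-specific spectral signatures, real
leaf morphology (masks are ellipse unions), sensor smile/keystone, or
drought/pathogen stress modes. Passing tests therefore demonstrate the
*algorithms* — encodings, PLS/VIP/SPA, imaging — under controlled,
linear-model-friendly conditions; they do not certify accuracy on real
plants.

## Imaging and calibration

Reflectance calibration is `R = (S − D)/(W − D)` with white/dark
references averaged over their spatial extent band-wise before division
(standard push-broom practice; the source workflow does not state its
formula, so the standard one is assumed), clamped to [0, 2] since
detector noise can push S below D; a non-positive W − D errors with the
offending band named. Leaf segmentation is an NDVI-style index
((R₈₀₀ − R₆₇₀)/(R₈₀₀ + R₆₇₀) > 0.3) for Vis/NIR and a simple intensity
threshold at 1100 nm for SWIR, with 8-connected components below
`min_pixels` (default 50, synthetic scale) dropped.

Pixel maps apply the selected-band β per leaf pixel; because the model is
linear, the mask-mean of the map equals the leaf-level prediction exactly
(asserted at 1e-10). Scores are clipped to [−20, 120] before
colormapping (extreme noise pixels stay visible but bounded) with the
colour scale spanning the code range 0–100; selected wavelengths map onto
the cube grid by nearest band, with no interpolation, since selection and
cube share the grid. Rendering composes the RGB array directly and writes
PNG bytes deterministically.

## Reproducibility and problem sizes

All pipeline randomness flows from one root seed through named substreams
(simulation, split, cross-validation, cubes); re-running a config
reproduces every artifact byte-for-byte. The test suite and acceptance
script use scaled simulation sizes chosen for fast, stable statistics:
study-scale group sizes (377/192/144) for the pipeline runs, (120/60/60)
with effect size 0.16 for the 20-seed planted-band recovery study, and
48×48 cubes for imaging. The recovery study's within-5-points
full-vs-selected comparison is evaluated on the mean over the 20 runs,
since a single validation split of this size quantizes accuracy in
~1.7-point steps.

## Known limitations

* One mid-group inconsistency exists in the source accounting: its prose
  swaps the AR and AS calibration counts relative to its summary table;
  the table (AR = 128, AS = 96 in Vis/NIR) is treated as authoritative.
* More than three groups is supported structurally (LDA axes, SPRI
  spacing, nearest-code classification) but not tuned or studied.
* SPA scoring refits PLS1 for every (start, size) pair; with very large
  candidate sets this is the pipeline's dominant cost, though still
  seconds at 128 bands.
* BPV codes are only guaranteed order-consistent with the LDA centres;
  where a middle group sits is a data property, not a parameter.
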