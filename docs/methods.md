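# Methods

## Measurement model

A PET volume is a 3-D grid of standardized uptake values (SUV,
body-weight convention: tissue activity concentration × body weight in
grams / decayed injected dose; ¹⁸F half-life 109.77 min). Geometry is
voxel-center, millimeters; all volumes are reported in ml
(product of spacings / 1000 per voxel).

**Liver reference.** A sphere of diameter 30 mm (analytic volume
14.14 ml) is placed at an expert-chosen point in normal liver; voxels
whose centers fall inside give the reference mean μ_L and SD σ_L, and
the detection threshold is μ_L + 2σ_L. The 3-cm figure is interpreted as
a diameter: a 3-cm-radius sphere would hold 113 ml, an order of
magnitude larger than any normal-liver reference region.

**Detection.** Candidate lesions are connected components of voxels
with SUV strictly above the threshold, 26-connectivity by default
(configurable to 6); components below `min_voxels` (default 2) are
dropped as noise. "Above" is strict everywhere in the package: ties at a
threshold are excluded.

**Curation.** Reader A may only accept or remove candidates — removals
are tagged physiologic or inflammatory, the two decoy classes the
detector cannot distinguish from tumor. Reader M may additionally
replace a candidate's boundary with a supplied mask or append
reader-drawn lesions; edits are supplied as voxel-index masks rather
than through an interactive editor so runs are reproducible. The 41%
isocontour is applied after curation, to the edited extent.

**41% isocontour, MTV, TLG.** Within each accepted lesion's extent, the
final boundary keeps voxels with SUV > 0.41 × SUVmax (SUVmax taken
within the extent); the argmax voxel is always kept, so at fraction 1.0
the mask degenerates to the SUVmax voxel(s). MTV is the voxel count of
the mask × voxel volume, summed over lesions. TLG sums per-lesion
MTV × SUVmean over the 41% mask. An alternative literal reading —
total MTV × mean of per-lesion SUVmax — is available via
`patient_totals(..., tlg_mode="suvmax_product")`; the per-lesion SUVmean
definition is the default because it is the conventional one and yields
TLG/MTV ratios inside the plausible SUVmean range of clinical cases.

## Agreement statistics

Lin's concordance correlation coefficient uses 1/n second moments
(Lin's original estimator); the 95% CI is a Fisher-z interval with
Lin's asymptotic SE. Identical constant series are treated as perfect
agreement (ρ_c = 1); a single pair is rejected. Bland-Altman limits use
the 1/(n−1) SD of the differences, bias ± 1.96·SD, with samples outside
the limits flagged. The convention matters at small n: with differences
(0,0,0,0,10) the large difference lies just inside the 1/(n−1) limits
and is not flagged, while a 1/n SD would flag it.

Tertile strata cut at the 1/3 and 2/3 quantiles (linear interpolation)
of the reference series — by design the manual reader's estimates, or
the shared lesion count — with half-open [low, high) bins and the last
bin closed at the observed maximum. Duplicate edges under heavy ties
collapse bins; an all-constant reference is an error.

## Survival analysis

Median splits assign values strictly above the sample median to the
high-burden group; ties go low, keeping "high = Poor" strictly above the
cut. Kaplan-Meier, the log-rank test and Cox proportional hazards are
delegated to lifelines; Cox uses Efron tie handling and Wald inference,
with the burden metric entered continuously (per ml or per SUV·ml —
hazard ratios near 1.001 per unit). Multivariable models add LDH
(continuous) and ECOG (numeric 0–3) to the metric. One-year
progression-free survival is handled by administrative censoring at 12
months (`restrict_followup`). Zero-variance covariates, event-free
tables and non-convergence raise instead of returning silent garbage.

Cut-point classification calls a patient Poor when the metric strictly
exceeds the cut; discordance between two call series is the count of
patients whose group flips, and the study-level matrix compares the
four series (MTV/TLG × readers M/A) pairwise within metric and within
reader, plus the union of discordant patients. The bundled worked
example (four patients flip between readers on MTV, one on TLG, five
between metrics for the manual reader, four for the semi-automated one;
seven distinct patients) is recomputed from its printed measurement
values, never hard-coded as counts. Its source table prints one
patient's semi-automated MTV two ways (79.51 and 78.88); both exceed
the 63.55 cut, so panel-local values are used and the inconsistency is
recorded, not resolved.

## Synthetic data: what it emulates, what it does not

**Phantoms.** Structures are axis-aligned ellipsoids with plateau
intensities: liver mean 2.0 SD 0.25 SUV (typical clinical values, giving
a ~2.5 detection threshold before smoothing), lesion plateaus 5–10 SUV,
soft-tissue background 1.0. Decoys (brain-like, bladder-like uptake) use
the same intensity model but are labeled non-malignant: they exist to
exercise curation, not detection-accuracy claims. The point spread is an
isotropic Gaussian with σ = FWHM/2.355 (default FWHM 4 mm, at the
sharp end of clinical PET); additive Gaussian noise follows, and
negative values are clipped to zero. Ground truth records the pre-blur
geometry, so measured SUVmax ≤ the specified peak and voxelized volumes
converge to the analytic (4/3)πr₁r₂r₃ as spacing shrinks. Not modeled:
attenuation, scatter, reconstruction artifacts, respiratory motion,
non-ellipsoidal or necrotic lesions — phantom tests validate the
measurement chain, not clinical detection sensitivity.

**Paired readers.** Per patient, a latent MTV is log-normal (median
75 ml, log-SD 1.5, spanning roughly 1–1300 ml, the range seen in
large-cell lymphoma cohorts; not calibrated to any specific cohort);
each reader observes latent × exp(N(0, σ_r)) with σ_r = 0.15 by default,
giving overall concordance near 0.96. TLG = MTV × a per-patient SUVmean
drawn uniform on [4, 15]; lesion counts (1 + Poisson, mean 7) are shared
between readers. Real reader disagreement is not purely multiplicative —
it includes whole-lesion inclusion/exclusion — so the generator
reproduces cohort-level agreement structure, not its mechanism.

**Survival.** Event times are exponential with rate
0.02·exp(0.0015·MTV) per month (hazard ratio ≈ 1.0015 per ml, the
reported magnitude for metabolic burden in CAR-T-treated lymphoma),
censored by an independent exponential (rate 0.015/month) capped at 36
months. LDH (log-normal around 320 U/l) and ECOG (0–3, ~80% 0–1) are
drawn independently of MTV, so multivariable fits test machinery, not
confounding structure. A follow-up cap of 0 produces an all-censored
cohort on which downstream fits raise cleanly.

All generators draw from one `numpy` Generator seeded per call; a fixed
seed reproduces outputs exactly, and the pipeline writes floats with 6
significant digits so byte-identical re-runs are testable.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems: phantoms of
50³–80³ voxels at 2 mm, cohorts of 96 patients (matching the emulated
study size), 200-replicate calibration loops at n = 96 (log-rank type-I
error) and n = 500 (Cox recovery), and a 10⁶-draw closed-form check for
the reader-pair generator's concordance. The log-rank calibration
accepts a rejection rate inside the binomial 95% band around 0.05; the
Cox check requires ≥ 90% CI coverage and a mean estimate within one
Monte-Carlo SE of truth. The latter is a stringent bar: the
partial-likelihood MLE carries a small positive finite-sample bias
(~+1% of β at n = 500 under this heavy-tailed covariate, verified
against an independent implementation), which exceeds one 200-replicate
SE; the check is kept as specified and its outcome reported honestly
rather than loosened.

## Known limitations

- Detection is threshold-plus-connectivity only; no discrimination of
  physiologic uptake from tumor (by design — that is the reader's job).
- SUV conversion supports body-weight normalization only (no lean-body
  mass or body-surface variants); DICOM ingestion is out of scope, NIfTI
  is the on-disk format.
- CCC confidence intervals assume approximate bivariate normality;
  heavy-tailed burden distributions make them optimistic in the extreme
  tertiles.
- The synthetic cohort cannot validate clinical cut points; published
  cut points are carried as worked-example constants, not estimated.
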