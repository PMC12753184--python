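# Methods

This note documents the models, parameter choices and numerical
conventions behind `dcistil`, and what the synthetic-data experiments do
and do not demonstrate.

## Imaging pipeline

**Stain model.** Images are converted to optical density per channel,
`OD = -log10((I+1)/256)`, and unmixed by least squares onto the
Ruifrok–Johnston H&E vectors (hematoxylin (0.65, 0.70, 0.29), eosin
(0.07, 0.99, 0.11), unit-normalised). Negative coefficients are clipped
to zero; stain matrices with condition number above 10⁶ are rejected as
degenerate. The `+1` in the OD formula keeps black pixels finite; pure
white maps to OD ≤ 0.002.

**Nuclei segmentation.** The hematoxylin channel is thresholded by Otsu's
method with a floor of 0.10 OD — without the floor, a tile containing no
nuclei at all would have Otsu binarise sensor noise. The binary map is
opened with a 1 µm disk, and touching nuclei are split by a watershed on
the negated distance transform, seeded at local maxima at least 3 µm
apart (the lymphocyte diameter floor). Components smaller than 10 µm²
are dropped. Circularity `4πA/P²` uses the Crofton perimeter; values may
exceed 1 slightly on discretised disks and are clipped at 1.05.

**Lymphocyte rule.** A nucleus is a lymphocyte iff area ∈ [15, 80] µm²,
circularity ≥ 0.80 and mean hematoxylin OD ≥ 0.40, all bounds inclusive
and all configurable (`LymphocyteRule`). This is a deterministic
morphometric stand-in for learned TIL classifiers: small, round,
hyperchromatic. It deliberately ignores texture and context.

**Stroma.** Tissue is separated from glass in HSV space (saturation
≥ 0.05 and value ≤ 0.95); stroma is tissue minus the annotated DCIS
minus non-lymphocyte nuclei inside the annotation dilated by 2 µm (so
epithelium spilling across the annotation boundary is not counted as
stroma).

## Microenvironment geometry

Annotations are simple polygons in (x, y) order, pixels or microns. A
pixel belongs to the rasterised mask iff its centre lies strictly inside
a polygon (even-odd rule); pixel (r, c) covers the half-open unit square
[c, c+1) × [r, r+1) with centre (c+0.5, r+0.5). With this convention an
axis-aligned 100 × 100 µm square at 1 µm/px rasterises to exactly
10,000 px.

The periductal ring is `{p ∉ DCIS : 0 < d(p, DCIS) ≤ r/mpp}` with
Euclidean distances from the distance transform of the mask complement;
default radius 250 µm with 200 µm as the sensitivity setting. Rings of
multiple ducts merge by union, so overlap is never double-counted, and
no ring pixel ever lies in any annotated duct. The ring ∩ stroma region
is partitioned into a fixed square grid anchored at the image origin
(default patch 100 µm; the patch size of the original pipelines is not
published, and 100 µm is large enough for stable per-patch fractions).
Half-open boxes make patch membership — including lymphocyte centroids
on box boundaries — unambiguous and order-independent.

## Scoring

Per-patch TIL density is the lymphocyte-nucleus area divided by the
stromal area of the patch, clipped to [0, 1]; a nucleus contributes its
whole area to the patch holding its centroid. The patient-level raw
density is the stroma-area-weighted mean over patches (unweighted means
would over-weight sliver patches at the ring edge; a count-per-mm²
definition is available via `score_mode="count_per_mm2"`). The published
score scale is raw density × 10, applied before thresholding so that
thresholds live on the published scale. Patients with under 0.01 mm² of
ring stroma, or no annotated duct, are flagged not evaluable and carry
no score.

Dichotomisation uses the cohort median of evaluable scores (midpoint
convention for even n) unless a frozen threshold is supplied; ties go to
the high category. The threshold is echoed in every assignment so it can
be reused on new patients.

## Synthetic histology

Tiles are rendered through the same OD stain model the analyser inverts:
stroma at eosin 0.35 / hematoxylin 0.08 OD, duct cytoplasm at eosin
0.16, glass at zero, lymphocytes as disks of diameter 6–9 µm at
hematoxylin 0.75–1.0, epithelial nuclei as 9–14 µm ellipses (axis ratio
0.55–0.80) jittered into clusters inside ducts. Gaussian OD noise
(σ = 0.02) is added and the image blurred by 1 px; the noise is added
before the blur so that pixel-level noise is spatially correlated rather
than white — unsmoothed white noise on near-white channels would
misclassify a visible fraction of glass and stroma pixels under the
fixed HSV thresholds. Lymphocyte counts are Poisson with mean
density × stroma area; positions are uniform over stroma pixels.
Everything derives from one `default_rng(seed)`, so identical specs
render bit-identically.

The default test tile is 400 × 400 px at 1 µm/px with a central circular
duct of radius a quarter of the tile side. The 1 µm/px scale matters: at
2 µm/px the 1-px blur plus discretisation inflates segmented lymphocyte
areas past the 80 µm² classification cap and counts are systematically
lost, so the generator should be regarded as emulating tiles at roughly
10× magnification equivalents. What the synthetic experiments show is
that the chain is internally consistent — the analyser recovers what the
generator plants (count recovery within ~10 % over 25–400/mm², score
calibration R² ≈ 0.99 against planted area fraction). They do not show
robustness to real-world variation: nuclear texture, stain variability
across scanners, fibroblasts and plasma cells with lymphocyte-like
morphometrics, or annotation error are all absent by construction.

## Synthetic cohorts

Covariates approximate a DCIS trial population: age ~ N(57.4, 6.0)
years, tumour size ~ N(15.6, 8.5) mm truncated positive, treatments as
independent Bernoulli(0.5) (a 2 × 2 factorial), HER2 prevalence 0.35,
and a lognormal score distribution matched to a published summary
(median 0.71, mean 0.90 on the ×10 scale) with the TIL category cut at
the quantile giving the requested prevalence (default 0.5). Two latent
exponential event times (in-situ recurrence at baseline 0.03/yr,
invasive progression at 0.02/yr for a reference patient) compete; the
earliest wins if it precedes administrative censoring at 10 years.
Planted log hazard ratios enter per cause, with an optional
TIL × radiotherapy interaction on the log-hazard scale. The exponential
baseline is immaterial for hazard-ratio recovery since the Cox model is
semi-parametric. `recovery_experiment` reads the planted comparison
value from the in-situ cause's log-HR dictionary; for composite-IBE
recovery both causes should plant the same value (as the shipped
experiments do).

## Statistics

Cox models are cause-specific with Efron tie handling (lifelines): when
one recurrence type is modelled, a patient whose first event is the
competing type is censored at that time, matching a first-event
analysis. Model χ² is the likelihood-ratio statistic against the null;
nested models are compared by δχ² = 2·Δlog-likelihood with degrees of
freedom equal to the added parameters, and comparisons across different
case-complete rows are rejected rather than silently reconciled.
Interaction p values come from the LRT of the product term; subgroup
treatment HRs are displayed from stratified fits (separate baseline
hazards), which agree with the joint model's `exp(β_b)` and
`exp(β_b + β_ab)` to within a couple of percent but are not numerically
identical.

Matched sets pair each case (any IBE) with up to two event-free controls
sharing the exact treatment allocation, within ±7 years of age, and
followed at least as long as the case's event time; selection among
eligibles is seeded-uniform without replacement across sets, cases
processed in patient-id order for determinism. Conditional logistic
regression maximises the per-set conditional likelihood (statsmodels,
Newton iterations at tolerance 1e-12, BFGS fallback), which on 1:1 sets
reproduces the classical discordant-pair ratio b/c to machine precision.
An analysis with no exposure-discordant set raises rather than returning
an unbounded estimate.

Rank statistics: Spearman with mid-rank ties (constant inputs flagged
undefined); Mann–Whitney for two continuous groups, exact enumeration
when the pooled n ≤ 10 and tie-free; Kruskal–Wallis otherwise, with an
exact enumeration over group assignments for pooled n ≤ 10. The
asymptotic two-group Mann–Whitney is computed without continuity
correction, making it numerically identical to the two-group
Kruskal–Wallis χ². Crosstab percentages are within-TIL-column with
non-missing column totals as denominators; missing values are counted
and reported, never imputed. All tests are two-sided at α = 0.05.

## Problem sizes in the shipped experiments

The repeated-simulation experiments use n = 1000 patients × 200
replicates for Cox recovery, 200 null and 100 alternative replicates
(n = 1000 / 4000) for the interaction error rates, 60 tiles for score
calibration and 30 patients for radius sensitivity — sizes chosen so the
Monte-Carlo error is small relative to the acceptance bands while a full
run stays in the minutes range on a single CPU.

## Known limitations

- The lymphocyte classifier is morphometric only; it cannot separate
  lymphocytes from other small round hyperchromatic cells, and spatial
  TIL subtypes (e.g. touching the basement membrane) are out of scope.
- The ring is measured from the annotation polygon as drawn; if an
  annotation traces outside the basement membrane the ring shifts with
  it.
- Whole-slide pyramidal formats are not handled; inputs are tiles or
  region crops with known mpp.
- No colour normalisation across scanners; stain vectors are fixed
  unless overridden.
- The cohort simulator plants proportional hazards by construction, so
  it cannot probe proportionality violations.
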