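# Methods

This note records the models, parameter choices and limitations behind
`tmeniche`. Everything quantitative stated here is computed by the test
suite, the `analysis/` scripts, or `scripts/acceptance.py`.

## Data model

Cells are points: the segmentation centroid in continuous μm, origin at
each ROI's lower-left corner. Membrane-to-membrane distances are not
modelled; every distance in the package is centroid-to-centroid. The
cell-type vocabulary is panel-driven: the compact 7-marker clinical panel
(CD4, CD8, CD20, CD11c, CD68, PD-L1, panCK → Th, CTL, B, DC, PD-L1⁺M,
PD-L1⁻M, tumor) and a 16-marker discovery panel (adding Treg, plasma
cells, M1/M2 macrophages, monocytes, neutrophils, endothelium, fibroblasts
and FAP⁺ CAFs, plus a Ki67 proliferation flag) run on the same machinery.
ROI bounds travel in a plain-text sidecar and are inferred from coordinate
extremes when absent. ROI physical size is not fixed by the data model;
the default is 1,000 × 1,000 μm (1 mm²), configurable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not tissue realism:

* **Background**: homogeneous Poisson field (default 2,000 cells/mm²,
  chosen so a 1 mm² ROI holds ~2,000–2,500 cells, at the low end of
  plausible pancreatic-tissue densities) with a tumor-dominated type
  mixture (75% tumor on the clinical panel).
* **Niches**: isotropic Gaussian blobs (SD = `blob_radius`, default
  30 μm; expected 100 member cells) whose member types are drawn i.i.d.
  from the niche composition. Two archetypes ship by default: a DC/T-cell
  niche (DC 0.30, CTL 0.25, Th 0.25, macrophage 0.20) and a stromal,
  immunosuppressive niche. On the discovery panel the stromal niche is
  fibroblast-dominated; the clinical panel stains no fibroblast marker,
  so there it is emulated as PD-L1⁺-macrophage/tumor/B-dominated — the
  closest immunosuppressive composition the 7-type vocabulary can
  express.
* **Planted effect**: blob counts per ROI are Poisson with archetype
  rates (non-responders: DC/T 0.8, stromal 2.5 per ROI); responders
  receive DC/T blobs at `effect_size` × the non-responder rate
  (default 4, the null being 1).
* **Cohort**: 16 responders + 31 non-responders (≈ one third responders,
  as in the trial) with 1–3 ROIs each. Note the trial reports 149 ROIs
  from 47 patients, which is arithmetically inconsistent with "1–3 ROIs
  per patient"; the generator follows the 1–3 range (expected ≈ 94 ROIs).
* **Markers**: intensity = signature value + N(0, `noise_sd`), truncated
  at 0. Signatures use high = 2.0 arbitrary units, low = 0; against the
  default noise SD of 0.5 this emulates a clean amplified stain
  (signal-to-noise 4). Under these conditions nearest-signature gating
  reaches ~0.96 accuracy on the 7-type panel.
* **Clinical**: survival is exponential with class-specific rates
  (non-responder medians: OS 7, PFS 4.5 months; responder hazard ratio
  0.5) under independent Uniform(6, 24)-month administrative censoring —
  the simplest model sufficient to exercise Kaplan–Meier and log-rank
  machinery. CA19-9 declines are Beta-distributed, more favorable in
  responders.
* **Reproducibility**: one integer seed feeds `numpy.random.SeedSequence`
  (PCG64); child 0 drives cell placement, child 1 clinical outcomes, so
  sub-streams are independently reproducible.

What passing tests on these cohorts do **not** show: robustness to
segmentation error, marker spillover, anisotropic tissue architecture,
batch effects across staining runs, or niche shapes other than Gaussian
blobs.

## Phenotyping

Marker columns are z-scored over the analysis set (population SD;
zero-variance columns become all-zero). Each cell is assigned the lineage
whose signature row — pushed through the identical standardization — is
nearest in Euclidean distance. Direct cosine matching against raw
signatures was rejected: when one type dominates the population (tumor
cells here), its marker's z-scale compresses and the dominant class
scores poorly. The reported score is the cosine between the cell and its
winning signature, both measured from the centroid of all transformed
signatures, which keeps the score scale comparable across types; cells
scoring below the similarity floor (default 0.3, calibrated for the
7-marker panel) are labelled "other". Wider panels dilute the score with
noise across more markers — on the 16-marker panel a floor near 0.15–0.2
is more appropriate and accuracy saturates around 0.85 at noise SD 0.5.
Exact distance ties break by the declared priority order (tumor > T
subsets > myeloid > B), making assignment deterministic and
order-independent. PD-L1 status is resolved after lineage by thresholding
the z-scored PD-L1 column at the midpoint of the split pair's transformed
signature values; Ki67 positivity is an orthogonal flag at z > 1.

Hotspot selection replaces the study's manual choice of CTL-rich regions
with a deterministic maximizer: candidate windows on a 10 μm grid are
scored by contained target cells (half-open windows, computed exactly by
2-D prefix sums) and chosen greedily without overlap.

## Niches

Neighborhoods use a closed ball of radius 50 μm (≈ 3–4 cell diameters, a
standard choice; the source analysis states only "a fixed radius"),
excluding the index cell. K-means uses K = 10 by default (the reported
niche count), pooled across patients so niche identity is comparable
between them, with 10 restarts and a fixed seed; fitted ids are
relabelled in descending cluster-size order because raw K-means labels
are arbitrary. Zero-neighbor cells are excluded from the fit and carry a
reserved "isolated" id (−1) rather than polluting the centroids with zero
vectors. Group comparisons default to the Mann–Whitney U (the ratios are
bounded and skewed); Welch's t is available. BH-FDR is reported alongside
raw p-values across niches or pairs.

Planted-archetype recovery is scored at K = 3 (two archetypes +
background) by the adjusted Rand index over blob-member cells. At the
default generator conditions the ARI sits at ~0.89–0.91 across cohort
draws: blob-edge cells see mostly background within 50 μm, so perfect
recovery is not expected.

## Interactions

Edges join cells with centroid distance **strictly** below 15 μm (ties at
exactly 15 μm excluded), within ROIs only. KD-tree candidate pairs are
filtered to the strict inequality so the graph equals a brute-force O(n²)
construction exactly — the test suite asserts bit-for-bit equality. Each
unordered pair counts once (an A–A edge adds one to the diagonal), so the
upper-triangle sum equals the edge count. The default "interaction
intensity" divides a pair's edge count by the smaller of the two type
counts (0/0 → 0), so ROI size does not dominate; raw and per-area (mm⁻²)
normalizations are retained. The cross-ROI normalization of interaction
intensity is an explicit assumption surfaced in configuration — the
source analysis does not state its own.

## Response and survival models

Features per ROI: 7 type ratios, 7 densities (cells/mm²), and the 15
unordered pairs among the 6 non-tumor types — C(6,2) = 15 exactly matches
the reported feature count, and is adopted as such (flagged as this
package's reading, not an established fact). Repeated splits default to
100 repeats at 75/25. Splitting is **patient-grouped** by default (no
patient contributes ROIs to both sides), preventing within-patient
leakage; `groups=None` reproduces plain ROI-level splitting as the trial
describes. Standardization is fit on training rows only; the L1 logistic
regularization strength is chosen per repeat from 20 log-spaced values by
5-fold internal CV with the one-standard-error rule. AUC is computed on
held-out rows only — a leakage test asserts that shifting test rows
leaves training coefficients unchanged.

Boruta: each iteration appends per-column permuted shadow copies of the
still-active features, fits a 500-tree random forest, and records a hit
when a real feature's impurity importance beats the best shadow; a
two-sided binomial test (α = 0.01) on the running hit count confirms or
rejects, rejected features leave the forest, and undecided features after
30 iterations are tentative. Two behaviors worth knowing: (i) strongly
correlated encodings of the same signal mask one another — on planted
cohorts the six DC/T-niche pair intensities are mutually correlated at
r ≈ 0.9, and the full-table run typically confirms a subset of them along
with the ratio/density encodings; run Boruta on the feature subset of
interest to score a specific layer. (ii) A noise feature that is
chance-correlated with the labels in a finite sample is genuinely
informative in-sample and may be confirmed — the null calibration bounds
this at the α level on average, not per draw.

Survival endpoints are dichotomized at a cutoff (study values: OS
9.3, PFS 6.1 months): "long" means time ≥ cutoff (censored past the
cutoff still qualifies), "short" means an event before it; rows censored
before the cutoff are uninformative and excluded with a warning. Under
the exponential generator the class depends on the spatial features only
through responder status, and exponential noise is large, so the
achievable AUC is information-limited: with hazard ratio 0.5 the
responder-composition ceiling works out to ≈ 0.7, and measured AUCs of
0.5–0.8 across cohort draws reflect that ceiling plus sampling noise, not
a defect of the classifier. The analysis scripts record the class
composition alongside the AUC to keep this visible.

## Trial statistics

Kaplan–Meier estimation and the log-rank test delegate to lifelines
(Greenwood log-log intervals); the median convention is the smallest
observed time with S(t) ≤ 0.5, reported as infinity when never reached
(lifelines' strict-inequality median is overridden for this convention).
The Simon two-stage calculator searches all (r1, n1, r, n) up to a cap
(default 100) with exact binomial stage probabilities, returning the
optimal (minimum expected size under the null) or minimax (minimum
maximum size) feasible design. The trial's stated "alpha 0.05 (both
sides)" is ambiguous for a one-sided design problem, so the analysis
script reports both one-sided 0.05 and one-sided 0.025 searches rather
than resolving the ambiguity: at one-sided 0.05 the optimal design is
stage 1 = 5/14, final = 20/44 (EN₀ 24.8); the trial's printed plan
(6-of-17 stage-1 rule, ~49 patients) matches neither search exactly and
is shown alongside, not asserted. The futility rule "less than 6/17" is
read as stop iff stage-1 successes ≤ 5; the alternative reading is
selectable.

## Numerical conventions and degenerate inputs

Constant marker columns z-score to zero. Identical comparison groups
return p = 1 and difference 0 (zero-variance guard ahead of the
Mann–Whitney tie correction). Unit clustering sorts rows by unit id
before linkage so results are invariant to input order. All-censored
survival input yields a flat curve and an unreached median. Hotspot
selection warns and returns an empty list when no target cells exist. A
K-means request exceeding the number of distinct profiles raises rather
than returning empty clusters.

## Problem sizes

Default test and acceptance runs use cohorts of 20 + 20 patients
(~80 ROIs, ~200k cells), 40–100 split repeats, 250-seed null
calibrations, and 10⁶-draw Monte-Carlo checks of the design calculator —
sizes chosen so the whole suite completes in minutes on a single CPU
while keeping Monte-Carlo error well inside the asserted tolerances.
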