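# Methods

This note documents the models, algorithms, defaults and design choices
behind `glioprog`, and what the synthetic generators do and do not
emulate.

## Cohort data model

One row per patient; any field may be missing.  Missing tokens in CSV
input are the empty string, `NA` and `N/A` (case-insensitive) — REDCap
exports vary in their conventions.  Dates are never ingested: outcomes
arrive as precomputed day counts (OS = days from primary resection to
death, PFS = days to first novel enhancing lesion), mirroring
deidentified exports.  Derived variables are recomputed, never trusted
from input: NLR = neutrophils/lymphocytes (missing when either parent is
missing or lymphocytes are zero) and BMI = weight/(height in m)².
`derive_variables` is idempotent.

Summaries report categoricals as count (percent, half-up to two decimals)
and numerics as mean [min–max].  Molecular markers (ATRX, p53, EGFR
amplification, MGMT methylation) use the tested-only (non-missing)
denominator, demographics the whole cohort — the convention of
"percent from collected patients" summary tables.  When a percentage is
quoted as prose it is rounded to the nearest integer.

The missingness filter drops rows with strictly more than the threshold
(default 30%) of the *analysis feature set* missing; the feature set is
configurable because instruments differ in which fields count as
analysis-relevant.

## Synthetic cohort generator

The generator's defaults are the study conditions the clinical tests run
under, chosen once from published multi-site marginals:

| parameter | default | basis |
|---|---|---|
| age | truncated normal, mean 61, sd 12, [20, 89] y | cohort mean 60.6 [20–89] |
| WBC | log-normal, median 9.0, σ 0.38 (log scale), ×10⁹/L | mean ~9.8 |
| neutrophil fraction | Beta(22.2, 7.8), mean 0.74 | neutrophils ~7.2 of WBC ~9.8 |
| lymphocyte share | Beta, mean 0.70, κ 20, of non-neutrophil WBC | lymphocytes ~1.65 |
| steroid dose | zero-inflated (P₀ = 0.45) gamma(1.6, 3.2) mg/day | mean ~2.8, ~half tapered to zero |
| steroid→WBC | +0.018 per mg/day on the WBC log-mean | steroid-linked leukocytosis, sign only |
| MGMT methylated | Bernoulli 0.43 | 189 of 438 tested |
| center mix | 0.65 / 0.10 / 0.16 / 0.09 | 377/57/94/53 of 581 |
| baseline OS | Weibull shape 1 (exponential), median 540 d | median OS ~18 months overall |
| baseline PFS | same form, median 270 d | median PFS ~6–9 months |
| log-hazards | β_age 0.02, β_wbc 0.03, β_neut 0.047, β_mgmt −0.43, β_rad −0.05, β_tmz −0.16 | published per-unit univariate scale |
| censoring | admin horizon 2200 d + exp dropout, mean 4000 d | ~91% deceased |

Survival times are drawn by inverse transform from
S(t|x) = exp(−λ tᵏ e^η) with η the centered linear predictor, so the
uncensored event time and the true β vector are exact ground truth;
`os_event` is the indicator that the event precedes the censor time.
The per-patient lymphocyte share (the remainder standing in for
monocytes/eosinophils/basophils) keeps WBC from being an exact linear
combination of neutrophils and lymphocytes, which would make joint Cox
designs singular — as it would in real CBC data, where the differential
never sums exactly from two series.

A single global seed spawns independent child streams for covariates,
survival and missingness, so each stage is separately reproducible.
Missingness combines per-center blocks of never-collected fields
(emulating sites that do not record, e.g., lesion imaging details or
molecular panels) with a global MCAR cell rate (default 2%); patient id
and the OS outcome are never masked.

What the generator does *not* emulate: the real cohort's joint
distribution (marginals are configured, not estimated), informative
censoring, site-level outcome differences, and correlation magnitudes
between CBC and steroids/BMI beyond sign.  Passing recovery tests
therefore demonstrates the *estimators* are correct under the assumed
proportional-hazards structure, not that real GB data satisfy it.

## Imputation

Chained equations, single imputation (m = 1): the downstream PCA
consumes one completed table, so no Rubin pooling.  Variables are swept
in ascending-missingness order for up to 10 sweeps (early exit when the
max relative change in imputed-cell means drops below 1e-3).  Numerics
use predictive mean matching: OLS on the z-scaled other features, then a
uniformly drawn donor among the k = 5 observed values with nearest
predictions — imputations are therefore always observed values and stay
within the observed range.  Categoricals/booleans use the most frequent
observed class within the leaf of a shallow (depth-4) decision tree
predicted for the row.  Everything is deterministic given the seed, and
observed cells are returned bit-identical.

## PCA and the eigenvector plot

Correlation-matrix PCA: clinical features carry incommensurate units, so
each is z-scored with the population SD before SVD.  Loadings are the
unit-norm eigenvectors of the correlation matrix; component signs are
fixed (largest-magnitude loading positive) for bit-reproducibility.
Binary features are encoded 0/1; categoricals with more than two levels
are excluded from the decomposition rather than arbitrarily ordered.

Contribution of feature j to component k is 100·v²ⱼₖ (summing to 100 per
component); the displayed pair contribution is the eigenvalue-weighted
mean of the two components.  The biplot draws one arrow per feature,
colored by contribution, omitting features below a configurable floor.

Relationship calls use the cosine between the two features' loading
vectors restricted to the displayed plane (default components 1–2):
direct if cos ≥ τ, inverse if cos ≤ −τ, else orthogonal, with τ = 0.5 so
the 60° boundaries split the plane into thirds; a near-zero projected
vector returns "indeterminate" instead of a category.  No rotations are
applied.

## Survival analysis

`fit_cox` maximizes the Cox partial likelihood with the Efron tie
correction (day-resolution survival ties heavily) by Newton–Raphson:
convergence at gradient norm < 1e-9, max 100 iterations, step-halving to
keep the likelihood non-decreasing, standard errors from the inverse
observed information.  A monotone likelihood (perfect separation) is
diagnosed when any per-SD log hazard |β·sd(x)| exceeds 15.  Efron and
Breslow agree exactly on untied data, which the tests exploit.

The univariate screen fits each feature on its own non-missing subset and
retains Wald p < 0.05; the full fit table is kept for reporting.  No
multiple-testing correction is applied across the ~29 tests — faithful
to the original workflow — but Benjamini–Hochberg is available
(`adjust="bh"`, off by default).  The multivariate model refits retained
features jointly on complete cases, warning below 10 cases per covariate
and rejecting designs with condition number > 1e10 (naming the worst
pair).

Quartile stratification cuts at the 25th/75th percentiles under the
linear-interpolation (type-7) definition — documented because group
membership depends on it — with inclusive boundaries (≤ Q1 / ≥ Q3), so
boundary ties can push a group above 25% of patients; unequal group
sizes are logged rather than resolved by arbitrary exclusion.
Kaplan–Meier curves use the product-limit estimator with censoring at an
event time processed after that time's events; the median is the
smallest event time with S(t) ≤ 0.5.  The log-rank statistic sums
hypergeometric O−E and variance over pooled event times, referred to
χ²(1).

## IHC pipeline

Optical density is OD = −log₁₀((I+1)/(i0+1)) per channel (the +1 guards
log 0; i0 = 255).  Unmixing solves OD = M·c per pixel by least squares
with the standard published H-DAB absorbance vectors as the default
matrix (hematoxylin (0.650, 0.704, 0.286), DAB (0.268, 0.570, 0.776),
unit-normalized; overridable); negative concentrations are clipped to
zero and counted.  Otsu thresholding operates on each deconvolved
concentration channel — not raw intensity — with a 256-bin histogram
over [min, max], returning the bin edge maximizing between-class
variance (ties to the lowest edge).  Segmentation takes 8-connected
components of (channel ≥ threshold), discards regions under 20 px, and
records area, centroid, mean/max concentration, perimeter, eccentricity
and solidity.

The stain-class filter is a 200-tree random forest over those six
morphology features, trained on synthetic segments labeled by true mean
concentration against cut points (default 0.15 / 0.45 / 0.80 for
no/low/medium/high) — a synthetic stand-in for manual pathologist
labels, which are not available.  Regions classed "no" are removed; the
PDL-1 score is then DAB area / hematoxylin area, flagged undefined when
the denominator is zero.  Group comparisons use the two-sided Wilcoxon
rank-sum (exact null for combined n ≤ 20 without ties, tie-corrected
normal approximation otherwise); the test choice is a documented
package decision.  Per-patient scores across multiple tiles pool by
summed areas (area-weighted), so large tiles count proportionally.

## Synthetic tiles

Nuclei are rendered as hard-edged ellipses (axis ratio 0.7–1.0, radius
N(7, 1.2²) px) placed by rejection sampling so outer radii never overlap
(packing error after 1000 attempts per cell).  Membranous PDL-1 is an
annular ring (default 2.5 px) around a configurable fraction of cells —
rings and nuclei are disjoint by construction, making the true area
ratio unambiguous.  Per-cell stain concentrations default to a narrow
0.45–0.85 band, reflecting the relative homogeneity of a counterstain;
the classifier-training configuration instead spans 0.1–1.2 with dim
artifact specks so all four stain classes have exemplars.  Fields render
to RGB through the same Beer–Lambert matrix the pipeline inverts (a
mismatched matrix mode probes robustness), Gaussian noise is added in
8-bit intensity space, and ground truth records the pre-noise areas.

## Problem sizes and numerical choices

The test suite and acceptance script run at sizes chosen for tight
Monte-Carlo bounds at interactive cost: parameter recovery at n = 2000
(3-SE bounds), null-screen calibration over 500 replicates of n = 200
cohorts (binomial SE ~0.01 around 0.05), PCA calibration over 200
replicates at n = 2000, tile recovery on 192² px tiles with 40 nuclei.
Oracles are independent of the code they check: brute-force 1-D partial
likelihood maximization, exhaustive Otsu search, hand product-limit and
hypergeometric fixtures, full rank-sum permutation at n = 6, and
`lifelines` as an external cross-check for Cox/KM/log-rank.

## Known limitations

- No time-varying covariates, frailty, or proportionality diagnostics.
- No whole-slide imaging, tumor-region detection, or TPS/CPS scoring;
  tiles are assumed pre-selected.
- The tile renderer is not photorealistic: no texture, chromatic scanner
  variation, overlapping cells, or out-of-focus blur, so classifier
  accuracy on synthetic segments overstates accuracy on real stains.
- Single imputation understates downstream variance relative to
  multiple imputation.
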