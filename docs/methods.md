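# Methods

`crypsis` implements the quantitative core of an integrative
species-delimitation workflow for a cryptic Nearctic ant separated from
Palearctic look-alikes: discriminant morphometrics, DNA-barcode mitotype
diversity, averaged body-profile imaging, and a lightweight ensemble
niche model with thresholded habitat-area estimation. This note records
the models, the defaults and their rationale, the numerical conventions,
and what the synthetic generators do and do not emulate.

## Morphometrics

**Measurement system.** Nineteen variables per specimen: absolute lengths
in mm (CL, CS, CW, dClAn, EYE, GuHL, MP6, PLF, PnHL, PoOc, SL), the
pubescence distance sqPDCL in µm, six setae counts, and the categorical
offset-mandibular-denticle state MaDe. CS (cephalic size) is defined as
(CL + CW)/2 and is filled from head length and width when absent; a
supplied CS deviating from that identity beyond rounding noise triggers a
warning. Size-corrected ratios (CL/CW, SL/CS, EYE/CS, GuHL/CS, dClAn/CS,
MP6/CS, PnHL/CS, PoOc/CL) are the group-comparison currency.

**Diagnostic function.** The frozen `PUBLISHED_D` is the published linear
diagnostic score

D = −43.792·GuHL + 113.436·dClAn + 75.68·MP6 − 0.431·nSt − 10.075

with lengths in mm and nSt a raw count; D < 0 diagnoses the Nearctic
species, D > 0 the Palearctic complex, D = 0 is reported as ambiguous.
The original coefficient normalization is not reproducible from the
description alone, so freshly fitted discriminants match `PUBLISHED_D`
only up to a positive scale factor: all comparisons between fitted and
published models are made on classifications and signs, never on raw
coefficients.

**LDA.** Two-group linear discriminant analysis in closed form: direction
w = S⁻¹(μ_pal − μ_nea) with the pooled within-group covariance S, and an
intercept placing the boundary at the midpoint of the projected group
means; the sign convention puts the Nearctic group below zero. Singular S
raises an error suggesting variable reduction; identical group means are
rejected (the direction is undefined). Classification is invariant under
invertible affine transforms of the inputs, which the tests verify.

**Stepwise selection.** Bidirectional stepwise logistic regression
minimizing AIC, starting from the intercept-only model; at each round the
single addition or removal with the lowest AIC wins, ties broken
alphabetically, stopping when no move improves. Covariates are
standardized internally (AIC ordering is unaffected). Under perfect
separation the maximum-likelihood fit diverges; the step falls back to an
L1-penalized likelihood (pseudo-AIC from the penalized log-likelihood)
with a warning. The search direction and criterion are this package's
choice — they are standard, deterministic, and documented here because
the source workflow did not pin them.

**Group comparison.** Per variable: median [min, max] per group; Wilcoxon
rank-sum (two-sided; exact when sample sizes permit and there are no
ties, otherwise normal approximation with continuity correction — the
semantics of R's `wilcox.test`) for numeric variables; Fisher's exact
test on the present/absent collapse of MaDe. No multiple-testing
adjustment, matching the source table's reporting. Medians interpolate
between order statistics for even n. Fully tied variables report p = 1
with a warning. Complete-case analysis per operation with dropped-record
counts carried in the result rows.

**Indices.** CI = round(100·HW/HL) and SI = round(100·SL/HW), half-up to
integers. The SI denominator is HW — forced by the holotype arithmetic
(100·0.821/0.823 → 100).

**PCA.** On the reduced four-variable set (GuHL, dClAn, MP6, nSt by
default), standardized to unit variance, via SVD; explained-variance
fractions sum to one, loadings are orthonormal.

## Barcode population genetics

Sequences are aligned COI fragments (canonically 658 bp; other lengths
are accepted with a warning) over {A,C,G,T,N,-,?}; IUPAC ambiguity codes
are mapped to N with a warning.

**Mitotype collapsing.** Two policies. `strict` (default): sequences
share a mitotype iff identical as strings, with N/-/? treated as ordinary
states — the default of commonly used haplotype-collapsing software.
`wildcard`: a sequence joins the first existing mitotype whose
representative (first member) matches it at every mutually non-missing
site, greedily in input order; this never yields more mitotypes than
strict collapsing. Collapsing is idempotent and preserves member ids.

**Diversity.** Haplotype diversity is Nei's unbiased estimator
h = n/(n−1)·(1 − Σp_i²). Pairwise distances are uncorrected p-distances
with pairwise deletion (mismatches over mutually non-missing sites); no
multiple-hit correction is applied anywhere, matching the "uncorrected
divergence" convention of the source analysis. Nucleotide diversity π is
the mean p-distance over all n(n−1)/2 pairs; pairs with no comparable
site are flagged NaN and excluded (an error only if every pair is empty).
Alignment summaries count a site as variable when ≥ 2 distinct states
among {A,C,G,T} occur; missing fraction is the share of N/-/? cells; GC
is computed over non-missing cells.

**Formatting.** Percentages print with half-up rounding to one decimal,
so 4/658 = 0.00608 prints as 0.6%.

## Profile imaging

Images are H×W intensity matrices in [0, 1] (0 = black). Standardization
maps each lateral-view photograph into a canonical frame: isotropic
scaling by target length / measured mesosoma length, and translation
taking a user-marked anchor (by convention the anterior-most pronotum
point) to a fixed canonical position (default: mid-height, one quarter
from the left). Bilinear resampling, white fill outside the source.
Binarization thresholds at 0.5 by default (configurable); averaging is
the pixel-wise arithmetic mean, linear and permutation-invariant. The
anchor convention and threshold are package choices — the source
describes only "same length and position" and "black and white" — and
both are parameters.

## Ensemble niche modelling

**Learner.** One reference learner, a ridge-penalized logistic
suitability model (internal covariate standardization; L2 penalty,
default α = 1, not on the intercept; L-BFGS on the penalized negative
log-likelihood), behind a registry so other learner families can plug
in. The seven-family learner suite of the source workflow is deliberately
not re-implemented: the reusable substance is the evaluation, ensembling,
projection and area arithmetic.

**Ensemble.** k members (default 20 in the CLI design, smaller in tests)
fitted on with-replacement bootstrap resamples of the occurrence points,
redrawn until both classes are present; member weights are their TSS on
the full fitting set, floored at zero; the ensemble prediction is the
weighted mean of member probabilities.

**Evaluation.** AUC by the Mann–Whitney rank statistic with ties counted
½; TSS = max over thresholds of sensitivity + specificity − 1, searched
over the unique observed scores (exact for step-function metrics, with
"predict presence when score ≥ t"); Cohen's kappa reported at the
TSS-optimal threshold.

**Projection and areas.** The ensemble is applied cell-wise to any grid
carrying the training layer names — including a second region, enabling
range transfer — with nodata propagated. Habitat area above a threshold
t is the count of cells with p strictly greater than t times the median
spherical cell area, R²·Δλ·|sin φ_top − sin φ_bottom| with R = 6371 km,
the median taken over non-nodata cells of the projection grid. Areas are
monotone non-increasing in t by construction.

**Variable importance.** Permutation importance: 1 minus the Pearson
correlation between baseline predictions and predictions after permuting
one covariate, averaged over repetitions (deterministic given the seed),
clipped to [0, 1]; constant baselines report 0 with a warning.

**Rasters.** ESRI ASCII grids (.asc) are read and written directly (the
format is six header lines plus a whitespace matrix; NODATA_value maps to
NaN); a directory of .asc files with matching georeferencing forms a
layer stack.

## Synthetic generators

One integer seed fans out to independent per-stage streams via fixed
offsets; the same seed reproduces every stage byte for byte.

**Morphometrics.** The published comparison table gives only per-group
medians and ranges. Each variable is drawn from a *split triangular*
distribution: half the probability mass on each side of the printed
median, density peaking there and decaying linearly to each printed range
end. A plain triangular with its mode at the median cannot realize
strongly skewed printed ranges (e.g. a count with median 8 on [2, 25]),
whereas the split form pins the population median at the printed value
for any range. Head size CS is drawn first and absolute appendage lengths
derive from sampled size-corrected ratios times CS, inducing realistic
size correlation; counts are rounded and clipped at zero. What this does
not emulate: the real correlation structure among ratios, measurement
error, and any within-group geographic structure — so passing tests show
estimator and pipeline correctness under a plausible marginal model, not
biological realism.

**Alignments.** k haplotypes derive from a random reference by
substituting exact per-haplotype site counts at disjoint site sets, so
the pairwise divergence between non-reference haplotypes is the sum of
their counts — exact, at the price of a star-like topology. Two frozen
design presets mirror the two published sampling designs: a
*deep-lineage* preset (n = 28, k = 15, count profile 8/4/3/2/1×11 giving
Nei h = 0.8995, divergences in four depth classes whose deepest pair is
39/658 ≈ 5.9%, π ≈ 0.012) and a *low-diversity* preset (n = 70, k = 7,
dominance profile 35/16/10/4/2/2/1 giving h = 0.682, max pairwise 4
substitutions = 0.6%). Limitation: with h fixed at 0.682 the
disjoint-site construction cannot push π below ≈ 0.0015 per site, so the
low-diversity preset's π is slightly above the sub-0.001 value a
star-shaped real genealogy can attain; shared-site homoplasy would be
needed and is deliberately not modelled.

**Landscapes.** Layers are smooth standardized fields (random linear
gradient plus low-frequency sinusoids plus mild noise) on a regular
lon/lat grid; the true occurrence probability is a logistic function of
the layers with known coefficients; labels are Bernoulli draws at
sampled cells until the design counts (default 180 presences, 182
absences) are reached. The default coefficients (3.0, −2.5, 0, 0) are
set so that the true surface itself discriminates presences from
absences at the performance level a well-performing model suite reports
(AUC comfortably above 0.9 for any landscape realization) — two
informative and two uninformative layers also exercise the
variable-importance contrast.

**Images.** A parametric mesosoma silhouette (pronotum bump plus
propodeum dome; the dome-to-bump height ratio is the group shape
parameter) is drawn per specimen under small random affine jitter
(isotropic scale sd 0.02, translation sd 1 px). With 35–50 specimens the
binarized average recovers the generating silhouette to pixel-wise MAE
well under 0.05.

## Problem sizes and numerics

The test suite and the acceptance script run everything at the published
design sizes (88 specimens, 28- and 70-sequence alignments, 180/182
occurrence points on a 40×60 grid) or smaller; Monte-Carlo checks use
n = 200–2000 where convergence is the property under test. Tolerances:
exact identities are asserted to 1e-9–1e-12; Monte-Carlo quantities to
2 standard errors or the band stated with the property. Degenerate
inputs (empty groups, singular covariances, single-class labels,
all-missing sequence pairs, constant predictions) raise typed errors or
warnings as documented per function.

## Known limitations

- Fitted discriminants reproduce published classifications, not the
  published coefficient values (normalization underdetermined).
- Mitotype counts on real data depend on the missing-data policy; both
  policies are provided and the strict default is a convention.
- The area estimator inherits the "median cell size" approximation; on
  large or high-latitude windows a per-cell exact sum would differ.
- No coalescent realism in sequence simulation and no photographic
  realism in image simulation; generators exist to give every estimator
  a known ground truth, not to mimic raw field data.
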