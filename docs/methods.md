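# Methods

`oxim` implements a multi-cohort tumor-subtyping analysis for bulk
expression data: cross-cohort integration by median binarization, consensus
clustering into an oxidative/proliferative (OX+) and an immune-infiltrated
(IM+) subtype, molecular and clinical characterization of the subtypes, and
a compact gene-panel classifier that predicts the subtype of new samples.
Because the public cohorts the design targets cannot be bundled, the package
ships a synthetic multi-cohort generator that plants the structure every
stage is supposed to recover; all claims the tests make are claims about
recovery of that planted structure.

## Integration by median binarization

Each cohort is processed independently: for every gene, the within-cohort
median is computed (midpoint of the two central order statistics for even
n) and a sample's value becomes 1 iff it lies strictly above that median.
Ties at the median therefore map to 0 and constant genes become all-zero —
a deterministic convention chosen over coin-flipping.  Binarization is
invariant to any strictly monotone per-(gene, cohort) transform, which is
exactly why it removes location/scale batch effects: cohorts that separate
completely in raw-value PC space mix after the transform.  The cost is the
loss of all within-half information about expression magnitude.

Cohorts are merged on the intersection of their gene inventories, sample
ids prefixed by cohort.  The merged matrix is split 50/50 at random,
without stratification, into training and testing halves.  Binarization
happens per cohort *before* the split, so both halves share per-(gene,
cohort) median thresholds.  This coupling is deliberate — it is the
published order of operations — and is called out rather than "fixed":
external validity rests on the testing half being re-clustered
independently, not on threshold independence.

The batch diagnostic is the mean silhouette coefficient of cohort labels in
the top-2 principal-component plane (samples centered; continuous input
optionally standardized per gene).  Values near 0 mean cohorts are
indistinguishable; values near 1 mean each cohort forms its own cloud.

## Consensus clustering

Subtypes come from resampled k-medoids: in each of `reps` (default 100)
iterations, `p_item` (default 0.8) of the samples are drawn without
replacement and clustered by PAM under Pearson-correlation distance
d = 1 − r (zero-variance profiles get d = 1 by convention).  The consensus
matrix entry for a pair is its co-clustering frequency among the iterations
that drew both.  Final labels cut an average-linkage tree built on
1 − consensus at k groups (k = 2 by default; the analysis targets exactly
two subtypes, but k is exposed).

PAM is implemented directly (no installed library provides it): greedy
BUILD, then best-improvement SWAP to convergence.  BUILD+SWAP can stall in
local optima that need a double exchange, so two extra seeded random
restarts of the SWAP phase are run and the best solution kept; on random
planar instances with n ≤ 7 the result matches exhaustive medoid
enumeration in well over 95% of cases.  Assignment ties break toward the
lowest medoid index.

Clustering, differential expression, and panel selection operate on a
curated analysis gene universe (supplied as a plain gene list), emulating
designs that restrict to a topical gene catalog; per-sample
microenvironment scoring uses the full gene complement.

## Naming the clusters

Clusters are anonymous until labelled.  Per-gene differential expression
between the two clusters uses the two-sided Fisher exact test on the
2×2 (cluster × {0,1}) table — on Bernoulli data this is exact and
assumption-free, where count-model dispersion machinery is ill-defined —
with fold change log2((p̂_A + ε)/(p̂_B + ε)), ε = 0.01, on the
within-cluster proportions of high calls, and Benjamini–Hochberg adjustment
across genes.  Genes ranked by fold change (ties by smaller p, then name)
feed a preranked GSEA: the enrichment score is the maximum deviation of the
weighted Kolmogorov–Smirnov running sum (weight exponent 1), the null is
10 000 random same-size gene sets by default (500 in the packaged runs),
NES = ES / mean |null ES| of matching sign, p one-sided with +1 smoothing,
BH across sets; sets with a degenerate null are flagged undefined and
excluded from the adjustment.  The cluster with the larger mean NES over
the oxidative marker sets becomes OX+, the other IM+; an exact tie falls
back to the immune marker sets with opposite sign.  The ranking statistic
and permutation scheme are package decisions — the tool family this
emulates does not pin them.

## Characterization

Per-sample gene-set scores are ssGSEA-style rank statistics (weight
exponent α = 0.25): within each sample genes get average ranks, and the
score integrates the gap between the weighted in-set rank ECDF and the
uniform out-of-set ECDF.  Rank-based scoring stays defined under the heavy
ties of 0/1 data, where kernel-density scoring degenerates.  Immune and
stromal signature scores are summed into a combined score and mapped to
tumor purity via the published calibration
purity = cos(0.6049872018 + 0.0001467884 · combined), clamped to [0, 1].
Cell-population abundance is the mean marker-gene value (the proportion of
high calls on binary data).  Group comparisons use the Wilcoxon rank-sum
test: exact null for combined n ≤ 25 without ties, otherwise the normal
approximation with tie and continuity corrections.  Checkpoint genes
(PDCD1, CTLA4 by default) are compared on the *continuous* pre-binarization
values, cohort by cohort, never pooled.  Clinical covariates: age by
rank-sum; sex and T/N/M stage by Pearson chi-square without continuity
correction, missing values dropped per covariate.

## Panel selection and classifiers

Candidate genes pass log2FC > 0.5 and adjusted p < 0.05 (both strict).
SVM-RFE ranks them: a linear SVM is refitted and the gene with the smallest
squared weight removed (ties broken by gene name) until one remains.
Candidate panel sizes {3, 6, 9, 12, 15, 18} are scored by stratified
fivefold CV accuracy of a linear SVM on the top-s genes; the chosen size is
the smallest within 0.005 of the best accuracy (the plateau rule).

Four families are tuned by grid search — decision tree (complexity
parameter cp, implemented as cost-complexity pruning α), radial-kernel SVM
(sigma, C), single-hidden-layer network (size, L2 decay), random forest
(mtry) — each grid point scored by replicated stratified fivefold CV
(50 replicates by default; the packaged study-scale run uses 5, and the
replicate count is a config knob, not part of any metric).  Fold metrics
are accuracy at a 0.5 score threshold and rank-statistic AUC; the winner
maximizes mean AUC, ties broken by mean accuracy, then by the simpler
model.  SVM scores are the logistic transform of the signed margin, so the
0.5 threshold coincides with the decision boundary; the other families
expose calibrated-enough predicted probabilities directly.  Folds are
stratified by class to stabilize fold AUC.  Per-gene importance is the
folded univariate AUC max(AUC, 1 − AUC) — a filter measure chosen because
kernel models have no native per-feature importance; the top gene is the
hub gene.

## Survival

Kaplan–Meier estimation and the unweighted log-rank test (hypergeometric
variance, simultaneous risk sets under ties) compare subtypes and, per
panel gene, the high (1) versus low (0) callers — the binary value *is* the
within-cohort median split, so no second dichotomization is introduced.
Per-gene survival p-values are BH-adjusted within each screen; whether the
emulated design adjusted them is unstated, so the adjusted column is
reported alongside the raw one.

## The synthetic compendium

The generator emulates a 12-cohort lung-adenocarcinoma compendium: cohort
sizes 58–492 (2154 samples), two disjoint gene programs (an OX program of
40 genes headed by 12 named oxidative/proliferative markers, an IM program
of 40 genes headed by checkpoint/effector genes such as PDCD1 and CTLA4),
and a latent OX+/IM+ label per sample (prevalence 0.5).  Expression is
gene-wise Gaussian: x = scale_cg·(μ_g + β·z + ε) + shift_cg with
shift ~ N(0, batch_mu_sd²), log scale ~ N(0, batch_scale_sd²), and β
calibrated from `delta_p` — the target difference in P(above cohort
median) between subtypes — as β = 2·Φ⁻¹((1+delta_p)/2).  Defaults:
delta_p = 0.4 (median-split fold changes around 1, matching the effect
sizes the design targets), batch_mu_sd = 1.0, batch_scale_sd = 0.25 (raw
PC silhouette near 1), 70% retention of non-shared genes per cohort.
Survival is exponential with hazard 0.12/year for IM+ and hazard ratio 2
for OX+, with independent exponential censoring tuned to a 30% censored
fraction.  Demographics are mildly subtype-associated (IM+ older and more
often female, OX+ higher T/N stage) with cohort-level missingness.  A
single seed drives named substreams (structure / expression / survival /
censoring / clinical), so adding a stage never perturbs earlier draws.

The generator also writes the stand-in curated inputs: hallmark-style
pathway sets (program-aligned sets plus random decoys), two
oxidative-stress scoring sets, immune/stromal signatures, eight
cell-population marker sets, and the analysis gene universe (both programs
plus 50 topical but uninformative filler genes — curation is topical, not
discriminative).  All are synthetic constructs aligned with the generator's
programs, not the published catalogs.

What the generator does *not* emulate: count-distribution artifacts,
probe-level platform effects, correlated gene modules beyond the two
programs, non-proportional hazards, informative censoring, and
subtype-mixture continua.  Passing recovery tests therefore show the
pipeline recovers planted two-group structure under location/scale batch
effects — not that real cohorts contain such structure.

## Problem sizes and numerical choices

Packaged test and acceptance runs scale the simulations to single-CPU
sizes chosen as follows: subtype-recovery experiments use 200 samples over
12 cohorts with 300 genes; panel recovery uses the study-like geometry of
126 candidates (12 strong at delta_p 0.4, 114 decoys at 0.18 — just past
the fold-change filter) and a 1077-sample training half; the study-scale
pipeline run uses all 2154 samples with 500 genes, 100 consensus
repetitions, 500 GSEA permutations and 5 CV replicates.  Tolerances:
oracle-equivalence checks are exact to 1e-12 (GSEA ES) or relative 1e-9;
stochastic recovery checks assert medians over 5–20 seeds.  Degenerate
inputs are pinned by convention rather than left undefined: zero-variance
correlation d = 1, constant genes all-zero after binarization and skipped
in survival screens, empty DEG filter results warn rather than raise,
all-tied rank-sum comparisons return p = 1.

## Known limitations

Binarization discards magnitude and can only mitigate batch effects that
are monotone within (gene, cohort); the train/test threshold coupling noted
above is inherited from the design; consensus clustering with k fixed at 2
will split even unstructured data (the consensus matrix, not the labels,
carries the evidence); the importance measure is univariate and ignores
gene interactions; and all performance claims are on synthetic data
generated under the model described here.
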