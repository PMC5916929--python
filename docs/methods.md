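# Methods

This note documents the models implemented in `cagekit`, the choices
made where the design was genuinely open, what the synthetic cohort
does and does not emulate, and the numerical details that matter for
reproducing results.

## Coordinates and formats

CTSS positions are 1-based single base pairs; BED and bedGraph I/O is
0-based half-open. All conversions live in `cagekit.io`; no other
module does file-format coordinate arithmetic. Library size defaults
to the sum of stored CTSS counts; a larger total (mapped tags including
reads outside clusters) can be supplied explicitly and is used as the
TPM denominator when given.

## Tag-cluster calling

Pooling drops, per library, positions supported by fewer than 2 tags,
then sums per-library TPM. Clustering is single linkage: same-strand
positions chain while consecutive gaps are ≤ 20 bp. Queue trimming
compares the TPM at the two current edges, removes the smaller (ties:
the lower coordinate, strand-agnostic), and stops *before* the
cumulative removed TPM would exceed 10% of the original total, so the
retained mass is always ≥ 90% and the last position is never removed.
The stop rule uses a strict comparison (`removed + edge > budget`
terminates), i.e. a removal landing exactly on the budget is allowed.
Summits are the argmax of pooled TPM with ties broken toward the lower
coordinate. Quantification counts raw tags (singletons included) in
the trimmed spans; TCs are kept at ≥ 1 TPM in ≥ 3 libraries.

## Annotation

A TC is represented by its summit. Categories, in priority order used
for gene assignment: canonical (±100 bp of a gene's most upstream
annotated TSS, same strand), known alternative (±100 bp of any other
transcript TSS), novel alternative (inside the gene span, introns
included, same strand), novel antisense (inside a span, opposite
strand), novel intergenic. Multi-gene conflicts resolve by that
priority, then by distance to the nearest annotated TSS. Gene-level
counts sum the member TCs of the first three categories only.

## Enhancer detection

Arms are ordinary tag clusters called on the joint profile restricted
to positions outside the exclusion mask (±200 bp around exons, ±500 bp
around annotated TSSs, merged, strand-ignored). Each minus-strand arm
pairs with the nearest unused plus-strand arm entirely to its right
with inner edges ≤ 400 bp apart (configurable); the midpoint is the
floor of the mean of the inner edges and D is computed from pooled arm
TPM, with |D| < 0.6 exclusive. Support counts sum both strands over
the full candidate span, since tag support for an enhancer region is
not strand-specific. Cluster chaining requires ≥ 3 members with
consecutive midpoint gaps ≤ 15 kb; shorter chains are reported
separately rather than silently dropped.

## Linkage

Counts are normalized as log2 CPM with RLE (median-of-ratios) effective
library sizes and a pseudocount of 0.25. The per-sample normalization
factor is the median-of-ratios size factor divided by library size,
rescaled to geometric mean one; this makes every normalized value
exactly invariant to rescaling all counts of one sample, which a
direct division by the raw median-of-ratios factor would not be (its
geometric-mean reference moves with the rescaled sample). Pearson
p-values use the exact t transform with n − 2 degrees of freedom;
constant features are skipped; BH runs across all tested pairs.

## Differential expression

The NB-GLM is a contract — any standard negative-binomial log-linear
fit with batch blocking qualifies — and is fulfilled with statsmodels
GLM (NegativeBinomial family, log link) on an intercept + group +
batch design. Dispersions are tagwise maximum-likelihood estimates at
Poisson-fitted means, shrunk in log space toward a lowess
mean-dispersion trend with tagwise weight 0.25 (configurable; heavier
shrinkage stabilizes the Wald tests at moderate sample sizes).
Contrasts are Wald z tests on coefficient combinations; log2FC divides
the natural-log contrast by ln 2. All-zero features are skipped with
FDR pinned to 1. Set logic is a pure threshold function: |log2FC| > 1
and FDR < 0.05, sign deciding IBD_up/IBD_down (IBD contrast) and
CD_spec/UC_spec (CDvsUC contrast, positive = higher in CDa). Extra
covariates can be added to the design via `extra_covariates`.

## Five-pattern EB enhancer model

Counts follow NB(r_gi, q) with r_gi = r_g·s_i; within an equal-mean
block of conditions a single q is drawn from Beta(α, β), giving a
beta-negative-binomial block marginal B(α + Σr, β + Σx)/B(α, β) up to
a pattern-independent factor. r_g comes from method of moments with the
**within-condition pooled variance** — using the total variance would
inflate v for differential enhancers, shrink r toward zero, flatten
their likelihood and let the all-different pattern absorb them. The
mixture over the five partitions of {CDa, UCa, Ctrl} is fitted by EM:
mixing proportions in closed form, (α, β) by warm-started Nelder–Mead
on the expected complete-data log likelihood (warm starting guarantees
the marginal likelihood never decreases, which the tests assert). The
Beta hyperprior is initialized by method of moments on the per-feature
q estimates; a flat start is a documented local-optimum trap.
Convergence: relative log-likelihood change < 1e-6, at most 100
iterations, with a warning and the last iterate on non-convergence.
Size factors should come from TSS counts of the same samples (far
stronger signal than the sparse enhancer counts); the model assumes a
single batch — run it per batch on batched cohorts.

Labels use a 0.9 posterior cutoff: IBD_up/IBD_down from pattern 2 with
the sign of both active-group means against Ctrl, CDa_spec from
pattern 4, UCa_spec from pattern 3. The cutoff is conservative: MAP
assignment recovers ≥ 95% of 4-fold pattern-2 features at n = 20/group,
while the > 0.9-posterior label rate depends on the fitted mixture —
with a realistic, pattern-1-dominated composition most true pattern-2
features are labeled; under an artificial equal allocation the prior
odds against any one pattern keep posteriors flatter.

## GWAS clump enrichment

LD partnership is strict: R² > 0.75 and distance ≤ 500 kb on the same
chromosome. Each GWAS SNP expands to the span covering itself and its
partners; overlapping spans merge transitively (per trait), and overlap
with a region set counts per clump with a ≥ 1 bp rule. The
beta-binomial prior across traits is fitted by maximum likelihood
(Nelder–Mead on log parameters, method-of-moments start); shrunken
fractions are posterior means (x + α)/(n + α + β), which provably lie
between the raw fraction and the prior mean. Degenerate all-equal
fractions return the raw values with a warning. DE-set enrichment is
the hypergeometric upper tail with BH across traits.

## Biomarker selection and classification

Iterative elimination splits the features into random even subsets
(≤ 500) several times per iteration, scores each subset with a
501-tree forest (mtry = (√x − 1)·2) and removes the 5% of features
with the lowest average permutation importance across the splits —
each feature is scored in several subset contexts before it can be
dropped. Importance is measured on a stratified held-out third of the
samples because a fully grown forest memorizes its training data and
training-set permutation importance is uninformative; this approximates
the out-of-bag accuracy decrease. Ties break randomly (seeded).
Consensus voting and the high-confidence TC filter (allowed annotation
categories, width 2–100 bp inclusive, > 10 TPM in ≥ 3 subjects, strict
inequality) are pure set operations.

The two-step classifier trains forest 1 on IBD-vs-Ctrl and forest 2 on
CDa-vs-UCa, consulting forest 2 only for step-1 IBD calls — step 2 can
never override a Ctrl call. The grid search covers n ∈ {2, 3, 4, 5}
and m = √(x − 1)·y, y ∈ {1/2, 3/4, 1, 3/2, 2}, maximizing mean overall
two-step accuracy under stratified 5-fold CV, then refits on all
training data. Repeated CV draws fresh stratified folds per repetition
(re-drawn if a training fold misses a class) and reports means with
percentile 95% CIs; per-class metrics recast one-vs-rest; the confusion
matrix is column-normalized over true labels. The shuffled-label null
permutes training labels, predicts a held-out cohort and aggregates;
its analytic expectation is Σ_c p_train(c)·p_test(c).

## qPCR processing

ΔCq values (already reference-gene normalized; the per-batch reference
list is an input, not inferred) are batch-adjusted per primer with a
robust Huber regression on group + sum-to-zero-coded batch terms,
subtracting only the batch component; external panels (organoid,
monocyte) are shifted by the mean of the per-batch corrections. QC
removes primers then samples exceeding 10% missingness and imputes the
remainder with bagged regression trees on the complete primers (k-NN
fallback available). ΔΔCq = log2(2^(−ΔCq) / min) with the minimum per
primer over non-missing samples, so each primer's minimum is exactly 0.
Response labels are medians of log2 ratios against the control (or 0 h)
average; a ratio of a zero ΔΔCq is undefined and counted missing, and a
primer with a missing median in any group is discarded (mirroring the
analyzable-primer count being below the panel size). "Upregulated"
requires a strictly positive median; the IBD-up label is an OR over
CDa and UCa, and stimulation responses pool 4 h and 24 h by OR.

## Synthetic cohort

The generator emulates: ~10 Mb genome, 300 non-overlapping genes (1–3
transcript TSSs, both strands), 200 intergenic enhancers ≥ 1 kb from
the exclusion mask with 30% arranged in clusters of 3–10 members
(gaps ≤ 15 kb, singletons kept > 15 kb apart); groups CDa:20, UCa:25,
Ctrl:29 over two batches; NB counts (dispersion 0.2) with sharp
promoter peaks (~90% of tags within 5 bp of the summit, on the gene
strand) and divergent enhancer arms splitting tags ~50/50 (|D| small);
planted DE (default 35 DE genes: 12/8/8/7 across the four sets, log2
effect 2.0, matching the biomarker-panel scale) and enhancer patterns;
links as shared per-sample latent activities (log2-sd 1.5·ρ, realized
co-expression r ≈ 0.7–0.8 at ρ = 0.8); GWAS panels with short-range LD
blocks and an enriched trait whose SNPs weight upregulated regions
5-fold (the panel guarantees 3 SNPs per upregulated region so the
signal exists at this scale); and qPCR ΔCq derived from expression
plus Gaussian noise (sd 0.5), cohort offsets and 2% missingness, with
planted organoid/monocyte response overlaps.

It does **not** emulate: mappability artifacts, multi-mapping, PCR
duplicates, realistic LD from reference panels, overlapping genes,
expression-dependent dispersion trends, or primer efficiency
differences. Passing recovery tests therefore certify the pipeline's
logic and statistics under its stated assumptions, not robustness to
those artifacts.

The linkage-precision check runs on a cohort with planted links but no
planted DE and a single batch: group effects and batch structure induce
genuine co-expression between unlinked features, which would make
"precision against the planted link list" an ill-posed measure of the
linkage statistic itself.

The pattern-model harness (`simulate_pattern_counts`) uses NB
dispersion 0.1 and a graded pattern-5 profile (base, base·f, base·f²);
the equal-allocation setting stresses MAP assignment while the
realistic pattern-1-dominated setting stresses posterior labeling.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` run the default cohort (74
samples, 300 genes, 200 enhancers), 2,000 enhancers per pattern for the
EB model check, 101 × 5-fold CV with 101-tree forests (1001 trees is
the production default; accuracy on the 35-feature cohort is identical
to three decimals), a 150-repetition shuffled null, and 100 random
50-SNP panels for the clump oracle. The full suite runs in a few
minutes on one CPU; the acceptance script in under two.
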