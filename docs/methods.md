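# Methods

This note records the models behind `icikit`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open. Every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Preprocessing and cohort merging

Expression enters as FPKM or TPM. FPKM→TPM is the exact per-column
renormalization `TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`; column sums of 10⁶
are an enforced invariant. Cross-cohort "unification" is implemented as
log₂(TPM+1) followed by per-gene z-scoring *within each cohort* on the
shared gene set. No explicit batch model (ComBat etc.) is fitted: the
downstream stages are rank- or PCA-based, and within-cohort location/scale
standardization removes exactly the cohort-level shifts they are sensitive
to. Genes with zero within-cohort variance are dropped (logged); duplicate
gene rows are collapsed by mean, there being no annotation-level rule to
prefer. Deconvolution, by contrast, runs on linear-scale (TPM) data, where
the mixture model is defined.

## Deconvolution

The bulk profile of a sample is modeled as a non-negative combination of
cell-type signature profiles: `x ≈ S w, w ≥ 0`. We solve per-sample
non-negative least squares and renormalize `w` to the simplex. NNLS is a
transparent estimator of the same linear-mixture model that ν-SVR-based
tools (CIBERSORT) target; its accuracy is validated against planted truth
(mean absolute fraction error ≈ 0.02 at the default noise level, criterion
< 0.05), and a hook accepts externally computed fraction tables for users
who want canonical CIBERSORT/LM22 output. Signature matrices are supplied
as genes × cell-types TSV; LM22 is not redistributed. An optional
permutation p-value per sample compares the achieved fit correlation with
gene-label permutations.

Stromal/immune scores use single-sample ssGSEA: genes ranked per sample
(average ties), in-set ECDF weighted by rank^α (α = 0.25 default),
minus the unweighted out-of-set ECDF, summed over all positions. The
ESTIMATE-style score is their sum. Purity calibration coefficients
(`purity = cos(a + b·estimate)`) are platform-specific and must be supplied
by the user; without them purity is reported undefined rather than
defaulted.

## Consensus clustering

Monti-style: each of `reps` repetitions subsamples 80% of samples, clusters
with the base method (k-means default for speed and seedability;
average-linkage hierarchical available to match the common R tool), and
consensus_ij = co-clustered / co-sampled. Final labels cut an
average-linkage tree of 1 − consensus at k and are relabeled by decreasing
cluster size for determinism. Pairs never co-sampled are NaN in the matrix
and counted, never silently zero. The API default is `reps = 1000`,
matching standard practice; the 50-seed end-to-end suites use `reps = 100`,
which the recovery tests show is already past the stability plateau for
cohorts of this size.

k is chosen by minimum PAC (share of consensus entries in (0.1, 0.9)), ties
to the smaller k; CDF areas and delta-areas are returned for inspection,
and a minimum PAC above 0.5 flags "no reproducible structure". Feature
columns are z-scored before clustering by default (disable with
`standardize=False`).

## Differential expression

Per-gene two-group comparison with empirical-Bayes variance moderation:
pooled variances s²_g (d_g df) are shrunk toward a prior,
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), with (d₀, s₀²) obtained by moment
matching of the observed s²_g distribution to its scaled-F sampling model
(E[F] and Var/E² identities; d₀ = ∞, i.e. complete shrinkage, when the
observed spread does not exceed chi-square sampling noise; d₀ is floored
just above 4 where the matching moments exist). The moderated t is referred
to t with d₀+d_g df. Under the null the procedure is calibrated: measured
type-I error at p < 0.05 is ≈ 0.050 over 200 simulations of 500 genes.
Zero-variance genes get p = 1 with a log entry.

DEG selection follows the printed rule read as |log₂FC| > 1 with raw
p < 0.05 (a literal |FC| > 1 is vacuous; BH-adjusted selection is available
but off by default to mirror the stated rule). Multi-cluster DEG pools use
one-vs-rest contrasts and the union of per-contrast lists (intersection
selectable); with two clusters the contrasts are complementary and the
union equals the single two-group list.

## ICI score

Signature side A holds DEGs with higher mean expression in gene-cluster-A
samples, side B the rest; exact ties are excluded with a warning. Each side
is standardized per gene and projected on its first principal component,
sign-anchored so PC1 correlates positively with the set-mean standardized
expression (PCA signs are otherwise arbitrary). The score is
ΣPC1A − ΣPC1B (one set per side by default; the Σ form accepts several).
Boruta (shadow-feature random-forest selection, two-sided binomial bounds
at α = 0.01, response = gene-cluster label) can prune each side before
scoring; it defaults off in the pipeline driver because the confirmed-subset
score is rank-equivalent to the full-set score (ρ ≥ 0.99 in the stability
test) while costing most of the runtime. When used, it runs after the
signature split, per side.

Because gene-cluster labels come from unsupervised clustering, the sign of
PC1A − PC1B is arbitrary. The pipeline therefore orients the final score to
correlate positively with a user-supplied immune-activity reference (mean
standardized expression of a marker set — cytotoxic markers such as CD8A /
GZMB in real data; the planted hot-cell-type markers in the synthetic
study). This anchors "high score" to "immune hot", the direction in which
the score is interpreted.

**Known limitation.** If a signature side mixes two anticorrelated marker
blocks of similar strength, its two leading eigenvalues nearly tie and PC1
is not identifiable: removing a few genes (e.g. by Boruta) can switch which
axis leads, changing the score beyond any sign convention. This arises
under perfectly symmetric subtype structure — the stability test uses an
asymmetric mixture, where the leading axis is well separated — and is an
intrinsic property of PC1-based signature scores, not of this
implementation.

## Survival machinery

Kaplan–Meier and the multi-group log-rank test are delegated to lifelines;
the reported median is the first time S(t) ≤ 0.5. Cox proportional hazards
is an in-package Newton–Raphson maximizer of the partial likelihood with
Efron tie handling by default and Breslow selectable (needed for exact
invariance under case duplication; lifelines, which implements Efron only,
serves as the cross-check oracle — agreement to ~1e-6 on tied data).
Covariates are centered/scaled internally; convergence requires max |score|
< 1e-8 within 50 step-halved Newton iterations, and monotone likelihoods
(separation) are reported as non-converged with a diagnostic rather than a
spurious estimate.

The maximally selected cutoff scans observed score values whose split keeps
both groups ≥ 10% of the cohort (floor configurable), maximizing the
two-group log-rank chi-square; the statistic is vectorized over thresholds
(risk-set sums as matrix products), making the selection-adjusted
permutation null (max-chi-square over permuted scores; default 1000
permutations, skippable) tractable. Candidate thresholds are capped at 200
evenly spaced quantiles for large cohorts. Ties at the cutoff go to the low
group (strictly greater = high); median risk splits likewise send exact
medians to low risk. Time-dependent AUC is the cumulative/dynamic estimator
with Kaplan–Meier censoring adjustment from scikit-survival; the 1/3/5-year
convention of prognostic-model reports is the intended use. Degenerate
survival input (no events) makes the score dichotomy fall back to the
median with a warning.

## Mutation burden

TMB is the raw count of non-silent records per sample (missense, nonsense,
frameshift and in-frame indels, splice site, nonstop, translation start
site); silent/UTR/flank/intron classes are excluded, the class list is
configurable, and per-megabase scaling is an optional constant — the
published comparisons use the unitless index. The contingency table takes
the union of the 20 most frequently mutated genes per score group,
tabulates wild/mutated counts against the high/low groups and applies the
Yates-corrected chi-square; continuity correction is on because the
published p-values are consistent with the corrected statistic to four
significant figures (verified by recomputation) and not with the
uncorrected one. Genes with a zero margin (mutated in all or no samples)
report chi2 = 0, p = 1. Note the corrected chi-square is an approximation:
an exhaustive scan of 2×2 tables with cells in 1..15 puts its worst
disagreement with Fisher's exact test at a factor of 8.4 on the p-value,
so small-count tables should be read with that in mind. TMB–score
association is Spearman's rank correlation; TMB × score-group strata use a
median TMB split (ties low) crossed with the high/low group and an overall
log-rank across non-empty strata.

## Enrichment

Over-representation is the upper-tail hypergeometric test against a stated
universe with BH correction across sets. GSEA computes the weighted-KS
running sum on a supplied ranking (hits weighted |score|^p, p = 1 default;
misses 1/(N−m)); ES is the signed maximum deviation. The null permutes
gene labels — it works for arbitrary rankings, unlike phenotype
permutation, which requires expression and labels — with NES = ES divided
by the mean |ES| of same-sign permutations and p the same-sign exceedance
share. Term databases (GO/KEGG) are not bundled; gene sets are user GMT
files, because database-version-dependent term counts are not reproducible
quantities.

## Single-cell QC and HVG

Cells are removed when they detect < 200 genes, exceed 15% mitochondrial
counts, or fall below 0.8 novelty (log₁₀ genes / log₁₀ UMIs); boundary
values are kept, matching the strict inequalities of the stated removal
rules. Cells with ≤ 1 UMI have undefined novelty and are removed. The
filter is idempotent, and per-rule removal counts are reported
non-exclusively. HVGs: counts-per-10k, log1p, per-gene variance of the log
values z-scored within 20 equal-width mean bins, top-N by standardized
variance. Within-bin z-scores lose power when planted high-dispersion genes
crowd a single bin (they become each other's reference); the recovery tests
therefore spread planted means across the expression spectrum, which is
also the realistic situation.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
realistic expression profiles. Bulk expression is signature · fractionsᵀ
with multiplicative log-normal noise (log-sd 0.3 default); the signature
has disjoint marker blocks (20 markers per cell type, 8× fold) over a
log-normal baseline. Three subtypes draw their 5-cell-type proportions from
Dirichlet concentrations (10, 1, 1, 0.8, 0.8) and rotations — each subtype
enriched for its own cell type, chosen once so that fraction-space
clustering recovers the subtypes with a comfortable margin (ARI ≈ 1 at
n = 150). Survival is exponential with per-subtype hazards
(10⁻³, 5·10⁻⁴, 2·10⁻³)/day under independent exponential censoring
(5·10⁻⁴/day): subtype B is simultaneously the cytotoxic-enriched
("immune-hot") and best-surviving subtype, the association the score is
meant to detect; hazard ratios of 2–4 are typical of published
immune-subtype contrasts. Mutation counts are Poisson with
log-mean = log(10) + 0.5·z(score), a few catalog genes get 5× odds in
high-score samples (planting contingency contrasts), and a sprinkle of
silent records exercises the TMB class filter. Single-cell metadata plants
exactly 5% failures per QC rule, each violating only its own rule.

What the generator does *not* emulate: library-size and GC biases, gene–gene
correlation beyond the mixture, non-proportional hazards, informative
censoring, subclonal mutation structure, or realistic single-cell count
distributions. Passing tests therefore demonstrate that the algorithms
recover the structure they model, under that model — not performance on
real cohorts.

## Problem sizes and determinism

Default analysis cohorts are 300 samples × 500 genes × 5 cell types —
large enough for stable clustering and survival contrasts while keeping the
full suite and the acceptance script at a few minutes each on one CPU.
Replicated checks use 50 seeds (end-to-end), 100–200 simulations
(calibrations), and reps = 100–300 consensus repetitions; all randomness
flows from explicit integer seeds (package default 2020), and generators
are pure functions of (parameters, seed).
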