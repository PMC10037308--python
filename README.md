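# icikit

Immune-cell-infiltration (ICI) scoring of bulk tumor transcriptomes.

Solid tumors differ widely in how strongly immune cells infiltrate them, and
that difference carries prognosis: patients whose tumors are "immune hot"
(cytotoxic T-cell rich, checkpoint-gene high) tend to live longer and respond
better to immunotherapy. `icikit` implements a complete, tested pipeline for
quantifying that axis from bulk RNA-seq of a patient cohort — the kind of
analysis routinely run on TCGA/GEO cervical-cancer cohorts — together with a
synthetic-cohort generator that plants known immune subtypes, survival
differences and mutation-burden links, so every stage can be validated
against ground truth.

## The method

Given a genes × samples expression matrix (FPKM or TPM), clinical follow-up
and optionally a somatic-mutation MAF:

1. **Preprocessing** — FPKM→TPM (`TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`),
   cohort merging on shared genes with per-gene z-scoring of log₂(TPM+1)
   within each cohort.
2. **Deconvolution** — per-sample immune cell fractions by non-negative
   least squares against a genes × cell-types signature matrix (any
   CIBERSORT-style signature; externally computed fraction tables are
   accepted), plus ssGSEA stromal/immune scores whose sum indexes tumor
   purity (ESTIMATE-style).
3. **ICI clusters** — Monti consensus clustering (resampled k-means or
   hierarchical, 1000 repetitions) of the fraction profiles; k chosen by
   the proportion of ambiguous clustering (PAC).
4. **Signature genes** — moderated-t (empirical-Bayes, limma-style)
   one-vs-rest contrasts between ICI clusters; DEGs at |log₂FC| > 1 and
   p < 0.05; consensus clustering of samples in DEG space into gene
   clusters A/B; DEGs up in cluster A form signature side A, the rest
   side B; optional Boruta (shadow-feature random forest) reduction.
5. **The score** — per side, samples are projected on the first principal
   component of the standardized signature genes, and

   ICI score = Σ PC1⁽ᴬ⁾ − Σ PC1⁽ᴮ⁾.

6. **Survival integration** — maximally selected log-rank cutoff splits the
   cohort into high/low score groups (permutation-adjusted significance);
   Kaplan–Meier, log-rank, Cox proportional hazards (Newton–Raphson,
   Efron/Breslow ties), median-split risk models, time-dependent AUC.
7. **Mutation burden** — TMB (non-silent mutation count), Spearman
   TMB–score association, per-gene high/low contingency tables with
   Yates-corrected chi-square, TMB × score survival strata.
8. **Enrichment & single-cell QC** — hypergeometric over-representation,
   weighted-KS GSEA with a gene-label permutation null, and the standard
   per-cell filters (≥200 genes, ≤15% mitochondrial counts, novelty
   ≥0.8) plus binned-dispersion HVG selection.

## Worked example

```python
from icikit.synthetic import simulate_cohort
from icikit.pipeline import run_scoring_pipeline

cohort = simulate_cohort(seed=2020)   # 300 samples, 3 planted subtypes
res = run_scoring_pipeline(
    cohort.expression, cohort.clinical, cohort.signature,
    orient_markers=cohort.hot_markers, seed=2020,
)
print(len(res.degs), res.cutoff, res.logrank_p)
```

Running the numbered drivers reproduces the full analysis; with the default
seed they print (abridged):

```
$ python analysis/03_immune_clusters.py
chosen k = 3 (PAC 0.000); ARI vs truth = 1.000
survival across ICI clusters: chi2 = 54.4 (df 2), log-rank p = 1.6e-12

$ python analysis/05_ici_score.py
optimal cutoff -0.007; groups {'high': 193, 'low': 107}
high vs low log-rank: chi2 = 47.2, p = 6.4e-12
mean score hot subtype 3.04 vs others -1.32

$ python analysis/06_mutation_burden.py
Spearman rho(TMB, ICI score) = 0.82, p = 7.4e-74
4-stratum log-rank: chi2 = 49.5 (df 3), p = 1e-10
```

That is: PAC recovers the three planted immune subtypes exactly, the
high-ICI group formed by the optimal cutoff lives significantly longer, the
score is oriented toward the planted immune-hot subtype, and mutation
burden tracks the score as planted. Each driver writes its tables under
`results/`.

## Layout

- `src/icikit/` — the library (io_core, synthetic, deconvolution,
  consensus, de, scoring, survival, mutation, enrichment, sc_qc, pipeline).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including end-to-end acceptance checks.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
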