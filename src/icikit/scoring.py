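"""The ICI score construction: signature gene split, Boruta reduction,
per-sample PC1 scores, ICI score = PC1A - PC1B, and the high/low dichotomy.

Signature set A holds DEGs whose expression is higher in gene-cluster-A
samples, set B the opposite; each side is optionally reduced with Boruta
(shadow-feature random-forest selection against the gene-cluster label);
each side's genes are standardized and projected on their first principal
component (sign-anchored to the set-mean expression); the ICI score is the
difference of the two PC1s, and the cohort is dichotomized at the maximally
selected log-rank cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .io_core import ClinicalTable, ExpressionMatrix
from .survival import optimal_cutoff

log = logging.getLogger(__name__)


@dataclass
class SignatureSplit:
    genes_A: list[str]
    genes_B: list[str]
    gene_cluster_labels: pd.Series   # per-sample {A, B}


@dataclass
class ICIResult:
    table: pd.DataFrame   # columns pc1_A, pc1_B, ici_score, group
    cutoff: float


def assign_signature_genes(
    expr: ExpressionMatrix,
    degs: list[str],
    gene_cluster_labels: pd.Series,
) -> SignatureSplit:
    """Split DEGs by the sign of their mean difference (cluster A - B)."""
    labels = gene_cluster_labels.reindex(expr.sample_ids)
    levels = sorted(pd.unique(labels.dropna().astype(str)))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 gene clusters, got {levels}")
    a_mask = (labels.astype(str) == levels[0]).to_numpy()
    b_mask = (labels.astype(str) == levels[1]).to_numpy()
    genes = [g for g in degs if g in expr.values.index]
    X = expr.values.loc[genes]
    diff = X.loc[:, a_mask].mean(axis=1) - X.loc[:, b_mask].mean(axis=1)
    ties = list(diff.index[diff == 0])
    if ties:
        log.warning("assign_signature_genes: excluding %d gene(s) with exactly equal means", len(ties))
    return SignatureSplit(
        genes_A=list(diff.index[diff > 0]),
        genes_B=list(diff.index[diff < 0]),
        gene_cluster_labels=labels,
    )


def boruta_select(
    features: pd.DataFrame,
    response: pd.Series,
    n_iter: int = 100,
    trees: int = 300,
    alpha: float = 0.01,
    seed: int = 2020,
) -> tuple[list[str], pd.DataFrame]:
    """All-relevant feature selection against shadow features.

    Each iteration appends a column-shuffled shadow copy of every feature,
    fits a random forest, and scores a hit for features whose importance
    exceeds the best shadow importance. Features whose hit counts exceed the
    two-sided Binomial(n_iter, 1/2) upper bound at ``alpha`` are confirmed;
    below the lower bound, rejected; in between, tentative (reported but not
    confirmed). Returns (confirmed genes, per-feature report).
    """
    if n_iter < 20:
        raise ValueError("n_iter must be >= 20")
    y = response.reindex(features.index)
    if y.isna().any():
        raise ValueError("response missing for some samples")
    if y.nunique() < 2:
        raise ValueError("response needs >= 2 classes")
    X = features.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        log.warning("boruta_select: removing %d constant feature(s)", len(const))
        X = X.drop(columns=const)
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    hits = np.zeros(len(cols), dtype=int)
    Xv = X.to_numpy()
    yv = pd.factorize(y)[0]
    for it in range(n_iter):
        shadow = Xv.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=trees, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
        )
        rf.fit(np.hstack([Xv, shadow]), yv)
        imp = rf.feature_importances_
        real, sh = imp[: len(cols)], imp[len(cols) :]
        hits += real > sh.max()
    upper = stats.binom.ppf(1 - alpha / 2, n_iter, 0.5)
    lower = stats.binom.ppf(alpha / 2, n_iter, 0.5)
    status = np.where(hits > upper, "confirmed", np.where(hits < lower, "rejected", "tentative"))
    report = pd.DataFrame({"feature": cols, "hits": hits, "status": status}).set_index("feature")
    confirmed = [c for c, st in zip(cols, status) if st == "confirmed"]
    return confirmed, report


def pc1_scores(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Per-sample projection on the first principal component of a gene set.

    Genes are standardized across samples first; the PC1 sign is anchored so
    scores correlate positively with the set-mean standardized expression
    (PCA sign is otherwise arbitrary and would flip the ICI score).
    """
    use = [g for g in genes if g in expr.values.index]
    X = expr.values.loc[use]
    sd = X.std(axis=1, ddof=1)
    X = X.loc[sd > 0]
    if X.shape[0] < 2:
        raise ValueError("pc1_scores needs >= 2 usable (non-constant) genes")
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
    A = Z.to_numpy().T           # samples x genes, column-centered by construction
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    scores = A @ vt[0]
    ref = A.mean(axis=1)
    if np.corrcoef(scores, ref)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.sample_ids, name="pc1")


def ici_score(pc1_A_sets, pc1_B_sets) -> pd.Series:
    """ICI score = sum of A-side PC1s minus sum of B-side PC1s."""

    def _tolist(v):
        if isinstance(v, pd.Series):
            return [v]
        return list(v)

    a_sets, b_sets = _tolist(pc1_A_sets), _tolist(pc1_B_sets)
    if not a_sets and not b_sets:
        raise ValueError("need at least one PC1 vector")
    index = (a_sets or b_sets)[0].index
    total = pd.Series(0.0, index=index)
    for v in a_sets:
        if not v.index.equals(index):
            raise ValueError("sample mismatch between PC1 vectors")
        total = total + v
    for v in b_sets:
        if not v.index.equals(index):
            raise ValueError("sample mismatch between PC1 vectors")
        total = total - v
    return total.rename("ici_score")


def orient_score(score: pd.Series, reference: pd.Series) -> pd.Series:
    """Flip the score sign, if needed, to correlate positively with a
    per-sample immune-activity reference (e.g. mean expression of cytotoxic
    markers). Consensus cluster labels are arbitrary, so the raw sign of
    PC1A - PC1B is too; this anchors 'high score' to 'immune hot'."""
    ref = reference.reindex(score.index)
    rho = stats.spearmanr(score, ref).statistic
    return (-score if rho < 0 else score).rename(score.name)


def dichotomize(
    score: pd.Series,
    clinical: ClinicalTable,
    pc1_A: pd.Series | None = None,
    pc1_B: pd.Series | None = None,
    floor: float = 0.1,
    n_perm: int = 0,
    seed: int = 2020,
) -> ICIResult:
    """Split the cohort at the maximally selected log-rank cutoff.

    Samples with score strictly above the cutoff form the high group. When
    the survival input is degenerate (no events), the cutoff falls back to
    the median with a warning.
    """
    clin = clinical.aligned(list(score.index))
    if clin.events.sum() == 0 or np.unique(clin.times).size == 1:
        log.warning("dichotomize: degenerate survival input; falling back to median cutoff")
        cutoff = float(np.median(score))
    else:
        cutoff, _, _ = optimal_cutoff(score, clin, floor=floor, n_perm=n_perm, seed=seed)
    group = pd.Series(np.where(score > cutoff, "high", "low"), index=score.index, name="group")
    table = pd.DataFrame(
        {
            "pc1_A": pc1_A.reindex(score.index) if pc1_A is not None else np.nan,
            "pc1_B": pc1_B.reindex(score.index) if pc1_B is not None else np.nan,
            "ici_score": score,
            "group": group,
        }
    )
    return ICIResult(table, cutoff)
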