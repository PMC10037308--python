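"""Reference-based immune deconvolution and microenvironment scores.

Per-sample immune fractions are estimated by non-negative least squares of
the sample's signature-gene expression against a genes x cell-types
signature matrix, with weights renormalized to the simplex and an optional
permutation p-value (fraction of gene-label permutations whose fit
correlation reaches the observed one). Stromal/immune scores use a
single-sample rank-based enrichment statistic (ssGSEA); their sum is the
ESTIMATE-style score, and tumor purity is obtained from it through a
user-supplied cosine calibration when available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import rankdata

from .io_core import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class FractionMatrix:
    fractions: pd.DataFrame     # samples x cell types, rows on the simplex
    perm_p: pd.Series           # per-sample permutation p-value (NaN if n_perm=0)

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("negative fractions")
        rs = arr.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass
class TMEScores:
    scores: pd.DataFrame  # columns stromal_score, immune_score, estimate_score, purity
    purity_defined: bool


def estimate_fractions(
    expr: ExpressionMatrix,
    signature: pd.DataFrame,
    n_perm: int = 0,
    seed: int = 2020,
) -> FractionMatrix:
    """NNLS mixture estimate of cell-type fractions per sample."""
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    shared = [g for g in signature.index if g in set(expr.gene_ids)]
    S = signature.loc[shared].to_numpy(dtype=float)
    if S.shape[0] < 2:
        raise ValueError("fewer than 2 signature genes present in expression")
    per_ct = (S != 0).sum(axis=0)
    thin = [c for c, n in zip(signature.columns, per_ct) if n < 2]
    if thin:
        raise ValueError(f"cell types with <2 signature genes present: {thin}")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        corr = np.corrcoef(S.T)
        pairs = [
            (signature.columns[i], signature.columns[j])
            for i in range(S.shape[1])
            for j in range(i + 1, S.shape[1])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient signature matrix; collinear cell types: {pairs or list(signature.columns)}")

    X = expr.values.loc[shared].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_samples = X.shape[1]
    fracs = np.zeros((n_samples, S.shape[1]))
    pvals = np.full(n_samples, np.nan)
    for i in range(n_samples):
        y = X[:, i]
        w, _ = nnls(S, y)
        tot = w.sum()
        if tot <= 0:
            log.warning("sample %s: zero NNLS solution; assigning uniform fractions", expr.sample_ids[i])
            fracs[i] = 1.0 / S.shape[1]
            continue
        fracs[i] = w / tot
        if n_perm > 0:
            fit = S @ w
            obs = _safe_corr(fit, y)
            hits = 0
            for _ in range(n_perm):
                yp = rng.permutation(y)
                wp, _ = nnls(S, yp)
                hits += _safe_corr(S @ wp, yp) >= obs
            pvals[i] = (hits + 1) / (n_perm + 1)
    return FractionMatrix(
        pd.DataFrame(fracs, index=expr.sample_ids, columns=signature.columns),
        pd.Series(pvals, index=expr.sample_ids, name="perm_p"),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ssgsea_scores(
    expr: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Single-sample gene-set scores (rank-weighted KS running sum).

    Per sample, genes are ranked by expression (average ranks on ties; the
    top gene gets the largest rank value). Walking down the ranking, the
    in-set ECDF is weighted by rank^alpha (normalized over the set) while the
    out-of-set ECDF is unweighted; the score is the sum of their differences
    over all positions. Rank-based, hence invariant to any monotone
    transformation of a sample's values.
    """
    genes = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    X = expr.values.to_numpy(dtype=float)
    out = {}
    members = {}
    for name, gs in gene_sets.items():
        idx = sorted({gene_pos[g] for g in gs if g in gene_pos})
        if len(idx) == 0:
            raise ValueError(f"gene set {name!r} empty after intersection with expression")
        members[name] = np.array(idx)

    for name, idx in members.items():
        in_set = np.zeros(N, dtype=bool)
        in_set[idx] = True
        scores = np.empty(X.shape[1])
        for s in range(X.shape[1]):
            scores[s] = _ssgsea_one(X[:, s], in_set, alpha)
        out[name] = scores
    return pd.DataFrame(out, index=expr.sample_ids)


def _ssgsea_one(x: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    N = x.size
    m = int(in_set.sum())
    if m == N:
        return 0.0
    ranks = rankdata(x)                    # ascending: top gene has rank N
    order = np.argsort(-x, kind="stable")  # walk from top
    hit = in_set[order]
    w = ranks[order] ** alpha
    w_hit = np.where(hit, w, 0.0)
    p_in = np.cumsum(w_hit) / w_hit.sum()
    p_out = np.cumsum(~hit) / (N - m)
    return float(np.sum(p_in - p_out))


def estimate_tme_scores(
    expr: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    purity_coeffs: tuple[float, float] | None = None,
    alpha: float = 0.25,
) -> TMEScores:
    """Stromal/immune ssGSEA scores, their sum, and optional purity.

    ``purity = cos(a + b * estimate_score)`` when calibration coefficients
    are supplied (they are platform-specific, so no default is hard-coded);
    otherwise the purity column is NaN and flagged undefined.
    """
    scores = ssgsea_scores(expr, {"stromal": stromal_set, "immune": immune_set}, alpha=alpha)
    df = pd.DataFrame(
        {
            "stromal_score": scores["stromal"],
            "immune_score": scores["immune"],
        }
    )
    df["estimate_score"] = df["stromal_score"] + df["immune_score"]
    if purity_coeffs is not None:
        a, b = purity_coeffs
        purity = np.cos(a + b * df["estimate_score"].to_numpy())
        if ((purity < 0) | (purity > 1)).any():
            log.warning("purity outside [0,1]; clipping")
        df["purity"] = np.clip(purity, 0.0, 1.0)
        defined = True
    else:
        df["purity"] = np.nan
        defined = False
    return TMEScores(df, purity_defined=defined)
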