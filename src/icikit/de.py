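"""Moderated two-group differential expression and DEG selection.

The per-gene statistic is an empirical-Bayes moderated t: gene-wise pooled
variances s2_g (d_g residual df) are shrunk toward a common prior value,
s2_tilde = (d0*s0^2 + d_g*s2_g) / (d0 + d_g), with the prior df d0 and scale
s0^2 estimated by moment matching of the observed s2_g distribution to its
scaled-F sampling model. The moderated t is referred to a t distribution on
d0 + d_g df. DEG selection follows the |log2 fold change| > 1 and p < 0.05
rule, and multi-cluster DEG pools come from one-vs-rest contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix

log = logging.getLogger(__name__)


def _fit_f_moments(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F model s2_g ~ s0^2 F(d, d0).

    Uses E[F] = d0/(d0-2) and Var[F]/E[F]^2 = 2(d + d0 - 2)/(d(d0 - 4)).
    Returns d0 = inf (complete shrinkage to the mean) when the observed
    spread is no larger than pure chi-square sampling noise allows.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m <= 0 or v <= 0:
        return np.inf, m if m > 0 else 1.0
    c = v / m**2
    denom = c * d - 2.0
    if denom <= 0:
        return np.inf, m
    d0 = (4.0 * c * d + 2.0 * (d - 2.0)) / denom
    if d0 <= 4.0:
        d0 = 4.0 + 1e-8  # moments exist only for d0 > 4; cap at the boundary
    s0 = m * (d0 - 2.0) / d0
    return d0, s0


def moderated_t(
    expr: ExpressionMatrix,
    group: pd.Series,
    shrink: bool = True,
    contrast: str = "1_vs_0",
) -> pd.DataFrame:
    """Per-gene moderated t between the two levels of ``group``.

    ``group`` is a binary per-sample label aligned to the expression columns;
    log2fc is mean(group 1) - mean(group 0) on the (log-scale) expression.
    ``shrink=False`` disables empirical-Bayes moderation, giving the ordinary
    pooled two-sample t. Zero-variance genes (in both groups) get p = 1.
    """
    group = group.reindex(expr.sample_ids)
    if group.isna().any():
        raise ValueError("group label missing for some samples")
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise ValueError(f"group must be binary, got levels {levels}")
    g1 = group == levels[1]
    g0 = group == levels[0]
    n1, n0 = int(g1.sum()), int(g0.sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs >= 2 samples")

    X = expr.values.to_numpy(dtype=float)
    x1, x0 = X[:, g1.to_numpy()], X[:, g0.to_numpy()]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    d = n0 + n1 - 2
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / d
    log2fc = m1 - m0

    zero_var = s2 <= 0
    if zero_var.any():
        log.warning("moderated_t: %d zero-variance gene(s) assigned p = 1", int(zero_var.sum()))

    if shrink:
        d0, s0 = _fit_f_moments(s2[~zero_var], d)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0)
            df = np.inf
        else:
            s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
            df = d0 + d
    else:
        s2_tilde = s2.copy()
        df = float(d)

    se = np.sqrt(s2_tilde * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "t_stat": t,
            "p": p,
            "p_adj": p_adj,
            "contrast": contrast,
        }
    ).set_index("gene_id")


def select_degs(
    de: pd.DataFrame,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    use_adjusted: bool = False,
) -> list[str]:
    """Genes with |log2fc| > fc_thresh and (raw or BH) p < p_thresh."""
    if de.empty:
        raise ValueError("empty DE result")
    pcol = "p_adj" if use_adjusted else "p"
    mask = (de["log2fc"].abs() > fc_thresh) & (de[pcol] < p_thresh)
    return list(de.index[mask])


def shared_degs(
    expr: ExpressionMatrix,
    labels: pd.Series,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    use_adjusted: bool = False,
    mode: str = "union",
    shrink: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """DEG pool across k clusters via one-vs-rest contrasts.

    Returns the pooled gene list (union by default, intersection with
    ``mode='intersect'``) and a per-gene record of which contrasts fired.
    """
    labels = labels.reindex(expr.sample_ids)
    clusters = sorted(pd.unique(labels.dropna()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    fired: dict[str, list] = {}
    for c in clusters:
        onevs = (labels == c).astype(int)
        if onevs.sum() < 2 or (1 - onevs).sum() < 2:
            raise ValueError(f"cluster {c!r} (or its complement) has < 2 samples")
        de = moderated_t(expr, onevs, shrink=shrink, contrast=f"{c}_vs_rest")
        for g in select_degs(de, fc_thresh, p_thresh, use_adjusted):
            fired.setdefault(g, []).append(c)
    if mode == "union":
        genes = [g for g in expr.gene_ids if g in fired]
    elif mode == "intersect":
        genes = [g for g in expr.gene_ids if len(fired.get(g, [])) == len(clusters)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    record = pd.DataFrame(
        {"gene_id": list(fired), "contrasts": [",".join(map(str, v)) for v in fired.values()]}
    ).set_index("gene_id")
    return genes, record
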