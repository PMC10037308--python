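"""Gene-set over-representation (hypergeometric) and rank-based GSEA.

Over-representation follows the standard upper-tail hypergeometric test with
BH correction across sets. GSEA computes the weighted Kolmogorov-Smirnov
running-sum enrichment score on a supplied per-gene ranking (e.g. a
moderated t between score groups), with a gene-label permutation null for
the normalized score and p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, member genes per line."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def hypergeom_enrich(
    query: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set."""
    uni = set(universe)
    q = set(query)
    if not q or not uni:
        raise ValueError("empty query or universe")
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    M, n = len(uni), len(q)
    rows = []
    for name, genes in sets.items():
        members = set(genes) & uni
        K = len(members)
        overlap = len(members & q)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, n)) if K else 1.0
        rows.append({"set_id": name, "overlap": overlap, "set_size": K, "p": p})
    out = pd.DataFrame(rows).set_index("set_id")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable")


def _es_running(scores_sorted: np.ndarray, hit: np.ndarray, weight_p: float) -> float:
    """Signed maximum deviation of the GSEA running sum."""
    N = hit.size
    m = int(hit.sum())
    if m == N:
        return 0.0
    w = np.abs(scores_sorted) ** weight_p
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all in-set scores are exactly 0 with weighting
        w_hit = hit.astype(float)
        denom = float(m)
    p_hit = np.cumsum(w_hit) / denom
    p_miss = np.cumsum(~hit) / (N - m)
    run = p_hit - p_miss
    return float(run[np.argmax(np.abs(run))])


def gsea(
    ranking: pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 2020,
) -> tuple[float, float, float]:
    """GSEA enrichment score on a per-gene ranking -> (ES, NES, perm_p).

    The null permutes gene labels (in-set membership positions); NES divides
    ES by the mean |ES| of same-sign permutations, and perm_p is the
    fraction of same-sign permutation ES at least as extreme.
    """
    ranking = ranking.sort_values(ascending=False, kind="stable")
    in_set = ranking.index.isin(set(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has empty intersection with the ranking")
    if m == 1:
        log.warning("gsea: singleton gene set after intersection")
    scores = ranking.to_numpy(dtype=float)
    es = _es_running(scores, in_set, weight_p)
    if n_perm <= 0:
        return es, np.nan, np.nan
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    N = scores.size
    for b in range(n_perm):
        hit = np.zeros(N, dtype=bool)
        hit[rng.choice(N, size=m, replace=False)] = True
        null[b] = _es_running(scores, hit, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        return es, np.nan, float(1.0 / (n_perm + 1))
    nes = es / np.abs(same_sign).mean()
    perm_p = float((1 + (np.abs(same_sign) >= abs(es)).sum()) / (same_sign.size + 1))
    return float(es), float(nes), perm_p
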