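"""Monti-style resampled consensus clustering.

Used twice in the pipeline: samples x immune-fraction profiles give the ICI
clusters, and samples x DEG expression gives the gene clusters. Each
repetition subsamples a fraction of the samples, clusters them with a base
method (k-means by default, hierarchical available), and the consensus entry
for a pair is the proportion of co-sampled repetitions in which the pair
co-clustered. Final labels come from average-linkage hierarchical clustering
of 1 - consensus; k is selected by the proportion of ambiguous clustering
(PAC), with CDF areas reported for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame          # samples x samples in [0,1]; NaN = never co-sampled
    labels: pd.Series                # per-sample cluster id 1..k (by decreasing size)
    pac: float
    cdf_area: float
    never_cosampled: int = 0         # number of sample pairs never co-sampled


def _base_cluster(x: np.ndarray, k: int, base: str, rs: int) -> np.ndarray:
    if base == "kmeans":
        km = KMeans(n_clusters=k, n_init=2, random_state=rs)
        return km.fit_predict(x)
    if base == "hclust":
        z = linkage(x, method="average")
        return fcluster(z, t=k, criterion="maxclust")
    raise ValueError(f"unknown base clusterer {base!r}")


def consensus_matrix(
    features: pd.DataFrame,
    k: int,
    reps: int = 1000,
    sample_frac: float = 0.8,
    base: str = "kmeans",
    standardize: bool = True,
    seed: int = 2020,
) -> ConsensusResult:
    """Consensus-cluster rows of ``features`` into ``k`` groups."""
    n = features.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_samples (k={k}, n={n})")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    m = int(np.ceil(sample_frac * n))
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        lab = _base_cluster(X[idx], k, base, int(rng.integers(0, 2**31 - 1)))
        sel = np.zeros(n, dtype=bool)
        sel[idx] = True
        co_sample += np.outer(sel, sel)
        for c in np.unique(lab):
            members = idx[lab == c]
            ind = np.zeros(n, dtype=bool)
            ind[members] = True
            co_cluster += np.outer(ind, ind)

    with np.errstate(invalid="ignore", divide="ignore"):
        cons = co_cluster / co_sample
    never = co_sample == 0
    n_never = int(never[np.triu_indices(n, 1)].sum())
    if n_never:
        log.warning("consensus_matrix: %d sample pair(s) never co-sampled (NaN in matrix)", n_never)
    cons[never] = np.nan
    np.fill_diagonal(cons, 1.0)

    filled = np.where(np.isnan(cons), 0.0, cons)
    dist = squareform(1.0 - (filled + filled.T) / 2.0, checks=False)
    z = linkage(dist, method="average")
    raw_labels = fcluster(z, t=k, criterion="maxclust")
    labels = _relabel_by_size(raw_labels)

    triu = cons[np.triu_indices(n, 1)]
    triu = triu[~np.isnan(triu)]
    pac = float(np.mean((triu > 0.1) & (triu < 0.9))) if triu.size else 0.0
    cdf_area = _cdf_area(triu)
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(cons, index=features.index, columns=features.index),
        labels=pd.Series(labels, index=features.index, name="cluster"),
        pac=pac,
        cdf_area=cdf_area,
        never_cosampled=n_never,
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size (ties by first occurrence)."""
    ids, counts = np.unique(labels, return_counts=True)
    first = {i: int(np.argmax(labels == i)) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)], first[i]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


def _cdf_area(entries: np.ndarray, grid: int = 100) -> float:
    if entries.size == 0:
        return 0.0
    xs = np.linspace(0, 1, grid + 1)
    cdf = np.searchsorted(np.sort(entries), xs, side="right") / entries.size
    return float(np.trapezoid(cdf, xs))


@dataclass
class KSelection:
    chosen_k: int
    pac: dict[int, float]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    no_structure: bool = False


def select_k(results: list[ConsensusResult]) -> KSelection:
    """Choose k by minimum PAC (ties to the smaller k); report CDF diagnostics.

    When even the best PAC exceeds 0.5 the data show no reproducible cluster
    structure; a k is still returned, flagged ``no_structure``.
    """
    if len(results) < 2:
        raise ValueError("select_k needs >= 2 candidate k")
    results = sorted(results, key=lambda r: r.k)
    pac = {r.k: r.pac for r in results}
    area = {r.k: r.cdf_area for r in results}
    delta = {}
    prev = None
    for r in results:
        delta[r.k] = np.nan if prev is None else (r.cdf_area - prev) / prev if prev else np.nan
        prev = r.cdf_area
    chosen = min(pac, key=lambda k: (pac[k], k))
    no_structure = pac[chosen] > 0.5
    if no_structure:
        log.warning("select_k: minimum PAC %.3f > 0.5 — no reproducible structure", pac[chosen])
    return KSelection(chosen, pac, area, delta, no_structure)
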