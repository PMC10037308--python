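"""Single-cell QC filters and highly-variable-gene selection.

Cells are kept when they detect enough genes, carry an acceptable
mitochondrial fraction, and show enough library complexity ("novelty" =
log10 genes / log10 UMIs). The boundary convention keeps cells exactly at a
threshold (the removal rules are strict inequalities: < 200 genes, > 15%
mito, < 0.8 novelty). HVGs are ranked by log-expression variance
standardized within mean bins after counts-per-10k normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class QCSummary:
    n_total: int
    n_kept: int
    n_removed: int
    fail_genes: int
    fail_mito: int
    fail_novelty: int


def novelty_score(n_genes: np.ndarray, n_umi: np.ndarray) -> np.ndarray:
    """log10(genes detected) / log10(UMIs); defined only for n_umi > 1."""
    n_genes = np.asarray(n_genes, dtype=float)
    n_umi = np.asarray(n_umi, dtype=float)
    out = np.full(n_genes.shape, np.nan)
    ok = n_umi > 1
    out[ok] = np.log10(np.maximum(n_genes[ok], 1.0)) / np.log10(n_umi[ok])
    return out


def cell_qc_filter(
    cells: pd.DataFrame,
    min_genes: int = 200,
    max_mito: float = 0.15,
    min_novelty: float = 0.8,
) -> tuple[pd.DataFrame, QCSummary]:
    """Apply the three QC rules; returns (filtered table, removal summary).

    ``cells`` needs columns n_genes, n_umi, mito_fraction. Keep iff
    n_genes >= min_genes AND mito_fraction <= max_mito AND novelty >=
    min_novelty (cells with <= 1 UMI have undefined novelty and are
    removed). Removal counts per rule are non-exclusive.
    """
    for col in ("n_genes", "n_umi", "mito_fraction"):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    if (cells["n_genes"] < 0).any() or (cells["n_umi"] < 0).any():
        raise ValueError("negative counts")
    nov = novelty_score(cells["n_genes"].to_numpy(), cells["n_umi"].to_numpy())
    fail_genes = cells["n_genes"].to_numpy() < min_genes
    fail_mito = cells["mito_fraction"].to_numpy() > max_mito
    fail_nov = ~(nov >= min_novelty)  # NaN novelty fails
    keep = ~(fail_genes | fail_mito | fail_nov)
    out = cells.loc[keep].copy()
    out["novelty"] = nov[keep]
    summary = QCSummary(
        n_total=len(cells),
        n_kept=int(keep.sum()),
        n_removed=int((~keep).sum()),
        fail_genes=int(fail_genes.sum()),
        fail_mito=int(fail_mito.sum()),
        fail_novelty=int(fail_nov.sum()),
    )
    return out, summary


def hvg_select(counts: pd.DataFrame, n_top: int = 2000, n_bins: int = 20) -> list[str]:
    """Top highly variable genes by binned standardized dispersion.

    ``counts`` is genes x cells, non-negative. Cells are library-size
    normalized to counts-per-10k and log1p-transformed; per-gene variance of
    the log values is z-scored within ``n_bins`` equal-width bins of the
    gene mean, and the top ``n_top`` genes by that standardized variance are
    returned (ordered, most variable first).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if n_top > counts.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    norm = np.log1p(counts.div(lib, axis=1) * 1e4)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    bins = pd.cut(mean, bins=n_bins, labels=False, include_lowest=True)
    z = pd.Series(index=var.index, dtype=float)
    for b, idx in var.groupby(bins).groups.items():
        v = var.loc[idx]
        sd = v.std(ddof=1)
        z.loc[idx] = (v - v.mean()) / sd if sd and sd > 0 else 0.0
    ranked = z.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_top])
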