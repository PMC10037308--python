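"""Tumor mutational burden and ICI-group x mutation contingency analysis.

TMB is the raw count of non-silent somatic records per sample (a unitless
burden index; per-megabase scaling is a config constant for users who want
it). The contingency table mirrors the published layout: for each frequently
mutated gene, wild/mutated counts within the high- and low-score groups with
a Yates-corrected chi-square p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MAFTable

log = logging.getLogger(__name__)

#: variant classes counted toward TMB
NONSILENT = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)


def compute_tmb(maf: MAFTable, samples: list[str], classes=NONSILENT, per_mb: float | None = None) -> pd.Series:
    """Non-silent mutation count per sample (0 for samples absent from MAF)."""
    rec = maf.records
    counted = rec[rec["Variant_Classification"].isin(classes)]
    counts = counted.groupby("Tumor_Sample_Barcode").size()
    tmb = counts.reindex(samples).fillna(0).astype(float)
    if per_mb:
        tmb = tmb / per_mb
    return tmb.rename("tmb")


def yates_chisq(table) -> tuple[float, float]:
    """Yates-continuity-corrected Pearson chi-square on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(chi2), float(p)


def mutated_gene_table(
    maf: MAFTable,
    groups: pd.Series,
    top_n: int = 20,
    classes=NONSILENT,
) -> pd.DataFrame:
    """Per-gene wild/mutated contingency between score groups.

    A sample counts as mutated for a gene when it carries >= 1 non-silent
    record. The table covers the union of the ``top_n`` most frequently
    mutated genes within each group, with Yates chi-square across groups,
    sorted by p. Genes mutated in every sample (or none) of both groups have
    a zero margin and are reported with chi2 = 0, p = 1.
    """
    rec = maf.records
    maf_samples = set(rec["Tumor_Sample_Barcode"])
    missing = maf_samples - set(groups.index)
    if missing:
        raise ValueError(f"MAF samples without a group label: {sorted(missing)[:5]}")
    if set(pd.unique(groups)) - {"high", "low"}:
        raise ValueError("groups must be 'high'/'low'")
    n_high = int((groups == "high").sum())
    n_low = int((groups == "low").sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both score groups must be non-empty")

    nonsilent = rec[rec["Variant_Classification"].isin(classes)]
    mutated = (
        nonsilent.drop_duplicates(["Tumor_Sample_Barcode", "Hugo_Symbol"])
        .assign(group=lambda d: groups.loc[d["Tumor_Sample_Barcode"]].to_numpy())
        .groupby(["Hugo_Symbol", "group"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["high", "low"], fill_value=0)
    )
    top = set()
    for g, n in (("high", n_high), ("low", n_low)):
        freq = mutated[g] / n
        top |= set(freq.sort_values(ascending=False, kind="stable").head(top_n).index)

    rows = []
    for gene in sorted(top):
        h_mut = int(mutated.loc[gene, "high"])
        l_mut = int(mutated.loc[gene, "low"])
        h_wild, l_wild = n_high - h_mut, n_low - l_mut
        table = [[h_wild, h_mut], [l_wild, l_mut]]
        try:
            chi2, p = yates_chisq(table)
        except ValueError:
            chi2, p = 0.0, 1.0
        rows.append(
            {
                "gene": gene,
                "high_wild": h_wild,
                "high_mut": h_mut,
                "low_wild": l_wild,
                "low_mut": l_mut,
                "high_mut_pct": 100.0 * h_mut / n_high,
                "low_mut_pct": 100.0 * l_mut / n_low,
                "chi2": chi2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene").sort_values("p", kind="stable")
    return out


def tmb_score_association(tmb: pd.Series, score: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) between burden and score."""
    score = score.reindex(tmb.index)
    if len(tmb) < 10:
        raise ValueError("need >= 10 samples")
    if tmb.nunique() <= 1 or score.nunique() <= 1:
        raise ValueError("constant input to Spearman correlation")
    res = stats.spearmanr(tmb, score)
    return float(res.statistic), float(res.pvalue)


def tmb_ici_strata(tmb: pd.Series, score_groups: pd.Series, clinical) -> tuple[pd.Series, tuple[float, int, float]]:
    """Cross median-split TMB with the ICI group and log-rank the strata.

    TMB at or below the median goes to the low-burden stratum. Empty strata
    are dropped with a warning (reducing the test's df).
    """
    from .survival import logrank

    groups = score_groups.reindex(tmb.index)
    med = float(np.median(tmb))
    tmb_grp = np.where(tmb > med, "TMB-high", "TMB-low")
    strata = pd.Series(
        [f"{t}/{g}-ICI" for t, g in zip(tmb_grp, groups)], index=tmb.index, name="stratum"
    )
    counts = strata.value_counts()
    expected = {f"{t}/{g}-ICI" for t in ("TMB-high", "TMB-low") for g in ("high", "low")}
    empty = expected - set(counts.index)
    if empty:
        log.warning("tmb_ici_strata: empty stratum(s) %s; df reduced", sorted(empty))
    clin = clinical.aligned(list(strata.index))
    chi2, df, p = logrank(clin.times, clin.events, strata.to_numpy())
    return strata, (chi2, df, p)
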