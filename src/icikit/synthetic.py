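"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the scoring pipeline
assumes: bulk expression is a non-negative mixture of cell-type signature
profiles, per-sample mixing proportions follow subtype-specific Dirichlet
distributions (three immune subtypes A/B/C), overall survival is exponential
with a subtype-specific hazard, and mutation burden is Poisson with a
log-linear link to an arbitrary per-sample score. Subtype B is the planted
"immune-hot" subtype: it is enriched for the cytotoxic-like cell type and
carries the lowest hazard, mirroring the favorable-prognosis, immune-activated
subgroup bulk-tumor studies report.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, ExpressionMatrix, MAFTable

SUBTYPES = ("A", "B", "C")
#: index of the planted immune-hot subtype (best survival, cytotoxic-rich)
HOT_SUBTYPE = "B"

#: default per-subtype Dirichlet concentrations for 5 cell types: subtype j
#: is enriched for cell type j (cell type 1 = cytotoxic-like, hot in B).
DEFAULT_DIRICHLET = (
    (10.0, 1.0, 1.0, 0.8, 0.8),
    (1.0, 10.0, 1.0, 0.8, 0.8),
    (1.0, 1.0, 10.0, 0.8, 0.8),
)

#: default exponential hazards per day: B best, C worst
DEFAULT_HAZARDS = (0.001, 0.0005, 0.002)

NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Nonstop_Mutation",
    "Translation_Start_Site",
)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth_subtype: pd.Series            # per-sample label in {A,B,C}
    truth_fractions: pd.DataFrame       # samples x cell types, rows sum to 1
    signature: pd.DataFrame             # genes x cell types, non-negative

    @property
    def hot_markers(self) -> list[str]:
        """Marker genes of the cytotoxic-like cell type enriched in subtype B."""
        hot_ct = self.signature.columns[SUBTYPES.index(HOT_SUBTYPE)]
        col = self.signature[hot_ct]
        others = self.signature.drop(columns=hot_ct).max(axis=1)
        return list(col.index[col > 2 * others])


def _make_signature(n_genes: int, n_celltypes: int, markers_per_type: int,
                    marker_fold: float, rng: np.random.Generator) -> pd.DataFrame:
    if markers_per_type * n_celltypes > n_genes:
        raise ValueError("not enough genes for the requested marker blocks")
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cts = [f"CT{j}" for j in range(n_celltypes)]
    base = rng.lognormal(mean=0.0, sigma=0.2, size=(n_genes, n_celltypes))
    sig = base.copy()
    for j in range(n_celltypes):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        sig[block, :] = base[block, :]
        sig[block, j] *= marker_fold
    return pd.DataFrame(sig, index=genes, columns=cts)


def simulate_cohort(
    n_samples: int = 300,
    n_genes: int = 500,
    n_celltypes: int = 5,
    subtype_dirichlet=DEFAULT_DIRICHLET,
    noise_sd: float = 0.3,
    hazard_by_subtype=DEFAULT_HAZARDS,
    censor_rate: float = 0.0005,
    markers_per_type: int | None = None,
    marker_fold: float = 8.0,
    seed: int = 2020,
) -> SyntheticCohort:
    """Simulate a bulk cohort with three planted immune subtypes.

    Expression = signature . fractions^T perturbed by multiplicative
    log-normal noise with log-sd ``noise_sd``; survival is exponential with
    the subtype's hazard under independent exponential censoring.
    """
    subtype_dirichlet = [np.asarray(a, dtype=float) for a in subtype_dirichlet]
    if len(subtype_dirichlet) != len(SUBTYPES):
        raise ValueError(f"need {len(SUBTYPES)} Dirichlet concentration vectors")
    for a in subtype_dirichlet:
        if len(a) != n_celltypes:
            raise ValueError("concentration vector length must equal n_celltypes")
        if (a <= 0).any():
            raise ValueError("degenerate Dirichlet: concentrations must be positive")
    hazard_by_subtype = np.asarray(hazard_by_subtype, dtype=float)
    if (hazard_by_subtype <= 0).any():
        raise ValueError("hazard rates must be positive")
    if n_celltypes < 3:
        raise ValueError("n_celltypes must be >= 3")

    if markers_per_type is None:
        # 20 markers per type by default, shrinking for small gene panels
        markers_per_type = max(2, min(20, n_genes // (2 * n_celltypes)))
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    sig = _make_signature(n_genes, n_celltypes, markers_per_type, marker_fold, rng)

    subtype_idx = rng.integers(0, len(SUBTYPES), size=n_samples)
    fractions = np.empty((n_samples, n_celltypes))
    for j, alpha in enumerate(subtype_dirichlet):
        mask = subtype_idx == j
        fractions[mask] = rng.dirichlet(alpha, size=int(mask.sum()))
    truth_fractions = pd.DataFrame(fractions, index=samples, columns=sig.columns)

    mix = sig.to_numpy() @ fractions.T            # genes x samples
    if noise_sd > 0:
        mix = mix * rng.lognormal(mean=0.0, sigma=noise_sd, size=mix.shape)
    expr = ExpressionMatrix(pd.DataFrame(mix, index=sig.index, columns=samples), unit="TPM")

    hazards = hazard_by_subtype[subtype_idx]
    event_t = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        censor_t = np.full(n_samples, np.inf)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)
    age = rng.integers(25, 85, size=n_samples)
    grade = rng.choice(["G1", "G2", "G3"], size=n_samples)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"os_time": os_time, "os_event": os_event, "age": age, "grade": grade},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth_subtype = pd.Series([SUBTYPES[j] for j in subtype_idx], index=samples, name="subtype")
    return SyntheticCohort(expr, clinical, truth_subtype, truth_fractions, sig)


def simulate_maf(
    cohort: SyntheticCohort,
    score: pd.Series,
    tmb_slope: float = 0.5,
    n_mut_genes: int = 50,
    mean_tmb: float = 10.0,
    n_biased_genes: int = 3,
    biased_odds: float = 5.0,
    seed: int = 2020,
) -> MAFTable:
    """Simulate a MAF whose per-sample burden tracks ``score``.

    Non-silent counts are Poisson(exp(a + tmb_slope * z(score))) with
    ``a = log(mean_tmb)``; mutated genes are drawn from a fixed catalog in
    which the first ``n_biased_genes`` genes have ``biased_odds``-fold
    sampling weight in above-median-score samples, planting contingency-table
    contrasts. A light sprinkling of Silent records exercises burden filters.
    """
    if n_mut_genes <= 0:
        raise ValueError("n_mut_genes must be positive")
    samples = cohort.expression.sample_ids
    score = score.reindex(samples)
    if score.isna().any():
        raise ValueError("score must be defined for all samples")
    rng = np.random.default_rng(seed)
    z = (score - score.mean()) / (score.std(ddof=0) or 1.0)
    lam = np.exp(np.log(mean_tmb) + tmb_slope * z.to_numpy())
    catalog = np.array([f"MUT{i:03d}" for i in range(n_mut_genes)])
    high = score.to_numpy() > np.median(score.to_numpy())

    rows = []
    for i, s in enumerate(samples):
        k = min(int(rng.poisson(lam[i])), n_mut_genes)
        w = np.ones(n_mut_genes)
        if high[i]:
            w[:n_biased_genes] = biased_odds
        w /= w.sum()
        genes = rng.choice(catalog, size=k, replace=False, p=w)
        classes = rng.choice(NONSILENT_CLASSES, size=k)
        rows += [(s, g, c) for g, c in zip(genes, classes)]
        for _ in range(rng.poisson(1.0)):
            rows.append((s, str(rng.choice(catalog)), "Silent"))
    df = pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"])
    df = df.drop_duplicates(ignore_index=True)
    return MAFTable(df)


def simulate_sc_metadata(
    n_cells: int = 1000,
    frac_low_genes: float = 0.05,
    frac_high_mito: float = 0.05,
    frac_low_novelty: float = 0.05,
    zero_mito: bool = False,
    seed: int = 2020,
) -> pd.DataFrame:
    """Per-cell QC metadata with planted low-quality subpopulations.

    Good cells sit comfortably inside all three filters (>=400 genes, mito
    <= 0.10, novelty >= 0.85); each planted failure group violates exactly
    one rule. The returned table carries a ``planted_fail`` column naming the
    violated rule ('none' for good cells) so filter bookkeeping can be
    checked exactly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_lg = int(round(frac_low_genes * n_cells))
    n_hm = int(round(frac_high_mito * n_cells))
    n_ln = int(round(frac_low_novelty * n_cells))
    n_good = n_cells - n_lg - n_hm - n_ln
    if n_good < 0:
        raise ValueError("planted fractions exceed 1")

    def good_cells(n):
        # genes in [400, 4000]; umi = genes**(1/0.9) keeps novelty ~0.9
        genes = rng.integers(400, 4000, size=n)
        umi = np.ceil(genes ** (1 / 0.9)).astype(int)
        mito = rng.uniform(0.0, 0.10, size=n)
        return genes, umi, mito

    blocks = []
    g, u, m = good_cells(n_good)
    blocks.append((g, u, m, np.repeat("none", n_good)))

    # low gene count, everything else clean (umi low enough to keep novelty high)
    g = rng.integers(50, 200, size=n_lg)
    u = np.ceil(g ** (1 / 0.9)).astype(int)
    m = rng.uniform(0.0, 0.10, size=n_lg)
    blocks.append((g, u, m, np.repeat("genes", n_lg)))

    # high mito, otherwise clean
    g, u, _ = good_cells(n_hm)
    m = rng.uniform(0.20, 0.6, size=n_hm)
    blocks.append((g, u, m, np.repeat("mito", n_hm)))

    # low novelty: plenty of UMIs but few distinct genes
    g = rng.integers(400, 1000, size=n_ln)
    u = np.ceil(g ** (1 / 0.7)).astype(int)   # novelty ~0.7
    m = rng.uniform(0.0, 0.10, size=n_ln)
    blocks.append((g, u, m, np.repeat("novelty", n_ln)))

    genes = np.concatenate([b[0] for b in blocks])
    umi = np.concatenate([b[1] for b in blocks])
    mito = np.concatenate([b[2] for b in blocks])
    planted = np.concatenate([b[3] for b in blocks])
    if zero_mito:
        mito = np.zeros_like(mito)
        planted = np.where(planted == "mito", "none", planted)
    order = rng.permutation(n_cells)
    df = pd.DataFrame(
        {
            "cell_id": [f"C{i:05d}" for i in range(n_cells)],
            "n_genes": genes[order],
            "n_umi": umi[order],
            "mito_fraction": mito[order],
            "planted_fail": planted[order],
        }
    ).set_index("cell_id")
    return df
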