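"""Containers and readers for the formats the pipeline touches.

Bulk expression lives in an :class:`ExpressionMatrix` (genes x samples with a
unit tag and per-sample cohort labels); clinical follow-up in a
:class:`ClinicalTable`; somatic mutations in a long-form :class:`MAFTable`.
Preprocessing covers FPKM->TPM conversion and the cross-cohort merge
(log2(TPM+1) then per-gene z-scoring within each cohort) used before
clustering and scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: allowed expression unit tags
UNITS = ("FPKM", "TPM", "LOG2TPM")

#: MAF controlled vocabulary for Variant_Classification
MAF_CLASSES = frozenset(
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
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


class ParseError(ValueError):
    """Raised when an on-disk table violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a unit tag and cohort labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``cohort`` maps each sample to a cohort label (single-cohort data uses a
    single shared label).
    """

    values: pd.DataFrame
    unit: str = "TPM"
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if self.cohort is None:
            self.cohort = pd.Series("cohort1", index=self.values.columns)
        self.cohort = self.cohort.reindex(self.values.columns)
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.empty:
            raise ValueError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.unit != "LOG2TPM" and (arr < 0).any():
            raise ValueError(f"negative values are not valid for unit {self.unit}")
        if self.cohort.isna().any():
            raise ValueError("cohort label missing for some samples")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], unit=self.unit, cohort=self.cohort.copy())

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ClinicalTable:
    """Per-sample overall-survival follow-up plus optional age/grade."""

    df: pd.DataFrame  # index sample_id; columns os_time, os_event[, age, grade]

    def __post_init__(self) -> None:
        required = {"os_time", "os_event"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if (self.df["os_time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.df["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def aligned(self, sample_ids) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise ValueError(f"samples without clinical data: {missing[:5]}")
        return ClinicalTable(self.df.loc[list(sample_ids)].copy())

    @property
    def times(self) -> np.ndarray:
        return self.df["os_time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["os_event"].to_numpy(dtype=int)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class MAFTable:
    """Long-form somatic mutation records (sample, gene, variant class)."""

    records: pd.DataFrame  # columns Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification

    def __post_init__(self) -> None:
        missing = set(MAF_REQUIRED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"MAF table missing columns: {sorted(missing)}")
        bad = set(self.records["Variant_Classification"]) - MAF_CLASSES
        if bad:
            raise ValueError(f"unknown Variant_Classification values: {sorted(bad)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["Tumor_Sample_Barcode"]))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV expression table.

    The first column holds gene ids, the header holds sample ids. Duplicate
    gene rows are collapsed by mean; non-numeric cells raise a
    :class:`ParseError` naming the offending row and column.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique()
        raise ParseError(f"{path}: duplicate sample ids in header: {list(dups[:5])}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy() )
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {values.index[i]!r}, sample "
            f"{values.columns[j]!r} (value {raw.iat[i, j]!r})"
        )
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        log.warning("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        values = values.groupby(level=0, sort=False).mean()
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values, unit=unit)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ClinicalTable(df)


def read_maf(path) -> MAFTable:
    """Read a tab-separated MAF, keeping the three mandatory columns.

    Extra columns are ignored; fully duplicated records are dropped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing mandatory column(s): {missing}")
    df = df[list(MAF_REQUIRED_COLUMNS)]
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < n_before:
        log.warning("%s: dropped %d fully duplicated MAF records", path, n_before - len(df))
    return MAFTable(df)


def fpkm_to_tpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM columns to TPM: TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6."""
    if x.unit != "FPKM":
        raise ValueError(f"fpkm_to_tpm expects unit FPKM, got {x.unit}")
    colsums = x.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {list(zero.index[:5])}")
    values = x.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values, unit="TPM", cohort=x.cohort.copy())


def merge_cohorts(cohorts: list[ExpressionMatrix], labels: list[str] | None = None) -> ExpressionMatrix:
    """Merge cohorts on shared genes with within-cohort standardization.

    Each cohort is brought to log2(TPM+1) (FPKM input is converted first) and
    every gene is z-scored within its cohort, which removes cohort-level
    location/scale differences before concatenation. Genes with zero variance
    in any cohort are dropped (logged). Output unit is LOG2TPM (standardized).
    """
    if len(cohorts) < 2:
        raise ValueError("merge_cohorts needs at least two cohorts")
    if labels is None:
        labels = [f"cohort{i + 1}" for i in range(len(cohorts))]
    shared = cohorts[0].values.index
    for c in cohorts[1:]:
        shared = shared.intersection(c.values.index)
    # keep first-cohort gene order
    shared = [g for g in cohorts[0].gene_ids if g in set(shared)]
    if not shared:
        raise ValueError("empty gene intersection across cohorts")
    all_samples = pd.Index([])
    for c in cohorts:
        overlap = all_samples.intersection(c.values.columns)
        if len(overlap):
            raise ValueError(f"duplicate sample id across cohorts: {list(overlap[:5])}")
        all_samples = all_samples.append(c.values.columns)

    blocks, cohort_labels, drop = [], [], set()
    logged = []
    for c in cohorts:
        x = c
        if x.unit == "FPKM":
            x = fpkm_to_tpm(x)
        vals = x.values.loc[shared]
        if x.unit != "LOG2TPM":
            vals = np.log2(vals + 1.0)
        logged.append(vals)
        sd = vals.std(axis=1, ddof=1)
        drop |= set(sd.index[(sd == 0) | sd.isna()])
    if drop:
        log.warning("merge_cohorts: dropping %d gene(s) with zero within-cohort variance", len(drop))
    keep = [g for g in shared if g not in drop]
    if not keep:
        raise ValueError("no genes with nonzero variance in every cohort")
    for vals, c, lab in zip(logged, cohorts, labels):
        vals = vals.loc[keep]
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        z = vals.sub(mu, axis=0).div(sd, axis=0)
        blocks.append(z)
        cohort_labels.append(pd.Series(lab, index=vals.columns))
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(merged, unit="LOG2TPM", cohort=pd.concat(cohort_labels))


def standardize_single(x: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM+1) + per-gene z-score for a single cohort (merge of one)."""
    vals = x.values
    if x.unit == "FPKM":
        vals = fpkm_to_tpm(x).values
    if x.unit != "LOG2TPM":
        vals = np.log2(vals + 1.0)
    sd = vals.std(axis=1, ddof=1)
    keep = sd[(sd > 0)].index
    if len(keep) < len(vals):
        log.warning("standardize_single: dropping %d zero-variance gene(s)", len(vals) - len(keep))
    vals = vals.loc[keep]
    z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
    return ExpressionMatrix(z, unit="LOG2TPM", cohort=x.cohort.copy())
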