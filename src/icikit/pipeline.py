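"""End-to-end pipeline drivers.

``run_scoring_pipeline`` executes the in-memory analysis chain on a cohort:
immune fractions -> ICI clusters -> DEGs -> gene clusters -> signature split
(optional Boruta) -> PC1 scores -> ICI score -> optimal-cutoff dichotomy ->
log-rank. ``run_full_pipeline`` is the on-disk driver: it reads the inputs
named in a config mapping (YAML-friendly), runs the stages in order, and
writes one TSV per stage plus a run log carrying the seed and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus, de, deconvolution, mutation, scoring, survival
from .io_core import (
    ClinicalTable,
    ExpressionMatrix,
    MAFTable,
    merge_cohorts,
    read_clinical,
    read_expression,
    read_maf,
    standardize_single,
)

log = logging.getLogger(__name__)


@dataclass
class ScoringResult:
    fractions: pd.DataFrame
    ici_labels: pd.Series        # A/B/C...
    degs: list[str]
    gene_labels: pd.Series       # A/B
    genes_A: list[str]
    genes_B: list[str]
    score: pd.Series
    group: pd.Series             # high/low
    cutoff: float
    logrank_chi2: float
    logrank_p: float
    pc1_A: pd.Series
    pc1_B: pd.Series


def _letters(labels: pd.Series) -> pd.Series:
    """Map size-ranked integer cluster ids 1..k to letters A..Z."""
    return labels.map(lambda i: chr(ord("A") + int(i) - 1)).rename(labels.name)


def _side_pc1(std: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """PC1 of a signature side, degrading gracefully for tiny sides."""
    if len(genes) >= 2:
        return scoring.pc1_scores(std, genes)
    if len(genes) == 1 and genes[0] in std.values.index:
        g = std.values.loc[genes[0]]
        sd = g.std(ddof=1)
        z = (g - g.mean()) / (sd if sd > 0 else 1.0)
        return pd.Series(z.to_numpy(), index=std.sample_ids, name="pc1")
    return pd.Series(0.0, index=std.sample_ids, name="pc1")


def run_scoring_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: pd.DataFrame,
    k_ici: int = 3,
    k_gene: int = 2,
    reps: int = 1000,
    sample_frac: float = 0.8,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    use_boruta: bool = False,
    boruta_iter: int = 30,
    boruta_trees: int = 100,
    orient_markers: list[str] | None = None,
    cutoff_floor: float = 0.1,
    cutoff_perms: int = 0,
    fractions: pd.DataFrame | None = None,
    seed: int = 2020,
) -> ScoringResult:
    """Run the scoring chain on one cohort held in memory.

    ``expr`` should be on a linear scale (TPM/FPKM) for deconvolution; DE
    and PCA stages run on the log2(TPM+1) per-gene z-scored matrix.
    ``fractions`` accepts an externally computed fraction table (e.g.
    canonical CIBERSORT output), bypassing the NNLS estimator.
    ``orient_markers`` anchors the score sign to immune-hot samples (mean
    standardized expression of the marker set); without it the sign follows
    the arbitrary gene-cluster labeling.
    """
    if fractions is None:
        fractions = deconvolution.estimate_fractions(expr, signature, seed=seed).fractions
    std = expr if expr.unit == "LOG2TPM" else standardize_single(expr)

    ici_res = consensus.consensus_matrix(
        fractions, k=k_ici, reps=reps, sample_frac=sample_frac, seed=seed
    )
    ici_labels = _letters(ici_res.labels).rename("ici_cluster")

    degs, _ = de.shared_degs(std, ici_labels, fc_thresh=fc_thresh, p_thresh=p_thresh)
    if len(degs) < 2:
        raise RuntimeError("fewer than 2 DEGs across ICI clusters; cannot build a signature")

    gene_res = consensus.consensus_matrix(
        std.values.loc[degs].T, k=k_gene, reps=reps, sample_frac=sample_frac, seed=seed + 1
    )
    gene_labels = _letters(gene_res.labels).rename("gene_cluster")

    split = scoring.assign_signature_genes(std, degs, gene_labels)
    genes_A, genes_B = split.genes_A, split.genes_B
    if use_boruta:
        for side, genes in (("A", genes_A), ("B", genes_B)):
            if len(genes) < 2:
                continue
            confirmed, _ = scoring.boruta_select(
                std.values.loc[genes].T,
                gene_labels,
                n_iter=boruta_iter,
                trees=boruta_trees,
                seed=seed + (2 if side == "A" else 3),
            )
            if len(confirmed) >= 2:
                if side == "A":
                    genes_A = confirmed
                else:
                    genes_B = confirmed

    pc1_A = _side_pc1(std, genes_A)
    pc1_B = _side_pc1(std, genes_B)
    score = scoring.ici_score(pc1_A, pc1_B)
    if orient_markers:
        ref_genes = [g for g in orient_markers if g in std.values.index]
        if len(ref_genes):
            ref = std.values.loc[ref_genes].mean(axis=0)
            score = scoring.orient_score(score, ref)

    dich = scoring.dichotomize(
        score, clinical, pc1_A=pc1_A, pc1_B=pc1_B,
        floor=cutoff_floor, n_perm=cutoff_perms, seed=seed,
    )
    clin = clinical.aligned(list(score.index))
    chi2, _, p = survival.logrank(clin.times, clin.events, dich.table["group"].to_numpy())
    return ScoringResult(
        fractions=fractions,
        ici_labels=ici_labels,
        degs=degs,
        gene_labels=gene_labels,
        genes_A=genes_A,
        genes_B=genes_B,
        score=score,
        group=dich.table["group"],
        cutoff=dich.cutoff,
        logrank_chi2=chi2,
        logrank_p=p,
        pc1_A=pc1_A,
        pc1_B=pc1_B,
    )


def load_config(path) -> dict:
    """Read a pipeline configuration mapping from a YAML file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_full_pipeline(config: dict, outdir=None) -> dict:
    """Execute the pipeline from a config mapping, writing stage TSVs.

    Config keys (paths are read relative to the caller's cwd):

    - ``expression``: path to a genes x samples TSV (single cohort), or
      ``cohorts``: list of ``{path, unit, label}`` mappings merged on shared
      genes with within-cohort standardization before DE/PCA stages.
    - ``unit``: expression unit for the single-cohort case (default TPM).
    - ``clinical``: path to the clinical TSV (sample_id, os_time, os_event).
    - ``signature``: path to the genes x cell-types signature TSV.
    - ``maf`` (optional): somatic mutations; enables the TMB stage.
    - ``params`` (optional): keyword overrides for
      :func:`run_scoring_pipeline`.
    - ``seed``: integer seed (default 2020).
    - ``outdir``: output directory (may also be given as the argument).

    Returns a manifest dict of stage -> written file. Any stage failure
    aborts with the stage name and cause.
    """
    outdir = Path(outdir or config.get("outdir", "icikit_out"))
    seed = int(config.get("seed", 2020))
    params = dict(config.get("params", {}))

    stage = "inputs"
    try:
        if "clinical" not in config:
            raise ValueError("config missing 'clinical'")
        clinical = read_clinical(config["clinical"])
        if "cohorts" in config:
            parts, labels = [], []
            for spec_ in config["cohorts"]:
                parts.append(read_expression(spec_["path"], unit=spec_.get("unit", "TPM")))
                labels.append(spec_.get("label", spec_["path"]))
            expr = merge_cohorts(parts, labels)
        elif "expression" in config:
            expr = read_expression(config["expression"], unit=config.get("unit", "TPM"))
        else:
            raise ValueError("config needs 'expression' or 'cohorts'")
        if "signature" not in config:
            raise ValueError("config missing 'signature'")
        signature = pd.read_csv(config["signature"], sep="\t", index_col=0)
        maf = read_maf(config["maf"]) if config.get("maf") else None
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    stage = "scoring"
    try:
        res = run_scoring_pipeline(expr, clinical, signature, seed=seed, **params)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    def _write(name, obj):
        path = outdir / name
        obj.to_csv(path, sep="\t")
        manifest[name] = str(path)

    _write("fractions.tsv", res.fractions)
    _write("ici_clusters.tsv", res.ici_labels)
    _write("gene_clusters.tsv", res.gene_labels)
    deg_df = pd.DataFrame(
        {"gene_id": res.degs,
         "signature_side": ["A" if g in set(res.genes_A) else ("B" if g in set(res.genes_B) else "excluded")
                            for g in res.degs]}
    ).set_index("gene_id")
    _write("degs.tsv", deg_df)
    score_df = pd.DataFrame(
        {"pc1_A": res.pc1_A, "pc1_B": res.pc1_B, "ici_score": res.score, "group": res.group}
    )
    _write("ici_scores.tsv", score_df)
    surv_df = pd.DataFrame(
        {"cutoff": [res.cutoff], "logrank_chi2": [res.logrank_chi2], "logrank_p": [res.logrank_p]}
    )
    _write("survival_logrank.tsv", surv_df)

    if maf is not None:
        stage = "mutation"
        try:
            tmb = mutation.compute_tmb(maf, expr.sample_ids)
            _write("tmb.tsv", tmb)
            mut_table = mutation.mutated_gene_table(maf, res.group)
            _write("mutation_table.tsv", mut_table)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    run_log = {
        "seed": seed,
        "params": {k: (v if isinstance(v, (int, float, str, bool, list)) else str(v)) for k, v in params.items()},
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "stages": sorted(manifest),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    manifest["run_log.json"] = str(outdir / "run_log.json")
    return manifest
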