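"""Generate the synthetic study cohort and write its ground truth.

Outputs (results/data/): expression TSV (TPM-scale mixture of cell-type
profiles), clinical table, cell-type signature matrix, true fractions and
subtypes, and per-cell single-cell QC metadata.
"""

from common import SEED, get_cohort, outdir

from icikit.synthetic import simulate_sc_metadata


def main():
    out = outdir("data")
    c = get_cohort()
    c.expression.to_tsv(out / "expression.tsv")
    c.clinical.to_tsv(out / "clinical.tsv")
    c.signature.to_csv(out / "signature.tsv", sep="\t", index_label="gene_id")
    c.truth_fractions.to_csv(out / "truth_fractions.tsv", sep="\t", index_label="sample_id")
    c.truth_subtype.to_csv(out / "truth_subtype.tsv", sep="\t", index_label="sample_id")
    simulate_sc_metadata(n_cells=1000, seed=SEED).to_csv(
        out / "sc_metadata.tsv", sep="\t", index_label="cell_id"
    )
    print(f"cohort: {c.expression.n_samples} samples x {c.expression.n_genes} genes")
    print("subtype counts:\n", c.truth_subtype.value_counts().to_string())
    print(f"event rate: {c.clinical.events.mean():.2f}")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
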