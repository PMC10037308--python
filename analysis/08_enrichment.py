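"""Over-representation and GSEA between the ICI score groups.

Finding to check: a gene set built from the hot-subtype markers is
over-represented among side-A signature genes and positively enriched
(GSEA) in the high-vs-low moderated-t ranking, while a random set is not.
"""

import numpy as np
import pandas as pd
from common import SEED, get_cohort, outdir

from icikit.de import moderated_t
from icikit.enrichment import gsea, hypergeom_enrich, write_gmt
from icikit.io_core import standardize_single
from icikit.pipeline import run_scoring_pipeline


def main():
    out = outdir("enrichment")
    c = get_cohort()
    res = run_scoring_pipeline(
        c.expression, c.clinical, c.signature, reps=200,
        orient_markers=c.hot_markers, seed=SEED,
    )
    std = standardize_single(c.expression)
    rng = np.random.default_rng(SEED)
    sets = {
        "hot_markers": [g for g in c.hot_markers if g in std.gene_ids],
        "random_set": list(rng.choice(std.gene_ids, 20, replace=False)),
    }
    write_gmt(sets, out / "gene_sets.gmt")

    ora = hypergeom_enrich(res.genes_A, std.gene_ids, sets)
    ora.to_csv(out / "ora.tsv", sep="\t")

    ranking = moderated_t(std, (res.group == "high").astype(int))["t_stat"]
    rows = []
    for name, genes in sets.items():
        es, nes, p = gsea(ranking, genes, n_perm=1000, seed=SEED)
        rows.append({"set_id": name, "es": es, "nes": nes, "perm_p": p})
    gsea_df = pd.DataFrame(rows).set_index("set_id")
    gsea_df.to_csv(out / "gsea.tsv", sep="\t")

    print("over-representation of signature side A:\n", ora.round(4).to_string())
    print("GSEA on high-vs-low ranking:\n", gsea_df.round(4).to_string())
    print(f"wrote {out}/ora.tsv, gsea.tsv, gene_sets.gmt")


if __name__ == "__main__":
    main()
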