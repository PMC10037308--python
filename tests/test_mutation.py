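import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icikit.io_core import MAFTable
from icikit.mutation import (
    compute_tmb,
    mutated_gene_table,
    tmb_ici_strata,
    tmb_score_association,
    yates_chisq,
)
from icikit.synthetic import simulate_cohort, simulate_maf

from conftest import make_clinical

# Published contingency rows (gene -> high_mut, low_mut) for a cohort of
# 69 high-score and 217 low-score samples with mutation data.
PUBLISHED_ROWS = {
    "CHD6": (10, 7, 0.001602),
    "BIRC6": (9, 7, 0.005265),
    "MXRA5": (8, 7, 0.016122),
    "PCLO": (12, 15, 0.018435),
    "KMT2C": (20, 35, 0.02889),
    "DNAH9": (8, 9, 0.046975),
}
N_HIGH, N_LOW = 69, 217


def maf_from_counts(rows: dict) -> tuple[MAFTable, pd.Series]:
    """Encode per-gene high/low mutated-sample counts as a MAF fixture."""
    high = [f"H{i:03d}" for i in range(N_HIGH)]
    low = [f"L{i:03d}" for i in range(N_LOW)]
    recs = []
    for gene, (h_mut, l_mut, _) in rows.items():
        recs += [(s, gene, "Missense_Mutation") for s in high[:h_mut]]
        recs += [(s, gene, "Missense_Mutation") for s in low[:l_mut]]
    # ensure every sample appears so group sizes are taken from the labels
    groups = pd.Series(
        ["high"] * N_HIGH + ["low"] * N_LOW, index=high + low, name="group"
    )
    maf = MAFTable(
        pd.DataFrame(recs, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"])
    )
    return maf, groups


class TestComputeTmb:
    def test_silent_records_not_counted(self):
        recs = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["S1"] * 4,
                "Hugo_Symbol": ["A", "B", "C", "D"],
                "Variant_Classification": [
                    "Missense_Mutation",
                    "Missense_Mutation",
                    "Missense_Mutation",
                    "Silent",
                ],
            }
        )
        tmb = compute_tmb(MAFTable(recs), ["S1"])
        assert tmb["S1"] == 3

    def test_absent_sample_gets_zero(self):
        recs = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["S1"],
                "Hugo_Symbol": ["A"],
                "Variant_Classification": ["Missense_Mutation"],
            }
        )
        tmb = compute_tmb(MAFTable(recs), ["S1", "S2"])
        assert tmb["S2"] == 0

    def test_poisson_mean_recovered(self):
        c = simulate_cohort(n_samples=300, n_genes=50, seed=31)
        score = pd.Series(
            np.random.default_rng(31).normal(size=300), index=c.expression.sample_ids
        )
        maf = simulate_maf(c, score, tmb_slope=0.0, n_biased_genes=0, seed=31)
        tmb = compute_tmb(maf, c.expression.sample_ids)
        assert abs(tmb.mean() - 10.0) < 0.6


class TestYatesChisq:
    @pytest.mark.parametrize(
        "gene,h_mut,l_mut,p_expected", [(g, *v) for g, v in PUBLISHED_ROWS.items()]
    )
    def test_published_contingency_pvalues(self, gene, h_mut, l_mut, p_expected):
        table = [[N_HIGH - h_mut, h_mut], [N_LOW - l_mut, l_mut]]
        _, p = yates_chisq(table)
        assert float(f"{p:.4g}") == pytest.approx(p_expected, rel=1e-3)

    def test_independence_gives_chi2_zero(self):
        chi2, p = yates_chisq([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_small_tables_track_fisher_exact(self, rng):
        # exhaustive scan of all 2x2 tables with cells in 1..15 puts the
        # worst Yates/Fisher p ratio at 8.37, so a 10x band is the honest
        # agreement bound for the corrected chi-square at these counts
        for _ in range(50):
            t = rng.integers(1, 16, size=(2, 2))
            _, p_yates = yates_chisq(t)
            p_fisher = stats.fisher_exact(t)[1]
            assert p_fisher / 10 <= p_yates <= 10 * p_fisher

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chisq([[0, 0], [5, 3]])


class TestMutatedGeneTable:
    def test_published_counts_reconstructed(self):
        maf, groups = maf_from_counts(PUBLISHED_ROWS)
        table = mutated_gene_table(maf, groups, top_n=20)
        chd6 = table.loc["CHD6"]
        assert (chd6["high_wild"], chd6["high_mut"]) == (59, 10)
        assert (chd6["low_wild"], chd6["low_mut"]) == (210, 7)
        assert chd6["high_mut_pct"] == pytest.approx(14.49, abs=0.005)
        for gene, (_, _, p_exp) in PUBLISHED_ROWS.items():
            assert float(f"{table.loc[gene, 'p']:.4g}") == pytest.approx(p_exp, rel=1e-3)
        # group sizes constant across genes
        assert (table["high_wild"] + table["high_mut"] == N_HIGH).all()
        assert (table["low_wild"] + table["low_mut"] == N_LOW).all()

    def test_gene_mutated_everywhere_gets_p_one(self):
        samples = [f"S{i}" for i in range(20)]
        recs = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": samples,
                "Hugo_Symbol": ["UBIQ"] * 20,
                "Variant_Classification": ["Missense_Mutation"] * 20,
            }
        )
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=samples)
        table = mutated_gene_table(MAFTable(recs), groups)
        assert table.loc["UBIQ", "p"] == 1.0
        assert table.loc["UBIQ", "chi2"] == 0.0

    def test_planted_biased_gene_ranks_first(self):
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            c = simulate_cohort(n_samples=300, n_genes=50, seed=seed)
            score = pd.Series(
                np.random.default_rng(seed).normal(size=300), index=c.expression.sample_ids
            )
            maf = simulate_maf(
                c, score, tmb_slope=0.0, n_biased_genes=1, biased_odds=5.0, seed=seed
            )
            groups = pd.Series(
                np.where(score > score.median(), "high", "low"), index=score.index
            )
            table = mutated_gene_table(maf, groups, top_n=20)
            hits += table.index[0] == "MUT000"
        assert hits >= 0.9 * n_rep


class TestTmbScoreAssociation:
    def test_perfect_monotone_pair(self):
        x = pd.Series(np.arange(20, dtype=float), index=[f"s{i}" for i in range(20)])
        rho, _ = tmb_score_association(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_rank_invariance(self, rng):
        idx = [f"s{i}" for i in range(50)]
        x = pd.Series(rng.poisson(10, 50).astype(float), index=idx)
        y = pd.Series(rng.normal(size=50), index=idx)
        rho1, _ = tmb_score_association(x, y)
        rho2, _ = tmb_score_association(
            pd.Series(stats.rankdata(x), index=idx), pd.Series(stats.rankdata(y), index=idx)
        )
        assert rho1 == pytest.approx(rho2)

    def test_constant_input_rejected(self):
        idx = [f"s{i}" for i in range(12)]
        with pytest.raises(ValueError, match="constant"):
            tmb_score_association(
                pd.Series(5.0, index=idx), pd.Series(np.arange(12.0), index=idx)
            )


class TestTmbIciStrata:
    def test_four_strata_logrank(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(n)]
        tmb = pd.Series(rng.poisson(10, n).astype(float), index=idx)
        grp = pd.Series(rng.choice(["high", "low"], n), index=idx)
        clin = make_clinical(rng.exponential(500, n), rng.integers(0, 2, n), index=idx)
        strata, (chi2, df, p) = tmb_ici_strata(tmb, grp, clin)
        assert strata.nunique() == 4
        assert df == 3
        assert 0 <= p <= 1

    def test_equal_tmb_collapses_strata(self, rng):
        n = 40
        idx = [f"s{i}" for i in range(n)]
        tmb = pd.Series(5.0, index=idx)
        grp = pd.Series(["high"] * 20 + ["low"] * 20, index=idx)
        clin = make_clinical(rng.exponential(500, n), np.ones(n), index=idx)
        strata, (_, df, _) = tmb_ici_strata(tmb, grp, clin)
        assert strata.nunique() == 2
        assert df == 1

    def test_planted_double_gradient_orders_strata(self):
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            n = 400
            idx = [f"s{i}" for i in range(n)]
            ici = pd.Series(r.choice(["high", "low"], n), index=idx)
            tmb = pd.Series(
                r.poisson(np.where(ici == "high", 14, 7)).astype(float), index=idx
            )
            hr = np.where(ici == "high", 0.5, 1.0) * np.where(
                tmb > tmb.median(), 0.5, 1.0
            )
            t = r.exponential(1 / (0.002 * hr))
            clin = make_clinical(t, np.ones(n), index=idx)
            strata, _ = tmb_ici_strata(tmb, ici, clin)
            med = {}
            from icikit.survival import km_curve

            for s in strata.unique():
                mask = (strata == s).to_numpy()
                med[s] = km_curve(clin.times[mask], clin.events[mask]).median_survival
            best = "TMB-high/high-ICI"
            worst = "TMB-low/low-ICI"
            if best in med and worst in med:
                hits += med[best] > med[worst]
        assert hits >= 0.8 * n_rep
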