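"""PRS harmonization, the interaction scan, gene mapping and gene-level
tests, competitive gene-set enrichment with BH-FDR, and the risk-by-diet
grid."""

import numpy as np
import pandas as pd
import pytest

from nutrigen.association import standardize, tertile_groups
from nutrigen.genetics import (InteractionRecord, bh_fdr, compute_prs,
                               filter_hits, gene_set_test, gene_test,
                               interaction_lrt, interaction_scan,
                               map_snps_to_genes, risk_by_diet_grid,
                               GeneResult)


def make_geno(rng, n, snps, mafs=None):
    ids = [f"rs{j}" for j in range(snps)] if isinstance(snps, int) else snps
    mafs = mafs if mafs is not None else np.full(len(ids), 0.3)
    d = rng.binomial(2, mafs[None, :], size=(n, len(ids))).astype(float)
    dosages = pd.DataFrame(d, columns=ids)
    info = pd.DataFrame({"snp": ids, "chrom": "1",
                         "pos": 1000 * (np.arange(len(ids)) + 1),
                         "a1": "A", "a2": "G"}).set_index("snp")
    return dosages, info


class TestPrs:
    def test_zero_dosages_give_zero(self, rng):
        dosages, info = make_geno(rng, 5, 3)
        dosages[:] = 0.0
        w = pd.DataFrame({"snp": dosages.columns, "effect_allele": "A",
                          "beta": [0.5, -0.2, 0.1]})
        prs, _ = compute_prs(dosages, w, info)
        np.testing.assert_allclose(prs, 0.0)

    def test_single_snp_beta_half_dosage_two_gives_one(self, rng):
        dosages, info = make_geno(rng, 1, 1)
        dosages.iloc[0, 0] = 2.0
        w = pd.DataFrame({"snp": ["rs0"], "effect_allele": ["A"],
                          "beta": [0.5]})
        prs, meta = compute_prs(dosages, w, info)
        assert prs.iloc[0] == 1.0
        assert meta["n_used"] == 1

    def test_matches_brute_force_sum(self, rng):
        dosages, info = make_geno(rng, 50, 6)
        w = pd.DataFrame({"snp": dosages.columns, "effect_allele": "A",
                          "beta": rng.normal(size=6)})
        prs, _ = compute_prs(dosages, w, info)
        brute = np.array([sum(w["beta"][j] * dosages.iloc[i, j]
                              for j in range(6)) for i in range(50)])
        np.testing.assert_allclose(prs, brute, atol=1e-12)

    def test_snp_reorder_invariance(self, rng):
        dosages, info = make_geno(rng, 40, 5)
        w = pd.DataFrame({"snp": dosages.columns, "effect_allele": "A",
                          "beta": rng.normal(size=5)})
        p1, _ = compute_prs(dosages, w, info)
        p2, _ = compute_prs(dosages, w.iloc[::-1], info)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_allele_flip_round_trip(self, rng):
        dosages, info = make_geno(rng, 40, 3)
        w = pd.DataFrame({"snp": dosages.columns, "effect_allele": "A",
                          "beta": [0.3, -0.4, 0.2]})
        p1, _ = compute_prs(dosages, w, info)
        # swap counted/other allele AND flip dosage: same genotype, same PRS
        info2 = info.copy()
        info2[["a1", "a2"]] = info[["a2", "a1"]].to_numpy()
        p2, meta = compute_prs(2.0 - dosages, w, info2)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert meta["n_flipped"] == 3

    def test_unmatched_allele_excluded_with_warning(self, rng):
        dosages, info = make_geno(rng, 10, 2)
        w = pd.DataFrame({"snp": dosages.columns, "effect_allele": ["A", "T"],
                          "beta": [0.5, 9.9]})
        with pytest.warns(UserWarning, match="excluded"):
            prs, meta = compute_prs(dosages, w, info)
        assert meta["n_excluded"] == 1


class TestInteractionScan:
    def test_zero_dosage_column_skipped_not_crashed(self, rng):
        dosages, info = make_geno(rng, 100, 2)
        dosages.iloc[:, 1] = 0.0
        y = rng.binomial(1, 0.4, 100)
        z = standardize(rng.normal(size=100))
        recs = interaction_scan(y, dosages, z, snp_info=info)
        assert not recs[0].skipped
        assert recs[1].skipped and "monomorphic" in recs[1].reason

    def test_low_maf_skipped_with_reason(self, rng):
        dosages, info = make_geno(rng, 400, 1)
        dosages.iloc[:, 0] = 0.0
        dosages.iloc[:4, 0] = 1.0  # in-sample maf 0.005
        y = rng.binomial(1, 0.4, 400)
        recs = interaction_scan(y, dosages, standardize(rng.normal(size=400)))
        assert recs[0].skipped and "maf" in recs[0].reason

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(5)
        n = 4000
        dosages, info = make_geno(rng, n, 1)
        z = standardize(rng.normal(size=n))
        d = dosages.iloc[:, 0].to_numpy()
        eta = -1.1 + 0.3 * d * z
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        rec = interaction_scan(y, dosages, z, snp_info=info)[0]
        assert rec.pvalue < 0.001
        assert rec.beta == pytest.approx(0.3, abs=3 * rec.se)

    def test_filter_hits_boundaries_and_manual_count(self, rng):
        recs = [InteractionRecord(f"rs{i}", "1", i, 0.0, 1.0, p)
                for i, p in enumerate([0.001, 0.02, 0.2, 0.9])]
        recs.append(InteractionRecord("rs_skip", "1", 9, np.nan, np.nan,
                                      np.nan, skipped=True))
        assert len(filter_hits(recs, 1.0)) == 4  # skipped never included
        assert len(filter_hits(recs, 1e-9)) == 0
        assert [r.snp for r in filter_hits(recs, 0.05)] == ["rs0", "rs1"]


class TestGeneMapping:
    loc = pd.DataFrame({"gene": ["G1", "G2"], "chrom": ["1", "2"],
                        "start": [10_000, 5_000], "end": [20_000, 8_000]})

    def rec(self, snp, chrom, pos):
        return InteractionRecord(snp, chrom, pos, 0.1, 0.05, 0.04)

    def test_snp_inside_gene_body_mapped_at_window_zero(self):
        gmap = map_snps_to_genes([self.rec("rs1", "1", 15_000)], self.loc, 0)
        assert gmap == {"G1": ["rs1"]}

    def test_upstream_snp_needs_window(self):
        r = [self.rec("rs1", "1", 5_000)]  # 5 kb upstream of G1
        assert map_snps_to_genes(r, self.loc, 0) == {}
        assert map_snps_to_genes(r, self.loc, 10) == {"G1": ["rs1"]}

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError, match="chromosome"):
            map_snps_to_genes([self.rec("rs1", "chrUn_gl000220", 1)], self.loc)

    def test_overlap_counts_match_interval_scan_oracle(self, rng):
        genes = pd.DataFrame({
            "gene": [f"G{i}" for i in range(10)],
            "chrom": "1",
            "start": rng.integers(0, 50_000, 10),
        })
        genes["end"] = genes["start"] + rng.integers(1_000, 20_000, 10)
        recs = [self.rec(f"rs{i}", "1", int(p))
                for i, p in enumerate(rng.integers(0, 80_000, 30))]
        gmap = map_snps_to_genes(recs, genes, 0)
        for _, grow in genes.iterrows():
            hits = [r.snp for r in recs
                    if grow["start"] <= r.pos <= grow["end"]]
            assert sorted(gmap.get(grow["gene"], [])) == sorted(hits)


class TestGeneTest:
    def test_single_snp_gene_equals_snp_lrt(self, rng):
        n = 600
        dosages, _ = make_geno(rng, n, 1)
        z = standardize(rng.normal(size=n))
        y = rng.binomial(1, 0.35, n)
        gres = gene_test(y, dosages, z, mode="pc_regression")
        oracle = interaction_lrt(y, dosages.iloc[:, 0], z)
        assert gres.pvalue == pytest.approx(oracle, abs=1e-8)

    def test_duplicated_snp_columns_collapse_to_one_pc(self, rng):
        n = 500
        dosages, _ = make_geno(rng, n, 1)
        dosages["rs_dup"] = dosages.iloc[:, 0]
        z = standardize(rng.normal(size=n))
        y = rng.binomial(1, 0.35, n)
        gres = gene_test(y, dosages, z, mode="pc_regression")
        single = gene_test(y, dosages.iloc[:, [0]], z, mode="pc_regression")
        assert gres.pvalue == pytest.approx(single.pvalue, abs=1e-8)

    def test_p_aggregation_mode_gives_valid_p(self, rng):
        n = 500
        dosages, _ = make_geno(rng, n, 4)
        z = standardize(rng.normal(size=n))
        y = rng.binomial(1, 0.35, n)
        gres = gene_test(y, dosages, z, mode="p_aggregation")
        assert 0 <= gres.pvalue <= 1

    def test_empty_gene_rejected(self, rng):
        z = standardize(rng.normal(size=10))
        with pytest.raises(ValueError):
            gene_test(np.zeros(10, int), pd.DataFrame(index=range(10)), z)


class TestGeneSet:
    def test_bh_stepup_matches_hand_oracle(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        # hand step-up for a second case: p=(.005,.04,.2), m=3 ->
        # q3=.2, q2=min(.04*3/2,.2)=.06, q1=min(.005*3,.06)=.015
        np.testing.assert_allclose(bh_fdr([0.005, 0.04, 0.2]),
                                   [0.015, 0.06, 0.2], atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_collection_rejected(self, rng):
        genes = [GeneResult(f"G{i}", 1, p, "pc_regression")
                 for i, p in enumerate(rng.uniform(size=5))]
        with pytest.raises(ValueError):
            gene_set_test(genes, {})

    def test_unscored_set_dropped_with_warning(self, rng):
        genes = [GeneResult(f"G{i}", 1, p, "pc_regression")
                 for i, p in enumerate(rng.uniform(size=6))]
        sets = {"A": ["G0", "G1"], "B": ["NOT_THERE"]}
        with pytest.warns(UserWarning, match="dropped"):
            res = gene_set_test(genes, sets)
        assert [r.set_id for r in res] == ["A"]

    def test_null_set_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            genes = [GeneResult(f"G{i}", 1, p, "pc")
                     for i, p in enumerate(rng.uniform(size=40))]
            sets = {"S": [f"G{i}" for i in range(10)]}
            pvals.append(gene_set_test(genes, sets)[0].pvalue)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRiskByDietGrid:
    def test_cell_counts_sum_to_n_and_reference_is_one(self, small_cohort):
        c = small_cohort
        prs = pd.Series(np.random.default_rng(3).normal(size=len(c.phenotype)),
                        index=c.phenotype.index, name="prs")
        diet = tertile_groups(c.indicator.sum(axis=1).astype(float))
        grid = risk_by_diet_grid(c.phenotype, prs, diet, c.covariates)
        assert grid["n"].sum() == len(c.phenotype)
        ref = grid[grid["reference"]]
        assert len(ref) == 1 and ref["odds_ratio"].iloc[0] == 1.0

    def test_planted_genetic_risk_gives_monotone_rows(self):
        rng = np.random.default_rng(13)
        n = 6000
        prs = pd.Series(rng.normal(size=n), name="prs")
        diet = tertile_groups(pd.Series(rng.normal(size=n)))
        eta = -1.3 + 1.0 * prs.to_numpy()
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        grid = risk_by_diet_grid(y, prs, diet)
        for dq in ("low", "intermediate"):
            ors = grid[grid["diet"] == dq].set_index("risk")["odds_ratio"]
            assert ors["low"] < ors["intermediate"] < ors["high"]

    def test_null_cis_cover_one(self):
        rng = np.random.default_rng(31)
        cover, total = 0, 0
        for rep in range(25):
            n = 900
            prs = pd.Series(rng.normal(size=n))
            diet = tertile_groups(pd.Series(rng.normal(size=n)))
            y = rng.binomial(1, 0.3, n)
            grid = risk_by_diet_grid(y, prs, diet)
            sub = grid[~grid["reference"] & ~grid["empty"]]
            cover += ((sub["ci_low"] <= 1) & (1 <= sub["ci_high"])).sum()
            total += len(sub)
        assert cover / total == pytest.approx(0.95, abs=3 * np.sqrt(0.05 * 0.95 / total))
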