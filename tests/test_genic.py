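"""Boundary expansion, classification, k-sweep, ranking, baseline, flags."""

import numpy as np
import pytest

from prs_architect import (
    GeneRecord,
    Predictor,
    PredictorSNP,
    ValidationError,
    build_index,
    classify_snps,
    flag_genes,
    random_baseline,
    rank_genes,
    subset_variance_fraction,
    sweep,
)
from prs_architect.genic import snp_gene_distances

from conftest import brute_genic_membership, random_genes, random_predictor


def snp(snp_id, pos, beta=0.5, maf=0.25, chrom="chr1"):
    return PredictorSNP(snp_id, chrom, pos, beta, maf)


class TestBuildIndex:
    def test_expansion_arithmetic(self):
        g = GeneRecord("g", "g", "chr1", 1000, 2000)
        idx = build_index([g], 0.5)
        assert idx.query("chr1", 500) == {"g"}
        assert idx.query("chr1", 499) == set()
        assert idx.query("chr1", 2500) == {"g"}
        assert idx.query("chr1", 2501) == set()

    def test_clipping_at_position_one(self):
        g = GeneRecord("g", "g", "chr1", 300, 900)
        idx = build_index([g], 1.0)
        assert idx.query("chr1", 1) == {"g"}
        assert idx.query("chr1", 1900) == {"g"}
        assert idx.query("chr1", 1901) == set()

    def test_k_zero_is_raw_gene_body(self):
        g = GeneRecord("g", "g", "chr1", 1000, 2000)
        idx = build_index([g], 0.0)
        assert idx.query("chr1", 1000) == {"g"}
        assert idx.query("chr1", 999) == set()
        assert idx.query("chr1", 2000) == {"g"}
        assert idx.query("chr1", 2001) == set()

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            build_index([GeneRecord("g", "g", "chr1", 10, 20)], -1.0)


class TestClassify:
    def test_inclusive_at_expanded_boundaries(self):
        g = GeneRecord("g", "g", "chr1", 10_000, 20_000)
        p = Predictor("b", [snp("lo", 9_000), snp("below", 8_999), snp("hi", 21_000)])
        sets = classify_snps(p, build_index([g], 1.0))
        assert sets == [{"g"}, set(), {"g"}]

    def test_multi_gene_membership(self):
        genes = [
            GeneRecord("g1", "g1", "chr1", 1000, 5000),
            GeneRecord("g2", "g2", "chr1", 4000, 9000),
        ]
        p = Predictor("m", [snp("s", 4500)])
        assert classify_snps(p, build_index(genes, 0.0)) == [{"g1", "g2"}]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = random_genes(rng, n=40)
        p = random_predictor(rng, n=120)
        k = float(rng.choice([0.0, 0.5, 3.0, 30.0]))
        idx = build_index(genes, k)
        for s, got in zip(p.snps, classify_snps(p, idx)):
            assert got == brute_genic_membership(s, genes, k)

    @pytest.mark.parametrize("seed", range(8))
    def test_distance_thresholding_equals_index_membership(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes = random_genes(rng, n=30)
        p = random_predictor(rng, n=80)
        dist = snp_gene_distances(p, genes)
        for k in (0.0, 1.5, 12.0):
            idx = build_index(genes, k)
            genic = [len(g) > 0 for g in classify_snps(p, idx)]
            assert list(dist <= 1000 * k) == genic


class TestSweep:
    def test_flat_zero_when_all_intergenic(self):
        genes = [GeneRecord("g", "g", "chr9", 1, 100)]
        p = Predictor("far", [snp("a", 1_000_000), snp("b", 2_000_000)])
        res = sweep(p, genes, [0.0, 15.0, 30.0])
        assert np.all(res.count_fraction == 0.0)
        assert np.all(res.variance_fraction == 0.0)

    def test_recovers_planted_fraction_at_k0(self, small_genome, planted_predictor):
        pred, truth = planted_predictor
        res = sweep(pred, small_genome, [0.0])
        assert res.count_fraction[0] == truth.genic_count_fraction == 0.55
        assert res.variance_fraction[0] == pytest.approx(
            truth.genic_variance_fraction, abs=1e-12
        )

    def test_jump_at_distance_of_high_variance_snp(self):
        # one big-variance SNP 17.5 kbp from a gene end: the variance series
        # must jump by exactly that SNP's variance fraction at k = 17.5
        gene = GeneRecord("g", "g", "chr1", 100_000, 150_000)
        inside = snp("in", 120_000, beta=0.1, maf=0.2)
        outlier = snp("out", 167_500, beta=2.0, maf=0.4)
        p = Predictor("jump", [inside, outlier])
        grid = np.arange(0.0, 30.5, 0.5)
        res = sweep(p, [gene], grid)
        jump_at = grid[np.flatnonzero(np.diff(res.variance_fraction)) + 1]
        assert list(jump_at) == [17.5]
        expected = subset_variance_fraction(p, ["out"])
        i = list(grid).index(17.5)
        assert res.variance_fraction[i] - res.variance_fraction[i - 1] == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_both_series_non_decreasing(self, seed):
        rng = np.random.default_rng(200 + seed)
        genes = random_genes(rng, n=25)
        p = random_predictor(rng, n=60)
        res = sweep(p, genes, np.arange(0.0, 30.5, 0.5))
        assert np.all(np.diff(res.count_fraction) >= 0)
        assert np.all(np.diff(res.variance_fraction) >= 0)
        assert np.all((0 <= res.count_fraction) & (res.count_fraction <= 1))

    def test_unsorted_grid_rejected(self, small_genome, planted_predictor):
        with pytest.raises(ValidationError):
            sweep(planted_predictor[0], small_genome, [1.0, 0.5])

    def test_genic_plus_nongenic_variance_is_total(self, small_genome, planted_predictor):
        pred, _ = planted_predictor
        res = sweep(pred, small_genome, [7.5])
        idx = build_index(small_genome, 7.5)
        genic_ids = [
            s.snp_id for s, g in zip(pred.snps, classify_snps(pred, idx)) if g
        ]
        nongenic_ids = [i for i in pred.snp_ids if i not in set(genic_ids)]
        assert subset_variance_fraction(pred, genic_ids) + subset_variance_fraction(
            pred, nongenic_ids
        ) == pytest.approx(1.0, abs=1e-12)
        assert res.variance_fraction[0] == pytest.approx(
            subset_variance_fraction(pred, genic_ids), abs=1e-12
        )


class TestRankGenes:
    def test_single_gene_tops_ranking_with_hand_fraction(self):
        gene = GeneRecord("g", "g", "chr1", 1000, 2000)
        p = Predictor(
            "r",
            [
                snp("in", 1500, beta=1.0, maf=0.5),     # variance 0.5
                snp("out", 500_000, beta=1.0, maf=0.1),  # 0.18
                snp("out2", 800_000, beta=2.0, maf=0.25),  # 2*4*0.75*0.25 = 1.5
            ],
        )
        ranking = rank_genes(p, [gene], k=0.0)
        assert len(ranking.groups) == 1
        grp = ranking.groups[0]
        assert grp.gene_ids == ("g",)
        assert grp.variance_fraction == pytest.approx(0.5 / (0.5 + 0.18 + 1.5))

    def test_overlapping_genes_grouped_with_equal_fraction(self):
        genes = [
            GeneRecord("gA", "gA", "chr1", 1000, 9000),
            GeneRecord("gB", "gB", "chr1", 2000, 8000),
        ]
        p = Predictor("r", [snp("s", 5000), snp("far", 900_000)])
        ranking = rank_genes(p, genes, k=0.0)
        assert len(ranking.groups) == 1
        assert ranking.groups[0].gene_ids == ("gA", "gB")

    def test_no_genic_snps_gives_empty_ranking(self):
        genes = [GeneRecord("g", "g", "chr1", 10, 20)]
        p = Predictor("r", [snp("s", 700_000)])
        assert rank_genes(p, genes, k=0.0).groups == []

    def test_top_n_counts_distinct_values_not_genes(self):
        # two disjoint gene pairs sharing SNP sets -> 2 distinct values, 4 genes
        genes = [
            GeneRecord("a1", "a1", "chr1", 1000, 9000),
            GeneRecord("a2", "a2", "chr1", 1500, 8000),
            GeneRecord("b1", "b1", "chr1", 500_000, 509_000),
            GeneRecord("b2", "b2", "chr1", 500_500, 508_000),
        ]
        p = Predictor(
            "r", [snp("x", 5000, beta=1.0), snp("y", 505_000, beta=0.5)]
        )
        ranking = rank_genes(p, genes, k=0.0, top_n=2)
        assert len(ranking.groups) == 2
        assert sum(len(g.gene_ids) for g in ranking.groups) == 4
        fractions = [g.variance_fraction for g in ranking.groups]
        assert fractions == sorted(fractions, reverse=True)

    def test_gene_fraction_equals_subset_variance_of_its_snps(
        self, small_genome, planted_predictor
    ):
        pred, _ = planted_predictor
        ranking = rank_genes(pred, small_genome, k=30.0, top_n=5)
        assert ranking.groups
        for grp in ranking.groups[:3]:
            assert grp.variance_fraction == pytest.approx(
                subset_variance_fraction(pred, grp.snp_ids), abs=1e-12
            )


class TestRandomBaseline:
    def test_exhaustive_sample_reproduces_manifest_sweep(self, small_genome):
        rng = np.random.default_rng(5)
        manifest = random_predictor(rng, n=80)
        grid = [0.0, 10.0, 30.0]
        df = random_baseline(manifest, len(manifest), small_genome, grid, reps=3, seed=1)
        own = sweep(manifest, small_genome, grid)
        assert np.allclose(df["mean_count_fraction"], own.count_fraction)
        assert np.allclose(df["std_count_fraction"], 0.0)

    def test_mean_tracks_manifest_fraction(self, small_genome, planted_predictor):
        pred, truth = planted_predictor
        df = random_baseline(pred, 100, small_genome, [0.0], reps=200, seed=2)
        mean = df["mean_count_fraction"].iloc[0]
        # hypergeometric: SE of the mean over 200 draws of 100 from 400
        se = np.sqrt(0.55 * 0.45 / 100) / np.sqrt(200)
        assert abs(mean - 0.55) < 5 * se

    def test_deterministic_given_seed(self, small_genome, planted_predictor):
        pred, _ = planted_predictor
        a = random_baseline(pred, 50, small_genome, [0.0, 5.0], reps=4, seed=9)
        b = random_baseline(pred, 50, small_genome, [0.0, 5.0], reps=4, seed=9)
        assert a.equals(b)

    def test_oversized_sample_rejected(self, small_genome, planted_predictor):
        with pytest.raises(ValidationError):
            random_baseline(planted_predictor[0], 10_000, small_genome, [0.0], reps=1)


class TestFlagGenes:
    def test_empty_flag_set(self, small_genome, planted_predictor):
        ranking = rank_genes(planted_predictor[0], small_genome, k=30.0, top_n=5)
        _, summary = flag_genes(ranking, set())
        assert summary.flagged_gene_count == 0
        assert summary.flagged_variance_fraction == 0.0

    def test_flagging_top_gene(self, small_genome, planted_predictor):
        ranking = rank_genes(planted_predictor[0], small_genome, k=30.0, top_n=5)
        top = ranking.groups[0]
        flagged, summary = flag_genes(ranking, {top.gene_ids[0]})
        assert summary.flagged_gene_count == 1
        assert summary.flagged_variance_fraction == pytest.approx(
            top.variance_fraction
        )
        assert flagged.groups[0].flagged[0] is True

    @pytest.mark.parametrize("seed", range(5))
    def test_count_equals_set_intersection(self, small_genome, planted_predictor, seed):
        rng = np.random.default_rng(seed)
        ranking = rank_genes(planted_predictor[0], small_genome, k=30.0, top_n=10)
        all_ids = [gid for grp in ranking.groups for gid in grp.gene_ids]
        universe = all_ids + [f"ABSENT{i}" for i in range(10)]
        flags = set(rng.choice(universe, size=8, replace=False))
        _, summary = flag_genes(ranking, flags)
        assert summary.flagged_gene_count == len(flags & set(all_ids))
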