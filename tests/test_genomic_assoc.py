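"""Interval-overlap statistics: overlap fraction, MC association, partitions, depletion."""

import numpy as np
import pytest
from scipy import stats

from transgen_nhg.genomic_assoc import (
    AssocConfig,
    ChromPartition,
    arm_center_enrichment,
    chrom_depletion_test,
    ltr_association,
    mc_overlap_test,
    overlap_fraction,
)
from transgen_nhg.io_formats import GeneModel, IntervalSet

SIZES = {"chr1": 1_000_000}


def _iv(records, sizes=SIZES):
    return IntervalSet.from_records(records, sizes)


class TestOverlapFraction:
    def test_self_overlap_is_one(self):
        q = _iv([("chr1", 100, 200), ("chr1", 5000, 5100)])
        assert overlap_fraction(q, q) == 1.0

    def test_flank_definition_at_one_bp_gap(self):
        annot = _iv([("chr1", 1000, 2000)])
        query = _iv([("chr1", 998, 999)])  # 1 bp left of the interval
        assert overlap_fraction(query, annot, flank_bp=0) == 0.0
        assert overlap_fraction(query, annot, flank_bp=500) == 1.0

    def test_matches_quadratic_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(25):
            annot_rec = [
                ("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 990_000, 5), rng.integers(100, 5000, 5))
            ]
            query_rec = [
                ("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 990_000, 20), rng.integers(100, 5000, 20))
            ]
            flank = int(rng.choice([0, 500, 1000]))
            got = overlap_fraction(_iv(query_rec), _iv(annot_rec), flank)
            want = np.mean(
                [
                    any(
                        qs < min(ae + flank, 1_000_000) and qe > max(as_ - flank, 0)
                        for (_, as_, ae) in annot_rec
                    )
                    for (_, qs, qe) in query_rec
                ]
            )
            assert got == pytest.approx(want)

    def test_monotone_in_flank(self):
        rng = np.random.default_rng(4)
        annot = _iv([("chr1", int(s), int(s) + 300) for s in rng.integers(0, 990_000, 10)])
        query = _iv([("chr1", int(s), int(s) + 2000) for s in rng.integers(0, 990_000, 30)])
        fs = [overlap_fraction(query, annot, f) for f in (0, 500, 1000, 5000)]
        assert fs == sorted(fs)

    def test_empty_query_rejected(self):
        annot = _iv([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(_iv([]), annot)


class TestMcOverlapTest:
    def test_saturated_annotation_forces_p_one(self):
        annot = _iv([("chr1", 0, 1_000_000)])
        res = mc_overlap_test(1.0, 10, annot, SIZES, AssocConfig(n_sims=200, seed=1))
        assert np.all(res.null_f == 1.0)
        assert res.p_empirical == 1.0

    def test_toy_genome_significant_association(self):
        # one 10 kb block in 1 Mb; P(random 2.92 kb region hits it) ~ 1.3%,
        # so ten out of ten hits is far beyond the null
        annot = _iv([("chr1", 500_000, 510_000)])
        res = mc_overlap_test(1.0, 10, annot, SIZES, AssocConfig(n_sims=10_000, seed=2))
        assert res.p_empirical <= 0.001

    def test_invariant_to_annotation_order_and_merging(self):
        recs = [("chr1", 1000, 3000), ("chr1", 2500, 4000), ("chr1", 800_000, 801_000)]
        merged = [("chr1", 1000, 4000), ("chr1", 800_000, 801_000)]
        cfg = AssocConfig(n_sims=2000, seed=3)
        p1 = mc_overlap_test(0.4, 25, _iv(recs), SIZES, cfg).null_f
        p2 = mc_overlap_test(0.4, 25, _iv(list(reversed(recs))), SIZES, cfg).null_f
        p3 = mc_overlap_test(0.4, 25, _iv(merged), SIZES, cfg).null_f
        assert np.array_equal(p1, p2) and np.array_equal(p1, p3)

    def test_empty_annotation_warns_and_p_one(self):
        with pytest.warns(UserWarning, match="empty"):
            res = mc_overlap_test(0.5, 10, _iv([]), SIZES, AssocConfig(n_sims=50, seed=0))
        assert res.p_empirical == 1.0

    def test_seeded_reproducibility(self):
        annot = _iv([("chr1", 1000, 5000)])
        cfg = AssocConfig(n_sims=500, seed=42)
        r1 = mc_overlap_test(0.2, 10, annot, SIZES, cfg)
        r2 = mc_overlap_test(0.2, 10, annot, SIZES, cfg)
        assert np.array_equal(r1.null_f, r2.null_f)

    def test_planted_ltr_linkage_detected(self, exp7):
        """NHG-family genes placed near planted LTRs associate significantly."""
        truth = exp7.truth.truth_sets()
        genes = {g.gene_id: g for g in exp7.genes}
        hs = [genes[i] for i in truth["high_stringent_nhg"]]
        query = IntervalSet.from_records(
            [(g.chrom, g.start, g.end, g.gene_id) for g in hs], exp7.chrom_sizes
        )
        res = ltr_association(
            query, exp7.ltr, exp7.chrom_sizes, AssocConfig(n_sims=10_000, seed=5)
        )
        assert res.p_empirical < 0.01


class TestChromPartition:
    sizes = {"chrA": 1000, "chrX": 600}

    def test_regions_tile_each_chromosome(self):
        part = ChromPartition(self.sizes)
        for chrom, size in self.sizes.items():
            regions = part.regions[chrom]
            assert regions[0][1] == 0 and regions[-1][2] == size
            for (_, _, e1), (_, s2, _) in zip(regions, regions[1:]):
                assert e1 == s2

    def test_x_split_at_one_sixth(self):
        part = ChromPartition(self.sizes)
        assert part.regions["chrX"][0][2] == 100

    def test_boundary_is_half_open_toward_start(self):
        part = ChromPartition(self.sizes)
        # position exactly at the 1/4 boundary belongs to the center
        assert part.assign("chrA", 250) == "center"
        assert part.assign("chrA", 249) == "left_arm"


def _toy_universe(rng, n=600, n_chrom=3, size=900_000):
    sizes = {f"chr{i}": size for i in range(n_chrom)}
    genes = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(n_chrom))}"
        start = int(rng.integers(0, size - 3000))
        genes.append(GeneModel(f"g{i}", chrom, start, start + 2000, "+", 1500))
    return sizes, genes


class TestArmCenterEnrichment:
    def test_uniform_draws_rarely_significant(self):
        rng = np.random.default_rng(21)
        sizes, genes = _toy_universe(rng)
        part = ChromPartition(sizes, x_chrom="chr2")
        hits = 0
        for _ in range(100):
            pick = {g.gene_id for g in rng.choice(genes, size=80, replace=False)}
            df = arm_center_enrichment(pick, genes, part)
            if (df.groupby("chrom")["p"].first() < 0.05).any():
                hits += 1
        assert hits <= 25  # ~3 chromosome tests per draw at alpha 0.05

    def test_midpoint_placement_all_center(self):
        sizes = {"chrA": 1000}
        center_genes = [GeneModel(f"g{i}", "chrA", 480, 520, "+", 30) for i in range(5)]
        arm_genes = [GeneModel("a1", "chrA", 10, 60, "+", 30),
                     GeneModel("a2", "chrA", 900, 950, "+", 30)]
        part = ChromPartition(sizes, x_chrom="none")
        df = arm_center_enrichment(
            {g.gene_id for g in center_genes}, center_genes + arm_genes, part
        )
        center = df[df.region == "center"].iloc[0]
        assert center.observed == 5
        assert df[df.region != "center"]["observed"].sum() == 0


class TestChromDepletion:
    def test_identity_set_has_fold_one(self):
        rng = np.random.default_rng(31)
        _, genes = _toy_universe(rng)
        fold, p = chrom_depletion_test({g.gene_id for g in genes}, genes, "chr0")
        assert fold == pytest.approx(1.0)
        assert p >= 0.5

    def test_autosome_only_set_is_depleted(self):
        rng = np.random.default_rng(32)
        _, genes = _toy_universe(rng)
        off = [g.gene_id for g in genes if g.chrom != "chr0"]
        pick = set(rng.choice(off, size=100, replace=False))
        fold, p = chrom_depletion_test(pick, genes, "chr0", n_sims=10_000, seed=1)
        assert fold == float("inf") or fold >= 5
        assert p < 0.01

    def test_zero_observed_matches_hypergeometric(self):
        rng = np.random.default_rng(33)
        _, genes = _toy_universe(rng)
        off = [g.gene_id for g in genes if g.chrom != "chr0"]
        pick = set(rng.choice(off, size=40, replace=False))
        fold, p = chrom_depletion_test(pick, genes, "chr0", n_sims=50_000, seed=2)
        n_chrom = sum(1 for g in genes if g.chrom == "chr0")
        exact = stats.hypergeom.cdf(0, len(genes), n_chrom, 40)
        assert fold == float("inf")
        assert p == pytest.approx(exact, abs=4 * np.sqrt(exact / 50_000) + 1e-4)

    @pytest.mark.parametrize("n_sims", [2_000, 20_000, 200_000])
    def test_mc_converges_to_hypergeometric_tail(self, n_sims):
        rng = np.random.default_rng(34)
        _, genes = _toy_universe(rng)
        mostly_off = [g.gene_id for g in genes if g.chrom != "chr0"][:90]
        some_on = [g.gene_id for g in genes if g.chrom == "chr0"][:10]
        pick = set(mostly_off) | set(some_on)
        _, p = chrom_depletion_test(pick, genes, "chr0", n_sims=n_sims, seed=3)
        n_chrom = sum(1 for g in genes if g.chrom == "chr0")
        exact = stats.hypergeom.cdf(10, len(genes), n_chrom, 100)
        se = np.sqrt(exact * (1 - exact) / n_sims)
        assert p == pytest.approx(exact, abs=4 * se + 1e-9)

    def test_absent_chromosome_rejected(self):
        rng = np.random.default_rng(35)
        _, genes = _toy_universe(rng)
        with pytest.raises(ValueError, match="absent"):
            chrom_depletion_test({genes[0].gene_id}, genes, "chrZ")
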