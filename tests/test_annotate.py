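import math

import numpy as np
import pandas as pd
import pytest

from atacdiff import annotate, diffacc
from atacdiff.intervals import ChromSizes, GenomeInterval, IntervalSet
from atacdiff.io import GeneModel
from atacdiff.peaks import BroadDomain
from atacdiff.tracks import CoverageTrack

from oracles import hypergeom_tail_oracle


@pytest.fixture(scope="module")
def toy_genes():
    # one +-strand and one --strand gene with CDS and introns
    return [
        GeneModel("gA", "chr1", "+", 2_000, 3_000, 2_200, 2_800,
                  [(2_000, 2_300), (2_600, 3_000)]),
        GeneModel("gB", "chr1", "-", 6_000, 7_000, 6_200, 6_800,
                  [(6_000, 6_400), (6_700, 7_000)]),
    ]


SIZES = ChromSizes({"chr1": 10_000})


class TestClassifyRegion:
    def test_tss_is_promoter(self, toy_genes):
        region = GenomeInterval("chr1", 1_950, 2_050)  # straddles gA TSS
        assert annotate.classify_region(region, toy_genes, 100) == "promoter"

    def test_priority_promoter_over_intron(self, toy_genes):
        # overlaps gA promoter window and gB intron via a wide span
        region = GenomeInterval("chr1", 1_950, 6_500)
        assert annotate.classify_region(region, toy_genes, 100) == "promoter"

    def test_distal_intergenic(self, toy_genes):
        region = GenomeInterval("chr1", 9_000, 9_100)
        assert annotate.classify_region(region, toy_genes, 100) \
            == "distal_intergenic"

    def test_utr_strand_logic(self, toy_genes):
        # gA '+': [2000,2200) exonic before CDS is 5'UTR
        region = GenomeInterval("chr1", 2_100, 2_150)
        assert annotate.classify_region(region, toy_genes, 10) == "utr5"
        # gB '-': [6000,6200) exonic before CDS is the 3' end
        region = GenomeInterval("chr1", 6_100, 6_150)
        assert annotate.classify_region(region, toy_genes, 10) == "utr3"
        # coding exon: inside exon (2000,2300) and CDS (2200,2800)
        region = GenomeInterval("chr1", 2_250, 2_290)
        assert annotate.classify_region(region, toy_genes, 10) == "exon"
        # intron of gA
        region = GenomeInterval("chr1", 2_400, 2_500)
        assert annotate.classify_region(region, toy_genes, 10) == "intron"


class TestGenomicDistribution:
    def test_all_promoter(self, toy_genes):
        regions = [GenomeInterval("chr1", 1_990, 2_010),
                   GenomeInterval("chr1", 6_990, 7_010)]
        table = annotate.genomic_distribution(regions, toy_genes, SIZES, 100)
        prom = table.set_index("feature").loc["promoter"]
        assert prom["region_fraction"] == 1.0

    def test_fractions_sum_to_one(self, toy_genes, rng):
        regions = [GenomeInterval("chr1", int(s), int(s) + 100)
                   for s in rng.integers(0, 9_800, 50)]
        table = annotate.genomic_distribution(regions, toy_genes, SIZES, 250)
        assert table["region_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["genome_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_baseline_matches_per_base_oracle(self, toy_genes):
        pw = 100
        table = annotate.genomic_distribution(
            [GenomeInterval("chr1", 0, 10)], toy_genes, SIZES, pw)
        index = annotate.FeatureIndex(toy_genes, pw)
        counts = {c: 0 for c in annotate.FEATURE_CLASSES}
        for base in range(SIZES["chr1"]):
            counts[index.classify(GenomeInterval("chr1", base, base + 1))] += 1
        got = table.set_index("feature")["genome_fraction"]
        for cls in annotate.FEATURE_CLASSES:
            assert got[cls] == pytest.approx(counts[cls] / SIZES["chr1"],
                                             abs=1e-12), cls

    def test_empty_regions_error(self, toy_genes):
        with pytest.raises(ValueError):
            annotate.genomic_distribution([], toy_genes, SIZES, 100)


class TestLinkGenes:
    def test_upstream_within_window(self, toy_genes):
        region = GenomeInterval("chr1", 500, 600)  # 1.4 kb from gA span
        links = annotate.link_genes([region], toy_genes, 10_000, SIZES)
        assert {l.gene_id for l in links} == {"gA", "gB"}

    def test_boundary_exclusion(self):
        sizes = ChromSizes({"chr1": 200_000})
        gene = GeneModel("g", "chr1", "+", 50_000, 60_000)
        # 10,001 bp away: clearly out of reach of a 10 kb extension
        far = GenomeInterval("chr1", 38_000, 39_999)
        assert annotate.link_genes([far], [gene], 10_000, sizes) == []
        # exactly 10,000 bp away: the extended region is bookended with the
        # gene span, and bookended intervals do not overlap
        at = GenomeInterval("chr1", 38_000, 40_000)
        assert annotate.link_genes([at], [gene], 10_000, sizes) == []
        # one base closer: linked
        links = annotate.link_genes(
            [GenomeInterval("chr1", 38_000, 40_001)], [gene], 10_000, sizes)
        assert len(links) == 1 and links[0].distance == 9_999

    def test_inside_gene_window_zero(self, toy_genes):
        region = GenomeInterval("chr1", 2_400, 2_450)
        links = annotate.link_genes([region], toy_genes, 0, SIZES)
        assert [l.gene_id for l in links] == ["gA"]
        assert links[0].distance == 0

    def test_region_vs_gene_extension_symmetry(self, rng):
        sizes = ChromSizes({"chr1": 100_000})
        for _ in range(50):
            w = int(rng.integers(0, 5_000))
            r_start = int(rng.integers(0, 99_000))
            region = GenomeInterval("chr1", r_start,
                                    r_start + int(rng.integers(1, 900)))
            g_start = int(rng.integers(0, 95_000))
            gene = GeneModel("g", "chr1", "+", g_start,
                             g_start + int(rng.integers(1, 4_000)))
            by_region = bool(annotate.link_genes([region], [gene], w, sizes))
            ext_gene_lo = max(0, gene.tx_start - w)
            ext_gene_hi = min(sizes["chr1"], gene.tx_end + w)
            by_gene = region.start < ext_gene_hi and ext_gene_lo < region.end
            assert by_region == by_gene


class TestColocateDE:
    def _setup(self):
        sizes = ChromSizes({"chr1": 100_000})
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 10_000, i * 10_000 + 2_000)
                 for i in range(1, 9)]
        de = pd.DataFrame({
            "gene_id": ["g1", "g3"],
            "log2fc": [2.5, -1.2],
            "padj": [1e-4, 1e-3],
            "direction": ["up", "down"],
        })
        return sizes, genes, de

    def test_planted_recovery(self):
        sizes, genes, de = self._setup()
        scored = [
            diffacc.ScoredRegion(GenomeInterval("chr1", 9_000, 9_400,
                                                name="near_g1"), 20.0),
            diffacc.ScoredRegion(GenomeInterval("chr1", 55_000, 55_400,
                                                name="far"), 18.0),
        ]
        hits, table = annotate.colocate_de(scored, de, genes, 10_000, sizes)
        assert [sr.region.name for sr in hits] == ["near_g1"]
        assert table.loc[0, "gene_id"] == "g1"
        assert table.loc[0, "direction"] == "up"

    def test_missing_gene_warns_not_errors(self):
        sizes, genes, de = self._setup()
        de = pd.concat([de, pd.DataFrame({
            "gene_id": ["ghost"], "log2fc": [1.0], "padj": [0.01],
            "direction": ["up"]})], ignore_index=True)
        with pytest.warns(UserWarning, match="absent"):
            annotate.colocate_de([], de, genes, 10_000, sizes)

    def test_empty_de_error(self):
        sizes, genes, _ = self._setup()
        with pytest.raises(ValueError):
            annotate.colocate_de([], pd.DataFrame(columns=["gene_id"]),
                                 genes, 10_000, sizes)


class TestColocateMarks:
    def test_empty_and_contained(self):
        region = GenomeInterval("chr1", 100, 300)
        assert annotate.colocate_marks([region], []) == []
        dom = BroadDomain("chr1", 0, 1_000, 0.01)
        ((iv, bp),) = annotate.colocate_marks([region], [dom])
        assert bp == 200

    def test_overlap_bp_against_base_oracle(self, rng):
        length = 50_000
        regions = [GenomeInterval("chr1", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, length - 500, 40),
                                   rng.integers(1, 500, 40))]
        doms = [GenomeInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, length - 2_000, 10),
                                rng.integers(100, 2_000, 10))]
        mask = np.zeros(length, dtype=bool)
        for d in doms:
            mask[d.start:d.end] = True
        got = dict(((iv.start, iv.end), bp)
                   for iv, bp in annotate.colocate_marks(regions, doms))
        for iv in regions:
            expect = int(mask[iv.start:iv.end].sum())
            if expect:
                assert got[(iv.start, iv.end)] == expect
            else:
                assert (iv.start, iv.end) not in got


class TestSignatureOverlap:
    def test_identical_and_disjoint(self):
        universe = {f"g{i}" for i in range(50)}
        a = {f"g{i}" for i in range(10)}
        st = annotate.signature_overlap(a, set(a), universe)
        assert st["n_overlap"] == 10 and st["fraction_of_a"] == 1.0
        b = {f"g{i}" for i in range(20, 30)}
        st = annotate.signature_overlap(a, b, universe)
        assert st["n_overlap"] == 0
        assert 0 < st["p_value"] <= 1

    def test_exact_tail_example(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(7, 12)}  # overlap {g7,g8,g9} = 3
        st = annotate.signature_overlap(a, b, universe)
        assert st["n_overlap"] == 3
        assert st["p_value"] == pytest.approx(
            hypergeom_tail_oracle(3, 100, 5, 10), abs=1e-12)

    def test_subset_enforced(self):
        with pytest.raises(ValueError, match="not a subset"):
            annotate.signature_overlap({"x"}, {"a"}, {"a", "b"})


class TestGenesetEnrichment:
    def test_two_by_two_table(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        lib_set = {f"g{i}" for i in range(3)} | {"g98", "g99"}
        # a=3 in-query-in-set, b=7, c=2, d=88
        df = annotate.geneset_enrichment(query, {"s": lib_set}, universe)
        row = df.iloc[0]
        assert row["overlap"] == 3
        assert row["odds_ratio"] == pytest.approx((3 * 88) / (7 * 2))
        assert row["p_value"] == pytest.approx(
            hypergeom_tail_oracle(3, 100, 5, 10), abs=1e-12)

    def test_identical_and_disjoint_sets(self):
        universe = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(8)}
        df = annotate.geneset_enrichment(
            query, {"same": set(query), "none": {f"g{i}" for i in range(30, 35)}},
            universe)
        same = df.set_index("set").loc["same"]
        none = df.set_index("set").loc["none"]
        assert same["overlap"] == 8
        assert none["odds_ratio"] == 0.0
        assert df["set"].tolist()[0] == "same"  # sorted by p
        assert (df["q_value"] >= df["p_value"] - 1e-15).all()

    def test_empty_query_error(self):
        with pytest.raises(ValueError):
            annotate.geneset_enrichment(set(), {"s": {"a"}}, {"a"})


class TestCoverageMatrix:
    def test_zero_and_constant(self):
        sizes = ChromSizes({"chr1": 10_000})
        zero = CoverageTrack.zeros(sizes, 50)
        regions = [GenomeInterval("chr1", 4_000, 4_400)]
        mat, order, offsets = annotate.coverage_matrix(zero, regions,
                                                       "center", 500, 10)
        assert (mat == 0).all()
        const = CoverageTrack(binsize=50, data={"chr1": np.full(200, 3.25)})
        mat, _, _ = annotate.coverage_matrix(const, regions, "center", 500, 10)
        np.testing.assert_allclose(mat, 3.25)

    def test_single_window_equals_base_average(self, rng):
        values = rng.normal(0, 1, 100)
        track = CoverageTrack(binsize=50, data={"chr1": values},
                              kind="log2ratio")
        region = GenomeInterval("chr1", 1_730, 1_790)
        mat, _, _ = annotate.coverage_matrix(track, [region], "center",
                                             flank=400, nbins=1)
        mid = (1_730 + 1_790) / 2
        per_base = np.repeat(values, 50)
        lo, hi = int(mid - 400), int(mid + 400)
        assert mat[0, 0] == pytest.approx(per_base[lo:hi].mean(), abs=1e-9)

    def test_row_mean_invariant_to_refinement(self, rng):
        values = rng.normal(0, 1, 100)
        track = CoverageTrack(binsize=50, data={"chr1": values},
                              kind="log2ratio")
        region = GenomeInterval("chr1", 2_000, 2_600)
        means = []
        for nb in (4, 12, 48):
            mat, _, _ = annotate.coverage_matrix(track, [region], "scale",
                                                 nbins=nb)
            means.append(mat[0].mean())
        assert means[0] == pytest.approx(means[1], abs=1e-9)
        assert means[1] == pytest.approx(means[2], abs=1e-9)

    def test_score_ordering_and_clipping(self):
        sizes = ChromSizes({"chr1": 5_000})
        track = CoverageTrack(binsize=50, data={"chr1": np.full(100, 2.0)})
        regions = [GenomeInterval("chr1", 100, 200, name="low"),
                   GenomeInterval("chr1", 2_000, 2_100, name="high")]
        mat, order, _ = annotate.coverage_matrix(
            track, regions, "center", flank=500, nbins=10, scores=[1.0, 9.0])
        assert order == [1, 0]
        # first region's window runs off the chromosome start: missing = 0
        assert mat[1, 0] < 2.0
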