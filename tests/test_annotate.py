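"""Priority genomic-context labels and nearest-TSS distances."""

import numpy as np
import pytest

from rrbsdmr.annotate import (
    CONTEXT_LABELS,
    GenomeAnnotator,
    annotate_region,
    build_tss_index,
    context_composition,
    distance_summary,
)
from rrbsdmr.dmr import classify_delta
from rrbsdmr.io import GeneModel

from conftest import make_call, make_region


def gene(gene_id, tss, strand="+", length=1000, chrom="chr1", exons=None):
    if strand == "+":
        start, end = tss, tss + length - 1
    else:
        start, end = tss - length + 1, tss
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        span_start=start,
        span_end=end,
        exons=exons if exons is not None else ((start, end),),
    )


class TestTSSIndex:
    def test_nearest_selection(self):
        idx = build_tss_index([gene("a", 1000), gene("b", 9000)])
        assert idx.nearest("chr1", 5001)[0] == "b"  # 3999 < 4001

    def test_tie_breaks_toward_lower_coordinate(self):
        idx = build_tss_index([gene("a", 1000), gene("b", 9000)])
        assert idx.nearest("chr1", 5000)[0] == "a"

    def test_single_gene_always_wins(self):
        idx = build_tss_index([gene("only", 1000)])
        for pos in (1, 1000, 10**6):
            assert idx.nearest("chr1", pos)[0] == "only"

    def test_same_position_tie_breaks_lexicographically(self):
        idx = build_tss_index([gene("zzz", 1000), gene("aaa", 1000)])
        assert idx.nearest("chr1", 900)[0] == "aaa"

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValueError):
            build_tss_index([])


class TestAnnotateRegion:
    def test_tss_overlap_wins(self):
        g = gene("g", 1000, "+", length=1001)
        ctx = annotate_region(make_region("chr1", [950, 1050]), [g])
        assert ctx.context == "TSS"
        assert ctx.signed_distance_bp == 0

    def test_promoter_band_upstream_of_plus_strand(self):
        g = gene("g", 10_000, "+")
        ctx = annotate_region(make_region("chr1", [8_500, 8_540]), [g])
        assert ctx.context == "promoter"
        assert ctx.signed_distance_bp == -1_480
        assert ctx.abs_distance_kb == pytest.approx(1.48)

    def test_promoter_band_is_mirrored_on_minus_strand(self):
        g = gene("g", 10_000, "-")
        assert annotate_region(make_region("chr1", [11_400, 11_460]), [g]).context == "promoter"
        assert annotate_region(make_region("chr1", [8_500, 8_540]), [g]).context == "intergenic"

    def test_intron_requires_span_but_no_exon(self):
        g = gene(
            "g", 1000, "+", length=5000,
            exons=((1000, 1200), (5000, 5999)),
        )
        ctx = annotate_region(make_region("chr1", [3_000, 3_050]), [g])
        assert ctx.context == "intron"

    def test_far_region_is_intergenic(self):
        g = gene("g", 1000, "+")
        ctx = annotate_region(make_region("chr1", [500_000, 500_050]), [g])
        assert ctx.context == "intergenic"

    def test_no_genes_on_chromosome_gives_no_distance(self):
        ctx = annotate_region(make_region("chr2", [100, 200]), [gene("g", 1000)])
        assert ctx.context == "intergenic"
        assert ctx.nearest_gene is None


def brute_annotate(region, genes, tss_w=100, prom_w=2000):
    """All-genes interval scan, written independently of the tree index."""

    def olap(a0, a1, b0, b1):
        return a0 <= b1 and b0 <= a1

    same = [g for g in genes if g.chrom == region.chrom]
    r0, r1 = region.start, region.end
    if any(olap(r0, r1, max(1, g.tss - tss_w), g.tss + tss_w) for g in same):
        context = "TSS"
    elif any(
        olap(r0, r1, *band)
        for g in same
        for band in [
            (max(1, g.tss - prom_w), g.tss - tss_w - 1)
            if g.strand == "+"
            else (g.tss + tss_w + 1, g.tss + prom_w)
        ]
        if band[0] <= band[1]
    ):
        context = "promoter"
    elif any(olap(r0, r1, es, ee) for g in same for es, ee in g.exons):
        context = "exon"
    elif any(olap(r0, r1, g.span_start, g.span_end) for g in same):
        context = "intron"
    else:
        context = "intergenic"
    mid = (r0 + r1) // 2
    if not same:
        return context, None, None
    best = min(same, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
    d = mid - best.tss
    return context, best.gene_id, d if best.strand == "+" else -d


def random_gene(rng, gid):
    start = int(rng.integers(1, 50_000))
    length = int(rng.integers(200, 8_000))
    end = start + length
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(1, 4))
    exons = []
    for _ in range(n_ex):
        es = int(rng.integers(start, end))
        ee = int(rng.integers(es, end + 1))
        exons.append((es, ee))
    return GeneModel(gid, "chr1", strand, start, end, tuple(sorted(exons)))


class TestOracleEquivalence:
    def test_matches_brute_force_scan_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(500):
            genes = [random_gene(rng, f"g{i}") for i in range(int(rng.integers(1, 8)))]
            start = int(rng.integers(1, 60_000))
            region = make_region("chr1", [start, start + int(rng.integers(0, 400))])
            got = annotate_region(region, genes)
            want = brute_annotate(region, genes)
            assert (got.context, got.nearest_gene, got.signed_distance_bp) == want

    def test_labels_partition_every_region(self):
        rng = np.random.default_rng(14)
        genes = [random_gene(rng, f"g{i}") for i in range(10)]
        annotator = GenomeAnnotator(genes)
        for _ in range(200):
            start = int(rng.integers(1, 70_000))
            ctx = annotator.annotate(make_region("chr1", [start, start + 100]))
            assert ctx.context in CONTEXT_LABELS

    def test_translation_invariance(self):
        rng = np.random.default_rng(15)
        shift = 1_000_000
        for _ in range(50):
            genes = [random_gene(rng, f"g{i}") for i in range(4)]
            start = int(rng.integers(1, 60_000))
            region = make_region("chr1", [start, start + 120])
            moved_genes = [
                GeneModel(
                    g.gene_id, g.chrom, g.strand,
                    g.span_start + shift, g.span_end + shift,
                    tuple((a + shift, b + shift) for a, b in g.exons),
                )
                for g in genes
            ]
            moved_region = make_region("chr1", [start + shift, start + 120 + shift])
            a = annotate_region(region, genes)
            b = annotate_region(moved_region, moved_genes)
            assert a.context == b.context
            assert a.signed_distance_bp == b.signed_distance_bp


class TestContextComposition:
    def test_tabulation_with_percentages(self):
        calls = [
            make_call("chr1", s, s + 10, -10.0, "decreased")
            for s in (100, 300, 500, 700)
        ]
        contexts = [
            annotate_region(c.region, [gene("g", 10**6)]) for c in calls[:2]
        ]
        # force distinct labels for the last two
        from rrbsdmr.annotate import GenomicContext

        contexts.append(GenomicContext(calls[2].region.region_id, "intron", "g", 10))
        contexts.append(GenomicContext(calls[3].region.region_id, "exon", "g", 10))
        comp = context_composition(contexts, calls)
        dec = comp[comp["direction"] == "decreased"].set_index("context")
        assert dec.loc["intergenic", "pct"] == pytest.approx(50.0)
        assert dec.loc["intron", "pct"] == pytest.approx(25.0)
        assert dec.loc["exon", "pct"] == pytest.approx(25.0)
        assert dec.loc["TSS", "count"] == 0
        assert dec["pct"].sum() == pytest.approx(100.0)

    def test_empty_direction_has_zero_counts_and_no_percentages(self):
        comp = context_composition([], [])
        inc = comp[comp["direction"] == "increased"]
        assert inc["count"].sum() == 0
        assert inc["pct"].isna().all()

    def test_missing_annotation_is_error(self):
        calls = [make_call("chr1", 100, 110, -10.0, "decreased")]
        with pytest.raises(KeyError):
            context_composition([], calls)


class TestDistanceSummary:
    def test_median_of_absolute_distances(self):
        from rrbsdmr.annotate import GenomicContext

        contexts = [
            GenomicContext(f"r{i}", "intergenic", "g", d * 1000)
            for i, d in enumerate([1, 3, 5])
        ]
        summ = distance_summary(contexts, {"all": ["r0", "r1", "r2"]})
        assert summ.loc[0, "median_kb"] == pytest.approx(3.0)

    def test_single_region_collapses_all_quantiles(self):
        from rrbsdmr.annotate import GenomicContext

        contexts = [GenomicContext("r0", "exon", "g", -4200)]
        summ = distance_summary(contexts, {"only": ["r0"]})
        row = summ.iloc[0]
        assert (
            row["min_kb"] == row["q1_kb"] == row["median_kb"]
            == row["q3_kb"] == row["max_kb"] == pytest.approx(4.2)
        )

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            summ = distance_summary([], {"none": []})
        assert summ.empty
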