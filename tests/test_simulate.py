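"""Synthetic methylome generator: determinism, statistics, truth bookkeeping."""

import gzip

import numpy as np
import pandas as pd
import pytest

from rrbsdmr.dmr import ComparisonSpec, call_dmrs, summarize_directions
from rrbsdmr.io import read_bismark_coverage
from rrbsdmr.regions import assemble_regions
from rrbsdmr.scoring import filter_scoreable, intersect_common_loci
from rrbsdmr.simulate import (
    SimConfig,
    TruthRecord,
    evaluate_recovery,
    simulate_gene_annotation,
    simulate_methylomes,
    write_fixtures,
)

from conftest import make_call

SMALL = SimConfig(
    seed=5,
    n_chroms=1,
    chrom_length=1_000_000,
    n_planted=10,
    n_genes=6,
)


def run_pipeline_on(samples, delta_threshold=5.0):
    matrix = filter_scoreable(intersect_common_loci(samples))
    regions = assemble_regions(matrix)
    ctrl = tuple(s.sample_id for s in samples if s.group == "control")
    trt = tuple(s.sample_id for s in samples if s.group == "treatment")
    spec = ComparisonSpec("sim", ctrl, trt, delta_threshold)
    return call_dmrs(regions, matrix, spec)


class TestGeneAnnotation:
    def test_deterministic_given_seed(self):
        a = simulate_gene_annotation(SMALL)
        b = simulate_gene_annotation(SMALL)
        assert a == b

    def test_zero_genes_gives_empty_annotation(self):
        cfg = SimConfig(seed=1, n_genes=0)
        assert simulate_gene_annotation(cfg) == []

    def test_genes_do_not_overlap_and_have_valid_structure(self):
        genes = simulate_gene_annotation(SimConfig(seed=2, n_genes=40))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            assert g.strand in "+-"
            assert g.exons[0][0] == g.span_start
            assert g.exons[-1][1] == g.span_end
        for chrom_genes in by_chrom.values():
            spans = sorted((g.span_start, g.span_end) for g in chrom_genes)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_plus_strand_tss_is_span_start(self):
        genes = simulate_gene_annotation(SimConfig(seed=3, n_genes=30))
        for g in genes:
            assert g.tss == (g.span_start if g.strand == "+" else g.span_end)


class TestSimulateMethylomes:
    def test_deterministic_given_seed(self, tmp_path):
        files = []
        for sub in ("a", "b"):
            samples, truth = simulate_methylomes(SMALL)
            genes = simulate_gene_annotation(SMALL)
            paths = write_fixtures(samples, genes, truth, tmp_path / sub)
            files.append(paths)
        for key in files[0]:
            raw = [
                (gzip.open(p, "rb").read() if str(p).endswith(".gz") else open(p, "rb").read())
                for p in (files[0][key], files[1][key])
            ]
            assert raw[0] == raw[1], f"{key} differs between identical runs"

    def test_truth_count_and_separation(self):
        samples, truth = simulate_methylomes(SMALL)
        assert len(truth) == SMALL.n_planted
        by_chrom = {}
        for t in truth:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert s2 - e1 > SMALL.cluster_gap

    def test_null_config_plants_nothing(self):
        samples, truth = simulate_methylomes(
            SimConfig(seed=5, n_chroms=1, chrom_length=500_000, n_planted=0)
        )
        assert truth == []
        assert len(samples) == 2

    def test_null_directions_roughly_symmetric(self):
        cfg = SimConfig(seed=8, n_chroms=1, chrom_length=2_000_000,
                        n_planted=0, planted_delta=0.0)
        samples, _ = simulate_methylomes(cfg)
        s = summarize_directions(run_pipeline_on(samples))
        total = s.increased + s.decreased
        assert total > 0
        assert abs(s.increased - s.decreased) < 0.25 * total

    def test_high_coverage_converges_to_planted_delta(self):
        # binomial mode isolates read-sampling noise, which vanishes as
        # coverage grows; beta-binomial replicate noise would not
        cfg = SimConfig(seed=9, n_chroms=1, chrom_length=2_000_000,
                        coverage_mean=10_000, n_planted=20, planted_delta=25.0,
                        meth_precision=None)
        samples, truth = simulate_methylomes(cfg)
        calls = run_pipeline_on(samples)
        by_pos = {}
        for c in calls:
            by_pos.setdefault(c.region.chrom, []).append(c)
        for t in truth:
            hits = [
                c for c in by_pos.get(t.chrom, [])
                if c.region.start <= t.end and t.start <= c.region.end
            ]
            assert hits, f"planted region {t.chrom}:{t.start}-{t.end} not recovered"
            best = max(hits, key=lambda c: min(c.region.end, t.end) - max(c.region.start, t.start))
            assert best.delta == pytest.approx(t.true_delta, abs=1.0)

    def test_delta_rmse_shrinks_with_coverage(self):
        rmses = []
        for cov in (10, 30, 100, 1000):
            cfg = SimConfig(seed=12, n_chroms=1, chrom_length=2_000_000,
                            coverage_mean=cov, n_planted=15, planted_delta=25.0,
                            meth_precision=None)
            samples, truth = simulate_methylomes(cfg)
            calls = run_pipeline_on(samples)
            rmses.append(evaluate_recovery(calls, truth).delta_rmse)
        assert rmses == sorted(rmses, reverse=True)

    def test_coverage_never_zero_in_tables(self):
        samples, _ = simulate_methylomes(SMALL)
        for s in samples:
            cov = s.table["meth"] + s.table["unmeth"]
            assert (cov >= 1).all()

    def test_binomial_mode_runs_without_beta_layer(self):
        cfg = SimConfig(seed=4, n_chroms=1, chrom_length=500_000,
                        n_planted=0, meth_precision=None)
        samples, _ = simulate_methylomes(cfg)
        assert len(samples[0]) > 0


class TestWriteFixtures:
    def test_refuses_non_empty_dir_without_force(self, tmp_path):
        samples, truth = simulate_methylomes(SMALL)
        out = tmp_path / "fx"
        out.mkdir()
        (out / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixtures(samples, [], truth, out)
        write_fixtures(samples, [], truth, out, force=True)

    def test_round_trip_reproduces_counts(self, tmp_path):
        samples, truth = simulate_methylomes(SMALL)
        paths = write_fixtures(samples, [], truth, tmp_path / "fx")
        back = read_bismark_coverage(
            paths[samples[0].sample_id], samples[0].sample_id, samples[0].group
        )
        pd.testing.assert_frame_equal(back.table, samples[0].table)

    def test_truth_file_has_one_row_per_planted_region(self, tmp_path):
        samples, truth = simulate_methylomes(SMALL)
        paths = write_fixtures(samples, [], truth, tmp_path / "fx")
        truth_df = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth_df) == SMALL.n_planted

    def test_percentage_column_matches_counts_to_2_decimals(self, tmp_path):
        samples, truth = simulate_methylomes(SMALL)
        paths = write_fixtures(samples, [], truth, tmp_path / "fx")
        with gzip.open(paths[samples[0].sample_id], "rt") as fh:
            for line in list(fh)[:200]:
                chrom, pos, _, pct, meth, unmeth = line.split("\t")
                meth, unmeth = int(meth), int(unmeth)
                assert float(pct) == pytest.approx(
                    100 * meth / (meth + unmeth), abs=0.0051
                )


class TestEvaluateRecovery:
    def test_perfect_recovery(self):
        truth = [TruthRecord("chr1", 100, 200, 25.0, "increased"),
                 TruthRecord("chr1", 500, 600, -25.0, "decreased")]
        calls = [make_call("chr1", 100, 200, 25.0, "increased"),
                 make_call("chr1", 500, 600, -25.0, "decreased")]
        m = evaluate_recovery(calls, truth)
        assert m.sensitivity == 1.0
        assert m.precision == 1.0
        assert m.direction_accuracy == 1.0
        assert m.delta_rmse == pytest.approx(0.0)

    def test_no_calls_gives_zero_sensitivity(self):
        truth = [TruthRecord("chr1", 100, 200, 25.0, "increased")]
        m = evaluate_recovery([], truth)
        assert m.sensitivity == 0.0
        assert m.confusion == {("increased", "none"): 1}

    def test_null_truth_is_error(self):
        with pytest.raises(ValueError):
            evaluate_recovery([], [])

    def test_opposite_direction_counts_against_accuracy(self):
        truth = [TruthRecord("chr1", 100, 200, 25.0, "increased")]
        calls = [make_call("chr1", 150, 180, -30.0, "decreased")]
        m = evaluate_recovery(calls, truth)
        assert m.sensitivity == 0.0
        assert m.n_detected_any == 1
        assert m.direction_accuracy == 0.0

    def test_truth_direction_must_match_delta_sign(self):
        with pytest.raises(ValueError):
            TruthRecord("chr1", 1, 2, 25.0, "decreased")
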