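"""End-to-end orchestration: coverage tables in, DMR/annotation tables out.

The stages run in the Methods order: joint-locus intersection, scoreability
filter (coverage > 8 in all samples), 50-bp region assembly, >5 pp DMR
classification, genomic-context annotation, TSS-distance summaries, and
cross-comparison conservation.  A structured run log (key=value lines)
records parameters and the counts at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    GenomeAnnotator,
    context_composition,
    distance_summary,
)
from .conservation import conserved_fraction
from .dmr import ComparisonSpec, call_dmrs, calls_to_frame, delta_histogram, summarize_directions
from .io import read_bismark_coverage, read_gene_models, write_table
from .regions import assemble_regions
from .scoring import filter_scoreable, intersect_common_loci

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SampleEntry", "validate_config", "run_pipeline"]


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    path: str


@dataclass
class PipelineConfig:
    samples: list[SampleEntry]
    comparisons: list[ComparisonSpec]
    out_dir: str
    annotation_path: str | None = None
    annotation_dialect: str = "bed12"
    tss_window: int = 100
    promoter_window: int = 2000
    bin_width: float = 5.0
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        samples = [
            SampleEntry(s["sample_id"], s["group"], resolve(s["path"]))
            for s in raw.get("samples", [])
        ]
        comparisons = [
            ComparisonSpec(
                comparison_id=c["comparison_id"],
                control_samples=tuple(c["control_samples"]),
                treatment_samples=tuple(c["treatment_samples"]),
                delta_threshold=c.get("delta_threshold", 5.0),
                max_gap=c.get("max_gap", 50),
                min_cov_exclusive=c.get("min_cov_exclusive", 8),
            )
            for c in raw.get("comparisons", [])
        ]
        ann = raw.get("annotation") or {}
        return cls(
            samples=samples,
            comparisons=comparisons,
            out_dir=resolve(raw["out_dir"]) if "out_dir" in raw else str(base / "out"),
            annotation_path=resolve(ann["path"]) if ann.get("path") else None,
            annotation_dialect=ann.get("dialect", "bed12"),
            tss_window=raw.get("tss_window", 100),
            promoter_window=raw.get("promoter_window", 2000),
            bin_width=raw.get("bin_width", 5.0),
            seed=raw.get("seed", 0),
            log_level=raw.get("log_level", "INFO"),
            force=raw.get("force", False),
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Referential and range checks; returns every violation, not just one."""
    violations: list[str] = []
    ids = [s.sample_id for s in config.samples]
    if len(set(ids)) != len(ids):
        violations.append("duplicate sample ids in manifest")
    if len(config.samples) < 2:
        violations.append("need at least 2 samples")
    for s in config.samples:
        if not Path(s.path).exists():
            violations.append(f"sample {s.sample_id}: file not found: {s.path}")
    known = set(ids)
    cids = [c.comparison_id for c in config.comparisons]
    if len(set(cids)) != len(cids):
        violations.append("duplicate comparison ids")
    if not config.comparisons:
        violations.append("no comparisons defined")
    for c in config.comparisons:
        for sid in (*c.control_samples, *c.treatment_samples):
            if sid not in known:
                violations.append(
                    f"comparison {c.comparison_id}: unknown sample {sid!r}"
                )
        if c.delta_threshold <= 0:
            violations.append(
                f"comparison {c.comparison_id}: delta_threshold must be > 0"
            )
        if c.max_gap < 0:
            violations.append(f"comparison {c.comparison_id}: max_gap must be >= 0")
        if c.min_cov_exclusive < 0:
            violations.append(
                f"comparison {c.comparison_id}: min_cov_exclusive must be >= 0"
            )
    if config.bin_width <= 0:
        violations.append("bin_width must be > 0")
    if config.annotation_path and not Path(config.annotation_path).exists():
        violations.append(f"annotation file not found: {config.annotation_path}")
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every comparison plus pairwise conservation; write TSVs + run log.

    Returns a result dict with per-comparison calls and stage counts (the
    same numbers the run log records).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(violations))
    out_dir = Path(config.out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not config.force:
        raise FileExistsError(f"{out_dir} is not empty (set force)")
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = [f"rrbsdmr_version={__version__}", f"seed={config.seed}"]

    samples = [
        read_bismark_coverage(s.path, s.sample_id, s.group) for s in config.samples
    ]
    for s in samples:
        log_lines.append(f"sample.{s.sample_id}.loci_read={len(s)}")

    genes = None
    annotator = None
    if config.annotation_path:
        genes = read_gene_models(config.annotation_path, config.annotation_dialect)
        annotator = GenomeAnnotator(
            genes, config.tss_window, config.promoter_window
        )
        log_lines.append(f"annotation.n_genes={len(genes)}")

    common = intersect_common_loci(samples)
    log_lines.append(f"common_loci={common.n_loci}")

    # matrix + regions are shared by comparisons with equal thresholds
    cache: dict[tuple[int, int], tuple] = {}
    results: dict[str, dict] = {}
    for spec in config.comparisons:
        key = (spec.min_cov_exclusive, spec.max_gap)
        if key not in cache:
            scoreable = filter_scoreable(common, spec.min_cov_exclusive)
            regions = assemble_regions(scoreable, spec.max_gap)
            cache[key] = (scoreable, regions)
            log_lines.append(
                f"threshold.cov{key[0]}.gap{key[1]}.scoreable_loci={scoreable.n_loci}"
            )
            log_lines.append(
                f"threshold.cov{key[0]}.gap{key[1]}.regions={len(regions)}"
            )
        scoreable, regions = cache[key]

        calls = call_dmrs(regions, scoreable, spec)
        counts = summarize_directions(calls)
        cid = spec.comparison_id
        log_lines += [
            f"comparison.{cid}.regions={len(calls)}",
            f"comparison.{cid}.increased={counts.increased}",
            f"comparison.{cid}.decreased={counts.decreased}",
            f"comparison.{cid}.unchanged={counts.unchanged}",
        ]

        calls_df = calls_to_frame(calls, cid)
        write_table(calls_df, out_dir / f"{cid}.dmrs.tsv", sort_by=["chrom", "start"])
        regions_df = calls_df[["region_id", "chrom", "start", "end", "n_cpgs"]].copy()
        regions_df["width"] = regions_df["end"] - regions_df["start"] + 1
        write_table(
            regions_df, out_dir / f"{cid}.regions.tsv", sort_by=["chrom", "start"]
        )
        hist_all = delta_histogram(calls, config.bin_width)
        write_table(hist_all, out_dir / f"{cid}.histogram_all.tsv")
        called = [c for c in calls if c.direction != "unchanged"]
        write_table(
            delta_histogram(called, config.bin_width),
            out_dir / f"{cid}.histogram_called.tsv",
        )

        result = {
            "spec": spec,
            "calls": calls,
            "direction_counts": counts,
            "n_scoreable": scoreable.n_loci,
            "n_regions": len(regions),
        }

        if annotator is not None:
            contexts = {}
            ann_rows = []
            for call in calls:
                ctx = annotator.annotate(call.region)
                contexts[ctx.region_id] = ctx
                ann_rows.append(
                    {
                        "region_id": ctx.region_id,
                        "chrom": call.region.chrom,
                        "start": call.region.start,
                        "context": ctx.context,
                        "nearest_gene": ctx.nearest_gene,
                        "signed_distance_bp": ctx.signed_distance_bp,
                        "abs_distance_kb": ctx.abs_distance_kb,
                    }
                )
            write_table(
                pd.DataFrame(ann_rows).drop(columns=["chrom", "start"]),
                out_dir / f"{cid}.annotation.tsv",
            )
            comp = context_composition(contexts, calls)
            write_table(comp, out_dir / f"{cid}.context_composition.tsv")
            grouping = {
                d: [c.region.region_id for c in calls if c.direction == d]
                for d in ("increased", "decreased", "unchanged")
            }
            dsumm = distance_summary(contexts, grouping)
            write_table(dsumm, out_dir / f"{cid}.distance_summary.tsv")
            result["contexts"] = contexts
            result["context_composition"] = comp
            result["distance_summary"] = dsumm
        results[cid] = result

    conservation_rows = []
    comp_ids = list(results)
    for i, qid in enumerate(comp_ids):
        for rid in comp_ids[i + 1 :]:
            for direction in ("increased", "decreased"):
                rep = conserved_fraction(
                    results[qid]["calls"], results[rid]["calls"], direction
                )
                conservation_rows.append(
                    {
                        "query": qid,
                        "reference": rid,
                        "direction": direction,
                        "n_query": rep.n_query,
                        "n_conserved": rep.n_conserved,
                        "fraction": rep.fraction,
                        "n_reference": rep.n_reference,
                        "n_reference_conserved": rep.n_reference_conserved,
                        "fraction_reference": rep.fraction_reference,
                        "jaccard_bp": rep.jaccard_bp,
                    }
                )
                log_lines.append(
                    f"conservation.{qid}.vs.{rid}.{direction}="
                    f"{rep.fraction:.4f}"
                )
    if conservation_rows:
        write_table(
            pd.DataFrame(conservation_rows), out_dir / "conservation.tsv"
        )

    with open(out_dir / "run_log.txt", "wt") as fh:
        fh.write("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)

    return {
        "comparisons": results,
        "conservation": conservation_rows,
        "common_loci": common.n_loci,
        "log_lines": log_lines,
        "out_dir": out_dir,
    }
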