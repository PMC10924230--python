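"""Genomic-context classification and nearest-TSS distances for CpG regions.

Regions are labelled with exactly one of five contexts by first-match
priority, mirroring peak-annotation practice (Homer's AnnotatePeaks):

1. **TSS** — the region overlaps ``[tss - tss_window, tss + tss_window]``
   of any gene (default window 100 bp);
2. **promoter** — it overlaps the strand-aware upstream band
   ``[tss - promoter_window, tss - tss_window - 1]`` (+ strand; mirrored on
   -), default 2 kb;
3. **exon** — it overlaps any exon;
4. **intron** — it overlaps a transcript span but no exon;
5. **intergenic** — otherwise.

The nearest-TSS distance is measured from the region midpoint, signed
negative when the midpoint lies upstream of the TSS in the gene's
orientation.  Distance summaries use absolute kb.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dmr import DMRCall
from .io import GeneModel
from .regions import CpGRegion

__all__ = [
    "TSSIndex",
    "GenomicContext",
    "GenomeAnnotator",
    "build_tss_index",
    "annotate_region",
    "context_composition",
    "distance_summary",
    "CONTEXT_LABELS",
]

CONTEXT_LABELS = ("TSS", "promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicContext:
    """A region's priority context and signed distance to the nearest TSS."""

    region_id: str
    context: str
    nearest_gene: str | None
    signed_distance_bp: int | None

    @property
    def abs_distance_kb(self) -> float:
        if self.signed_distance_bp is None:
            return float("nan")
        return abs(self.signed_distance_bp) / 1000.0


class TSSIndex:
    """Per-chromosome sorted TSS positions supporting nearest queries.

    Ties in absolute distance break toward the lower-coordinate TSS, then the
    lexicographically smaller gene_id.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("cannot build a TSS index from an empty gene list")
        per_chrom: dict[str, list[tuple[int, str, str]]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))
        self._index: dict[str, tuple[list[int], list[str], list[str]]] = {}
        for chrom, entries in per_chrom.items():
            entries.sort()  # by (tss, gene_id)
            self._index[chrom] = (
                [e[0] for e in entries],
                [e[1] for e in entries],
                [e[2] for e in entries],
            )

    def nearest(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Return (gene_id, tss, strand) of the nearest TSS, or None if the
        chromosome has no genes."""
        if chrom not in self._index:
            return None
        tss_list, gene_ids, strands = self._index[chrom]
        i = bisect_left(tss_list, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(tss_list):
                d = abs(tss_list[j] - pos)
                # tie -> lower coordinate; equal coordinates -> first (lex) id
                if best is None or d < best[0]:
                    best = (d, j)
        return (gene_ids[best[1]], tss_list[best[1]], strands[best[1]])


def build_tss_index(genes: Sequence[GeneModel]) -> TSSIndex:
    return TSSIndex(genes)


def _signed_distance(midpoint: int, tss: int, strand: str) -> int:
    d = midpoint - tss
    return d if strand == "+" else -d


class GenomeAnnotator:
    """Interval indexes over one gene set, reusable across many regions."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tss_window: int = 100,
        promoter_window: int = 2000,
    ):
        self.tss_window = tss_window
        self.promoter_window = promoter_window
        self.genes = list(genes)
        self.tss_index = TSSIndex(genes) if genes else None
        # intervaltree uses half-open ints; store [start, end+1)
        self._tss_trees: dict[str, IntervalTree] = {}
        self._prom_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        for g in genes:
            lo = max(1, g.tss - tss_window)
            hi = g.tss + tss_window
            self._tss_trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1)
            ps, pe = _promoter_interval(g, tss_window, promoter_window)
            if ps is not None:
                self._prom_trees.setdefault(g.chrom, IntervalTree()).addi(ps, pe + 1)
            for es, ee in g.exons:
                self._exon_trees.setdefault(g.chrom, IntervalTree()).addi(es, ee + 1)
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.span_start, g.span_end + 1
            )

    def _hits(self, trees: dict[str, IntervalTree], region: CpGRegion) -> bool:
        tree = trees.get(region.chrom)
        return bool(tree is not None and tree.overlap(region.start, region.end + 1))

    def annotate(self, region: CpGRegion) -> GenomicContext:
        if self._hits(self._tss_trees, region):
            context = "TSS"
        elif self._hits(self._prom_trees, region):
            context = "promoter"
        elif self._hits(self._exon_trees, region):
            context = "exon"
        elif self._hits(self._span_trees, region):
            context = "intron"
        else:
            context = "intergenic"
        midpoint = (region.start + region.end) // 2
        nearest = self.tss_index.nearest(region.chrom, midpoint) if self.tss_index else None
        if nearest is None:
            return GenomicContext(region.region_id, context, None, None)
        gene_id, tss, strand = nearest
        return GenomicContext(
            region.region_id,
            context,
            gene_id,
            _signed_distance(midpoint, tss, strand),
        )


def _promoter_interval(
    gene: GeneModel, tss_window: int, promoter_window: int
) -> tuple[int | None, int | None]:
    """Strand-aware upstream band outside the near-TSS window (1-based incl.)."""
    if promoter_window <= tss_window:
        return None, None
    if gene.strand == "+":
        lo, hi = gene.tss - promoter_window, gene.tss - tss_window - 1
    else:
        lo, hi = gene.tss + tss_window + 1, gene.tss + promoter_window
    lo = max(1, lo)
    if lo > hi:
        return None, None
    return lo, hi


def annotate_region(
    region: CpGRegion,
    genes: Sequence[GeneModel],
    tss_window: int = 100,
    promoter_window: int = 2000,
) -> GenomicContext:
    """Classify one region against a gene set (convenience wrapper).

    For many regions against one gene set, build a :class:`GenomeAnnotator`
    once instead.
    """
    return GenomeAnnotator(genes, tss_window, promoter_window).annotate(region)


def context_composition(
    contexts: Sequence[GenomicContext] | Mapping[str, GenomicContext],
    calls: Sequence[DMRCall],
) -> pd.DataFrame:
    """Per-direction counts and percentages over the five context labels.

    Directions with no calls get a zero-count row per context and no
    percentages (NaN).  A called region missing from ``contexts`` is an
    error.
    """
    if not isinstance(contexts, Mapping):
        contexts = {c.region_id: c for c in contexts}
    rows = []
    for direction in ("increased", "decreased"):
        sub = [c for c in calls if c.direction == direction]
        counts = dict.fromkeys(CONTEXT_LABELS, 0)
        for call in sub:
            ctx = contexts.get(call.region.region_id)
            if ctx is None:
                raise KeyError(
                    f"region {call.region.region_id} has no genomic-context annotation"
                )
            counts[ctx.context] += 1
        total = len(sub)
        for label in CONTEXT_LABELS:
            rows.append(
                {
                    "direction": direction,
                    "context": label,
                    "count": counts[label],
                    "pct": 100.0 * counts[label] / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def distance_summary(
    contexts: Sequence[GenomicContext] | Mapping[str, GenomicContext],
    grouping: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Quartile summary of absolute TSS distance (kb) per named region group.

    ``grouping`` maps a label (e.g. "increased") to region_ids.  Empty groups
    are skipped with a warning; regions without a nearest TSS (chromosome
    with no genes) are excluded from the summary.
    """
    if not isinstance(contexts, Mapping):
        contexts = {c.region_id: c for c in contexts}
    rows = []
    for label, region_ids in grouping.items():
        dists = []
        for rid in region_ids:
            ctx = contexts.get(rid)
            if ctx is None:
                raise KeyError(f"region {rid} has no genomic-context annotation")
            if ctx.signed_distance_bp is not None:
                dists.append(ctx.abs_distance_kb)
        if not dists:
            warnings.warn(f"distance_summary: group {label!r} is empty; skipped")
            continue
        arr = np.asarray(dists)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {
                "group": label,
                "n": len(arr),
                "min_kb": float(arr.min()),
                "q1_kb": float(q1),
                "median_kb": float(med),
                "q3_kb": float(q3),
                "max_kb": float(arr.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n", "min_kb", "q1_kb", "median_kb", "q3_kb", "max_kb"],
    )
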