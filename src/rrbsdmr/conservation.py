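"""Cross-comparison conservation of direction-matched DMR calls.

A query DMR is "conserved" when it overlaps (>= 1 shared bp, 1-based
inclusive coordinates) at least one reference DMR called in the same
direction.  Because no convention fixes which comparison is the denominator,
the fraction is reported in both orientations, together with the base-pair
Jaccard of the two direction-matched region sets (intersection bp / union
bp, the bedtools-jaccard convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .dmr import DMRCall
from .regions import CpGRegion

__all__ = ["ConservationReport", "overlaps", "conserved_fraction"]


@dataclass(frozen=True)
class ConservationReport:
    direction: str
    n_query: int
    n_conserved: int
    fraction: float
    n_reference: int
    n_reference_conserved: int
    fraction_reference: float
    jaccard_bp: float


def overlaps(a: CpGRegion, b: CpGRegion) -> bool:
    """True iff the regions share >= 1 bp (1-based inclusive intervals)."""
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _build_trees(regions: Sequence[CpGRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
    return trees


def _count_conserved(
    queries: Sequence[CpGRegion],
    trees: dict[str, IntervalTree],
    min_reciprocal_overlap: float,
) -> int:
    n = 0
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = tree.overlap(q.start, q.end + 1)
        if min_reciprocal_overlap <= 0:
            if hits:
                n += 1
            continue
        q_len = q.end - q.start + 1
        for iv in hits:
            r_len = iv.end - iv.begin  # half-open stored length
            ov = min(q.end + 1, iv.end) - max(q.start, iv.begin)
            if (
                ov / q_len >= min_reciprocal_overlap
                and ov / r_len >= min_reciprocal_overlap
            ):
                n += 1
                break
    return n


def _total_bp(trees: dict[str, IntervalTree]) -> int:
    total = 0
    for tree in trees.values():
        merged = tree.copy()
        merged.merge_overlaps()
        total += sum(iv.end - iv.begin for iv in merged)
    return total


def _intersection_bp(
    a_trees: dict[str, IntervalTree], b_trees: dict[str, IntervalTree]
) -> int:
    total = 0
    for chrom, a_tree in a_trees.items():
        b_tree = b_trees.get(chrom)
        if b_tree is None:
            continue
        a_m = a_tree.copy()
        a_m.merge_overlaps()
        b_m = b_tree.copy()
        b_m.merge_overlaps()
        for iv in a_m:
            for hit in b_m.overlap(iv.begin, iv.end):
                total += min(iv.end, hit.end) - max(iv.begin, hit.begin)
    return total


def conserved_fraction(
    query_calls: Sequence[DMRCall],
    reference_calls: Sequence[DMRCall],
    direction: str,
    min_reciprocal_overlap: float = 0.0,
) -> ConservationReport:
    """Fraction of direction-matched query DMRs overlapping reference DMRs.

    Both call sets are restricted to ``direction`` first.  The fraction is
    n_conserved / n_query (0 when there are no query calls); the swapped
    orientation and the bp-level Jaccard are reported alongside.  With
    ``min_reciprocal_overlap`` > 0 an overlap only counts when it covers at
    least that fraction of both regions.
    """
    if direction not in ("increased", "decreased"):
        raise ValueError(f"unknown direction {direction!r}")
    q_regions = [c.region for c in query_calls if c.direction == direction]
    r_regions = [c.region for c in reference_calls if c.direction == direction]
    q_trees = _build_trees(q_regions)
    r_trees = _build_trees(r_regions)
    n_q_cons = _count_conserved(q_regions, r_trees, min_reciprocal_overlap)
    n_r_cons = _count_conserved(r_regions, q_trees, min_reciprocal_overlap)
    inter = _intersection_bp(q_trees, r_trees)
    union = _total_bp(q_trees) + _total_bp(r_trees) - inter
    return ConservationReport(
        direction=direction,
        n_query=len(q_regions),
        n_conserved=n_q_cons,
        fraction=n_q_cons / len(q_regions) if q_regions else 0.0,
        n_reference=len(r_regions),
        n_reference_conserved=n_r_cons,
        fraction_reference=n_r_cons / len(r_regions) if r_regions else 0.0,
        jaccard_bp=inter / union if union else 0.0,
    )
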