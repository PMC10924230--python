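"""Proximity chaining of scoreable CpGs into regions and pooled methylation.

CpGs are grouped by single linkage: adjacent scoreable CpGs at most
``max_gap`` bp apart (default 50) join the same region, so a region can span
far more than 50 bp through chaining.  Region methylation is the
coverage-weighted pooled fraction: counts are summed over member CpGs and
samples, then divided.  An unweighted per-CpG mean is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scoring import MethylomeMatrix

__all__ = [
    "CpGRegion",
    "assemble_regions",
    "pool_region_counts",
    "region_methylation",
    "region_methylation_unweighted",
]


@dataclass(frozen=True)
class CpGRegion:
    """A maximal run of scoreable CpGs pairwise-chained at <= max_gap bp.

    ``member_index`` holds row indices into the matrix the region was built
    from (a contiguous range, since loci are sorted); ``member_positions`` the
    corresponding 1-based cytosine positions.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    member_index: tuple[int, ...]
    member_positions: tuple[int, ...]

    @property
    def n_cpgs(self) -> int:
        return len(self.member_positions)

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def assemble_regions(matrix: MethylomeMatrix, max_gap: int = 50) -> list[CpGRegion]:
    """Chain sorted loci into regions, splitting where the gap exceeds max_gap.

    Every locus belongs to exactly one region; singletons are kept.  Region
    ids are ``chrom:start-end``.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    chroms = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    if len(pos) == 0:
        return []
    order_ok = np.all(
        (chroms[:-1] < chroms[1:])
        | ((chroms[:-1] == chroms[1:]) & (pos[:-1] < pos[1:]))
    )
    if not order_ok:
        raise RuntimeError("matrix loci are not strictly sorted by (chrom, pos)")

    # new region wherever the chromosome changes or the gap exceeds max_gap
    brk = np.zeros(len(pos), dtype=bool)
    brk[0] = True
    brk[1:] = (chroms[1:] != chroms[:-1]) | ((pos[1:] - pos[:-1]) > max_gap)
    starts = np.flatnonzero(brk)
    ends = np.append(starts[1:], len(pos))

    regions = []
    for i0, i1 in zip(starts, ends):
        chrom = chroms[i0]
        members = pos[i0:i1]
        regions.append(
            CpGRegion(
                region_id=f"{chrom}:{members[0]}-{members[-1]}",
                chrom=str(chrom),
                start=int(members[0]),
                end=int(members[-1]),
                member_index=tuple(range(i0, i1)),
                member_positions=tuple(int(p) for p in members),
            )
        )
    return regions


def pool_region_counts(
    region: CpGRegion, matrix: MethylomeMatrix, sample_ids: Sequence[str]
) -> tuple[int, int]:
    """Sum meth/unmeth counts over member CpGs and the listed samples."""
    if not sample_ids:
        raise ValueError("at least one sample id required for pooling")
    cols = [matrix.sample_index(s) for s in sample_ids]
    rows = np.asarray(region.member_index)
    meth = int(matrix.meth[np.ix_(rows, cols)].sum())
    unmeth = int(matrix.unmeth[np.ix_(rows, cols)].sum())
    return meth, unmeth


def region_methylation(pooled_meth: int, pooled_unmeth: int) -> float:
    """Coverage-weighted region methylation as a percentage in [0, 100]."""
    cov = pooled_meth + pooled_unmeth
    if cov <= 0:
        raise ValueError("zero pooled coverage")
    return 100.0 * pooled_meth / cov


def region_methylation_unweighted(
    region: CpGRegion, matrix: MethylomeMatrix, sample_ids: Sequence[str]
) -> float:
    """Unweighted mean of per-CpG methylation percentages across members.

    Each member CpG's counts are first pooled across the listed samples, then
    the per-CpG percentages are averaged with equal weight.  Differs from
    :func:`region_methylation` when member coverages are unequal.
    """
    if not sample_ids:
        raise ValueError("at least one sample id required")
    cols = [matrix.sample_index(s) for s in sample_ids]
    rows = np.asarray(region.member_index)
    meth = matrix.meth[np.ix_(rows, cols)].sum(axis=1)
    unmeth = matrix.unmeth[np.ix_(rows, cols)].sum(axis=1)
    cov = meth + unmeth
    if (cov <= 0).any():
        raise ValueError("zero pooled coverage at a member CpG")
    return float(np.mean(100.0 * meth / cov))
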