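"""Joint-locus intersection and the scoreability (coverage) filter.

RRBS libraries cover overlapping but non-identical CpG sets, so a multi-sample
analysis first restricts to loci present in every sample, then keeps only
"scoreable" CpGs: those whose read coverage is strictly greater than the
threshold (default 8, i.e. coverage >= 9) in every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleMethylome

logger = logging.getLogger(__name__)

__all__ = [
    "MethylomeMatrix",
    "intersect_common_loci",
    "filter_scoreable",
    "cpg_methylation",
]


@dataclass
class MethylomeMatrix:
    """Jointly covered CpG loci with per-sample meth/unmeth counts.

    ``loci`` has columns chrom, pos, strictly sorted; ``meth`` and ``unmeth``
    are (n_loci, n_samples) integer arrays with columns in ``sample_ids``
    order.
    """

    loci: pd.DataFrame = field(repr=False)
    sample_ids: list[str]
    groups: list[str]
    meth: np.ndarray = field(repr=False)
    unmeth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n, k = len(self.loci), len(self.sample_ids)
        if self.meth.shape != (n, k) or self.unmeth.shape != (n, k):
            raise ValueError("count array shapes do not match loci/samples")
        if len(self.groups) != k:
            raise ValueError("one group label per sample required")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def group_of(self, sample_id: str) -> str:
        return self.groups[self.sample_index(sample_id)]


def intersect_common_loci(samples: Sequence[SampleMethylome]) -> MethylomeMatrix:
    """Build the matrix of loci present in every input sample.

    Counts are copied unchanged.  An empty intersection is an error: it almost
    always means a coverage or chromosome-naming mismatch between libraries.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to intersect")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")

    common = samples[0].table[["chrom", "pos"]]
    for s in samples[1:]:
        common = common.merge(s.table[["chrom", "pos"]], on=["chrom", "pos"])
    common = common.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    if common.empty:
        raise ValueError(
            "no CpG locus is covered in all samples; check that libraries "
            "share a genome build and chromosome naming (e.g. 'chr1' vs '1')"
        )
    n, k = len(common), len(samples)
    meth = np.empty((n, k), dtype=np.int64)
    unmeth = np.empty((n, k), dtype=np.int64)
    for j, s in enumerate(samples):
        merged = common.merge(s.table, on=["chrom", "pos"], how="left")
        meth[:, j] = merged["meth"].to_numpy()
        unmeth[:, j] = merged["unmeth"].to_numpy()
    logger.info(
        "intersect_common_loci: n_samples=%d n_common_loci=%d", k, n
    )
    return MethylomeMatrix(
        loci=common,
        sample_ids=ids,
        groups=[s.group for s in samples],
        meth=meth,
        unmeth=unmeth,
    )


def filter_scoreable(
    matrix: MethylomeMatrix, min_cov_exclusive: int = 8
) -> MethylomeMatrix:
    """Keep loci with coverage strictly greater than the bound in every sample.

    The default bound 8 retains coverage >= 9.  Idempotent, and monotone in
    the bound: raising it never adds loci.
    """
    if min_cov_exclusive < 0:
        raise ValueError(f"min_cov_exclusive must be >= 0, got {min_cov_exclusive}")
    keep = (matrix.coverage > min_cov_exclusive).all(axis=1)
    n_kept = int(keep.sum())
    logger.info(
        "filter_scoreable: min_cov_exclusive=%d retained=%d dropped=%d",
        min_cov_exclusive,
        n_kept,
        matrix.n_loci - n_kept,
    )
    return MethylomeMatrix(
        loci=matrix.loci.loc[keep].reset_index(drop=True),
        sample_ids=list(matrix.sample_ids),
        groups=list(matrix.groups),
        meth=matrix.meth[keep],
        unmeth=matrix.unmeth[keep],
    )


def cpg_methylation(meth_count: int, unmeth_count: int) -> float:
    """Methylation fraction meth/(meth+unmeth) in [0, 1]."""
    cov = meth_count + unmeth_count
    if cov <= 0:
        raise ValueError("cannot compute methylation of a zero-coverage CpG")
    return meth_count / cov
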