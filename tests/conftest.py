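"""Shared helpers: tiny in-memory matrices, regions and calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rrbsdmr.dmr import DMRCall
from rrbsdmr.regions import CpGRegion
from rrbsdmr.scoring import MethylomeMatrix


def make_matrix(
    loci: list[tuple[str, int]],
    meth,
    unmeth,
    sample_ids=None,
    groups=None,
) -> MethylomeMatrix:
    """Build a MethylomeMatrix from explicit loci and count arrays."""
    meth = np.asarray(meth, dtype=np.int64)
    unmeth = np.asarray(unmeth, dtype=np.int64)
    if meth.ndim == 1:
        meth = meth[:, None]
        unmeth = unmeth[:, None]
    k = meth.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(k)]
    if groups is None:
        groups = ["control"] * (k // 2 + k % 2) + ["treatment"] * (k // 2)
    frame = pd.DataFrame(loci, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    order = frame.index.to_numpy()
    return MethylomeMatrix(
        loci=frame.reset_index(drop=True),
        sample_ids=list(sample_ids),
        groups=list(groups),
        meth=meth[order],
        unmeth=unmeth[order],
    )


def make_region(chrom: str, positions: list[int], index_offset: int = 0) -> CpGRegion:
    positions = sorted(positions)
    return CpGRegion(
        region_id=f"{chrom}:{positions[0]}-{positions[-1]}",
        chrom=chrom,
        start=positions[0],
        end=positions[-1],
        member_index=tuple(range(index_offset, index_offset + len(positions))),
        member_positions=tuple(positions),
    )


def make_call(
    chrom: str, start: int, end: int, delta: float, direction: str
) -> DMRCall:
    region = CpGRegion(
        region_id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        member_index=(0,),
        member_positions=(start,),
    )
    base = 50.0
    return DMRCall(
        region=region,
        meth_control=base,
        meth_treatment=base + delta,
        delta=delta,
        direction=direction,
    )


@pytest.fixture
def two_group_matrix() -> MethylomeMatrix:
    """4 loci x 2 samples with coverage 10 everywhere."""
    loci = [("chr1", 100), ("chr1", 140), ("chr1", 190), ("chr1", 260)]
    meth = [[4, 5], [3, 6], [2, 7], [9, 1]]
    unmeth = [[6, 5], [7, 4], [8, 3], [1, 9]]
    return make_matrix(loci, meth, unmeth, ["ctrl", "trt"], ["control", "treatment"])
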