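"""Differential methylation calling at an absolute percentage-point threshold.

A region is differentially methylated when the pooled treatment methylation
differs from the pooled control methylation by strictly more than the
threshold (default 5 percentage points).  Delta is treatment minus control,
so in a re-expression experiment "decreased upon treatment" is delta < -5.
No statistical test is applied: the method is a pure effect-size threshold,
and the synthetic-data module quantifies the resulting false-call behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .regions import (
    CpGRegion,
    region_methylation,
    region_methylation_unweighted,
)
from .scoring import MethylomeMatrix

__all__ = [
    "ComparisonSpec",
    "DMRCall",
    "DirectionCounts",
    "call_dmrs",
    "delta_histogram",
    "summarize_directions",
]

Direction = Literal["increased", "decreased", "unchanged"]


@dataclass(frozen=True)
class ComparisonSpec:
    """One control-vs-treatment contrast plus the analysis thresholds."""

    comparison_id: str
    control_samples: tuple[str, ...]
    treatment_samples: tuple[str, ...]
    delta_threshold: float = 5.0
    max_gap: int = 50
    min_cov_exclusive: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_samples", tuple(self.control_samples))
        object.__setattr__(self, "treatment_samples", tuple(self.treatment_samples))
        if not self.control_samples or not self.treatment_samples:
            raise ValueError("control and treatment sample sets must be non-empty")
        if set(self.control_samples) & set(self.treatment_samples):
            raise ValueError("control and treatment sample sets overlap")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be > 0")


@dataclass(frozen=True)
class DMRCall:
    """A region with its group methylation levels and classification."""

    region: CpGRegion
    meth_control: float
    meth_treatment: float
    delta: float  # treatment - control, percentage points
    direction: Direction


class DirectionCounts(NamedTuple):
    increased: int
    decreased: int
    unchanged: int


def classify_delta(delta: float, threshold: float) -> Direction:
    """Strict classification: exactly +-threshold is unchanged."""
    if delta > threshold:
        return "increased"
    if delta < -threshold:
        return "decreased"
    return "unchanged"


def call_dmrs(
    regions: Sequence[CpGRegion],
    matrix: MethylomeMatrix,
    spec: ComparisonSpec,
    aggregation: str = "pooled",
) -> list[DMRCall]:
    """Classify every region against the comparison's delta threshold.

    ``aggregation`` selects the region methylation definition: "pooled"
    (coverage-weighted, default) or "mean" (unweighted per-CpG mean).
    Output is sorted by (chrom, start).
    """
    for sid in (*spec.control_samples, *spec.treatment_samples):
        matrix.sample_index(sid)  # raises KeyError for unknown ids
    if aggregation not in ("pooled", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    # per-locus group sums computed once; per region only a small slice is summed
    cols_c = [matrix.sample_index(s) for s in spec.control_samples]
    cols_t = [matrix.sample_index(s) for s in spec.treatment_samples]
    meth_c = matrix.meth[:, cols_c].sum(axis=1)
    unmeth_c = matrix.unmeth[:, cols_c].sum(axis=1)
    meth_t = matrix.meth[:, cols_t].sum(axis=1)
    unmeth_t = matrix.unmeth[:, cols_t].sum(axis=1)

    calls = []
    for region in regions:
        idx = np.asarray(region.member_index)
        if aggregation == "pooled":
            mc = region_methylation(
                int(meth_c[idx].sum()), int(unmeth_c[idx].sum())
            )
            mt = region_methylation(
                int(meth_t[idx].sum()), int(unmeth_t[idx].sum())
            )
        else:
            mc = region_methylation_unweighted(region, matrix, spec.control_samples)
            mt = region_methylation_unweighted(region, matrix, spec.treatment_samples)
        delta = mt - mc
        calls.append(
            DMRCall(
                region=region,
                meth_control=mc,
                meth_treatment=mt,
                delta=delta,
                direction=classify_delta(delta, spec.delta_threshold),
            )
        )
    calls.sort(key=lambda c: (c.region.chrom, c.region.start))
    return calls


def delta_histogram(
    calls: Sequence[DMRCall],
    bin_width: float = 5.0,
    hist_range: tuple[float, float] = (-100.0, 100.0),
) -> pd.DataFrame:
    """Bin deltas into left-closed right-open bins (final bin closed).

    Returns a frame with bin_left, bin_right, count and per-direction
    subtotals; counts sum to the number of calls.
    """
    lo, hi = hist_range
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin_width {bin_width} does not evenly divide range [{lo}, {hi}]"
        )
    edges = np.linspace(lo, hi, int(round(n_bins)) + 1)
    deltas = np.array([c.delta for c in calls], dtype=float)
    counts, _ = np.histogram(deltas, bins=edges)
    inc = np.array([c.delta for c in calls if c.direction == "increased"])
    dec = np.array([c.delta for c in calls if c.direction == "decreased"])
    counts_inc, _ = np.histogram(inc, bins=edges)
    counts_dec, _ = np.histogram(dec, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "count_increased": counts_inc,
            "count_decreased": counts_dec,
        }
    )


def summarize_directions(calls: Sequence[DMRCall]) -> DirectionCounts:
    """Count calls per direction; the three counts sum to len(calls)."""
    inc = sum(1 for c in calls if c.direction == "increased")
    dec = sum(1 for c in calls if c.direction == "decreased")
    return DirectionCounts(
        increased=inc, decreased=dec, unchanged=len(calls) - inc - dec
    )


def calls_to_frame(calls: Sequence[DMRCall], comparison_id: str) -> pd.DataFrame:
    """Flatten calls into the documented DMR table schema."""
    return pd.DataFrame(
        {
            "comparison_id": comparison_id,
            "region_id": [c.region.region_id for c in calls],
            "chrom": [c.region.chrom for c in calls],
            "start": [c.region.start for c in calls],
            "end": [c.region.end for c in calls],
            "n_cpgs": [c.region.n_cpgs for c in calls],
            "meth_control": [c.meth_control for c in calls],
            "meth_treatment": [c.meth_treatment for c in calls],
            "delta": [c.delta for c in calls],
            "direction": [c.direction for c in calls],
        }
    )
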