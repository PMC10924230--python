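"""Synthetic RRBS methylomes with planted differentially methylated regions.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* **Clustered CpG positions** — inter-CpG gaps are a two-scale mixture:
  short within-cluster gaps (mean ``gap_in_mean``) with probability
  ``p_cluster``, long between-cluster gaps (mean ``gap_out_mean``)
  otherwise.  RRBS enriches MspI fragments, so covered CpGs come in dense
  clusters separated by long empty stretches.
* **Overdispersed coverage** — reads per CpG per sample are negative
  binomial (mean ``coverage_mean``, size ``coverage_dispersion``), truncated
  at >= 1: a CpG with zero reads is simply absent from that sample's table,
  exactly as in real Bismark coverage files.
* **Beta-binomial methylation** — each realized CpG cluster draws one
  baseline methylation level mu from a (typically bimodal) beta; methylated
  counts are beta-binomial around mu with concentration ``meth_precision``
  (None = pure binomial, for analytic checks).
* **Planted DMRs** — ``n_planted`` clusters are selected (size within
  ``planted_width_cpgs``, baseline compatible with the full shift) and the
  treatment-group mu is shifted by the planted delta, clamped to
  [0.01, 0.99]; the achieved shift is recorded in the truth table.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .dmr import DMRCall
from .io import GeneModel, SampleMethylome, write_bismark_coverage

__all__ = [
    "SimConfig",
    "TruthRecord",
    "RecoveryMetrics",
    "simulate_gene_annotation",
    "simulate_methylomes",
    "write_fixtures",
    "evaluate_recovery",
]

MU_CLAMP = (0.01, 0.99)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic methylome; defaults are the desk-scale
    study conditions (2 x 10 Mb, ~50k CpGs, 200 planted DMRs)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    # CpG gap mixture
    p_cluster: float = 0.85
    gap_in_mean: float = 12.0
    gap_out_mean: float = 2600.0
    # coverage model
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    # methylation model
    baseline_meth_alpha: float = 0.4
    baseline_meth_beta: float = 0.4
    meth_precision: float | None = 300.0
    # planted DMRs
    n_planted: int = 200
    planted_width_cpgs: tuple[int, int] = (8, 40)
    planted_delta: float = 25.0
    planted_frac_decreased: float = 0.5
    # design
    group_sizes: tuple[int, int] = (1, 1)  # (control, treatment)
    cluster_gap: int = 50
    n_genes: int = 120

    def __post_init__(self) -> None:
        if min(self.gap_in_mean, self.gap_out_mean, self.coverage_mean) <= 0:
            raise ValueError("gap and coverage means must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        if not (0 <= self.p_cluster <= 1):
            raise ValueError("p_cluster must be in [0, 1]")
        if abs(self.planted_delta) > 100:
            raise ValueError("planted_delta magnitude cannot exceed 100")
        if self.meth_precision is not None and self.meth_precision <= 0:
            raise ValueError("meth_precision must be > 0 (or None for binomial)")
        if min(self.group_sizes) < 1:
            raise ValueError("each group needs at least one sample")
        w0, w1 = self.planted_width_cpgs
        if w0 < 1 or w1 < w0:
            raise ValueError("planted_width_cpgs must be a valid integer range")


@dataclass(frozen=True)
class TruthRecord:
    """One planted region with its achieved methylation shift."""

    chrom: str
    start: int
    end: int
    true_delta: float  # achieved shift, percentage points (treatment - control)
    direction: str

    def __post_init__(self) -> None:
        expect = "increased" if self.true_delta > 0 else "decreased"
        if self.true_delta != 0 and self.direction != expect:
            raise ValueError("direction inconsistent with sign of true_delta")


@dataclass
class RecoveryMetrics:
    n_planted: int
    n_detected_any: int
    n_detected_same_direction: int
    sensitivity: float
    direction_accuracy: float
    n_calls_directional: int
    n_calls_true_positive: int
    precision: float
    delta_rmse: float
    confusion: dict = field(default_factory=dict)


def _draw_gaps(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    short = rng.random(n) < config.p_cluster
    g_in = max(config.gap_in_mean, 2.0)
    # short gaps >= 2 bp (CpG dinucleotides cannot overlap), long gaps >= 1
    gaps_in = 1 + rng.geometric(1.0 / (g_in - 1.0), size=n)
    gaps_out = rng.geometric(1.0 / config.gap_out_mean, size=n)
    return np.where(short, gaps_in, gaps_out)


def _chrom_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mean_gap = (
        config.p_cluster * config.gap_in_mean
        + (1 - config.p_cluster) * config.gap_out_mean
    )
    usable = config.chrom_length - 2000
    positions = [np.empty(0, dtype=np.int64)]
    current = 1000
    while current < 1000 + usable:
        n = max(int((1000 + usable - current) / mean_gap * 1.3), 1000)
        gaps = _draw_gaps(n, config, rng)
        new = current + np.cumsum(gaps)
        positions.append(new)
        current = int(new[-1])
    pos = np.concatenate(positions)
    return pos[pos <= 1000 + usable]


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def simulate_gene_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models uniformly in slots.

    Genes are split evenly across chromosomes; each gene occupies a random
    5-20 kb span inside its own slot, with random strand and 2-8 exons.
    Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.n_genes == 0:
        return []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes = []
    for ci in range(config.n_chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot < 12_000:
            raise ValueError(
                f"cannot pack {n} genes into a {config.chrom_length} bp chromosome"
            )
        chrom = _chrom_name(ci)
        max_len = min(20_000, slot - 6_000)
        for gi in range(n):
            length = int(rng.integers(5_000, max_len + 1))
            lo = gi * slot + 2_000
            hi = (gi + 1) * slot - length - 2_000
            start = int(rng.integers(lo, max(hi, lo + 1)))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 9))
            n_cuts = 2 * (n_exons - 1)
            interior = rng.choice(
                np.arange(start + 1, end), size=min(n_cuts, end - start - 1),
                replace=False,
            )
            interior.sort()
            if len(interior) % 2:
                interior = interior[:-1]
            bounds = [start, *interior.tolist(), end]
            exons = tuple(
                (int(bounds[i]), int(bounds[i + 1]))
                for i in range(0, len(bounds) - 1, 2)
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{gi:04d}",
                    chrom=chrom,
                    strand=strand,
                    span_start=start,
                    span_end=end,
                    exons=exons,
                )
            )
    return sorted(genes, key=lambda g: (g.chrom, g.span_start, g.gene_id))


def _cluster_ids(chroms: np.ndarray, pos: np.ndarray, gap: int) -> np.ndarray:
    brk = np.zeros(len(pos), dtype=bool)
    if len(pos):
        brk[0] = True
        brk[1:] = (chroms[1:] != chroms[:-1]) | ((pos[1:] - pos[:-1]) > gap)
    return np.cumsum(brk) - 1


def simulate_methylomes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    planted_filter: Callable[[str, str, int, int], bool] | None = None,
) -> tuple[list[SampleMethylome], list[TruthRecord]]:
    """Generate per-sample CpG tables and the planted-region truth table.

    ``planted_filter(direction, chrom, start, end)`` can restrict which
    clusters are eligible for planting (e.g. to place decreases far from
    TSSs); it defaults to accepting every cluster.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chrom_arrays = []
    pos_arrays = []
    for ci in range(config.n_chroms):
        p = _chrom_positions(config, rng)
        chrom_arrays.append(np.full(len(p), _chrom_name(ci), dtype=object))
        pos_arrays.append(p)
    chroms = np.concatenate(chrom_arrays)
    pos = np.concatenate(pos_arrays)
    n_cpgs = len(pos)

    cluster = _cluster_ids(chroms, pos, config.cluster_gap)
    n_clusters = int(cluster[-1]) + 1 if n_cpgs else 0
    cluster_sizes = np.bincount(cluster, minlength=n_clusters)
    cluster_start_idx = np.searchsorted(cluster, np.arange(n_clusters), side="left")
    cluster_end_idx = np.searchsorted(cluster, np.arange(n_clusters), side="right") - 1

    mu_cluster = rng.beta(
        config.baseline_meth_alpha, config.baseline_meth_beta, size=n_clusters
    )
    mu_cluster = np.clip(mu_cluster, MU_CLAMP[0], MU_CLAMP[1])

    # --- select planted clusters -----------------------------------------
    mag = abs(config.planted_delta) / 100.0
    n_dec = int(round(config.planted_frac_decreased * config.n_planted))
    n_inc = config.n_planted - n_dec
    if config.planted_delta < 0:
        n_dec, n_inc = n_inc, n_dec  # a negative delta flips the mix
    shift_cluster = np.zeros(n_clusters)
    truth: list[TruthRecord] = []
    if config.n_planted and mag > 0:
        w0, w1 = config.planted_width_cpgs
        size_ok = (cluster_sizes >= w0) & (cluster_sizes <= w1)
        available = size_ok.copy()

        def eligible(direction: str, d: float) -> np.ndarray:
            ok = available & (mu_cluster + d >= MU_CLAMP[0]) & (
                mu_cluster + d <= MU_CLAMP[1]
            )
            if planted_filter is not None:
                idx = np.flatnonzero(ok)
                keep = [
                    k
                    for k in idx
                    if planted_filter(
                        direction,
                        str(chroms[cluster_start_idx[k]]),
                        int(pos[cluster_start_idx[k]]),
                        int(pos[cluster_end_idx[k]]),
                    )
                ]
                ok = np.zeros_like(ok)
                ok[keep] = True
            return ok

        for direction, d, count in (
            ("decreased", -mag, n_dec),
            ("increased", +mag, n_inc),
        ):
            if count == 0:
                continue
            pool = np.flatnonzero(eligible(direction, d))
            if len(pool) < count:
                raise ValueError(
                    f"only {len(pool)} clusters eligible for {count} planted "
                    f"{direction} regions; enlarge the genome or relax the config"
                )
            chosen = rng.choice(pool, size=count, replace=False)
            shift_cluster[chosen] = d
            available[chosen] = False
            for k in chosen:
                mu_t = float(np.clip(mu_cluster[k] + d, *MU_CLAMP))
                achieved = (mu_t - mu_cluster[k]) * 100.0
                if abs(achieved - d * 100.0) > 1e-9:
                    warnings.warn(
                        f"planted shift clamped at cluster {k}: achieved "
                        f"{achieved:.2f} instead of {d * 100:.2f}"
                    )
                truth.append(
                    TruthRecord(
                        chrom=str(chroms[cluster_start_idx[k]]),
                        start=int(pos[cluster_start_idx[k]]),
                        end=int(pos[cluster_end_idx[k]]),
                        true_delta=achieved,
                        direction=direction,
                    )
                )
    truth.sort(key=lambda t: (t.chrom, t.start))

    # --- draw counts ------------------------------------------------------
    mu_control = mu_cluster[cluster]
    mu_treatment = np.clip(mu_control + shift_cluster[cluster], *MU_CLAMP)

    n_control, n_treatment = config.group_sizes
    samples: list[SampleMethylome] = []
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    for group, n_samp, mu in (
        ("control", n_control, mu_control),
        ("treatment", n_treatment, mu_treatment),
    ):
        for si in range(n_samp):
            cov = rng.negative_binomial(r, p_nb, size=n_cpgs)
            if config.meth_precision is None or np.isinf(config.meth_precision):
                p = mu
            else:
                c = config.meth_precision
                p = rng.beta(mu * c, (1 - mu) * c)
            meth = rng.binomial(cov, p)
            covered = cov >= 1
            table = pd.DataFrame(
                {
                    "chrom": chroms[covered],
                    "pos": pos[covered],
                    "meth": meth[covered],
                    "unmeth": (cov - meth)[covered],
                }
            )
            samples.append(
                SampleMethylome(
                    sample_id=f"{group}_{si + 1}", group=group, table=table
                )
            )
    return samples, truth


def write_fixtures(
    samples: Sequence[SampleMethylome],
    genes: Sequence[GeneModel],
    truth: Sequence[TruthRecord],
    out_dir: str | Path,
    config: SimConfig | None = None,
    force: bool = False,
) -> dict[str, Path]:
    """Write the full fixture set the pipeline consumes.

    Produces one Bismark ``.cov.gz`` per sample, a BED12 annotation, a
    truth TSV, a sample manifest, and (when given) the config echoed as
    YAML.  Refuses a non-empty output directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    manifest_rows = []
    for s in samples:
        fname = f"{s.sample_id}.cov.gz"
        write_bismark_coverage(s, out_dir / fname)
        paths[s.sample_id] = out_dir / fname
        manifest_rows.append({"sample_id": s.sample_id, "group": s.group, "path": fname})
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    paths["manifest"] = out_dir / "manifest.tsv"

    bed_path = out_dir / "genes.bed"
    with open(bed_path, "wt") as fh:
        for g in genes:
            chrom_start = g.span_start - 1
            sizes = ",".join(str(ee - es + 1) for es, ee in g.exons)
            starts = ",".join(str(es - 1 - chrom_start) for es, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{chrom_start}\t{g.span_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{chrom_start}\t{g.span_end}\t0\t{len(g.exons)}\t"
                f"{sizes},\t{starts},\n"
            )
    paths["genes"] = bed_path

    truth_df = pd.DataFrame(
        [dataclasses.asdict(t) for t in truth],
        columns=["chrom", "start", "end", "true_delta", "direction"],
    )
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.4f")
    paths["truth"] = out_dir / "truth.tsv"

    if config is not None:
        with open(out_dir / "sim_config.yaml", "wt") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
        paths["config"] = out_dir / "sim_config.yaml"
    return paths


def simulate_tss_scenario(
    seed: int = 0,
    far_kb: float = 50.0,
    near_bp: int = 2_000,
    n_planted: int = 200,
) -> tuple[list[GeneModel], list[SampleMethylome], list[TruthRecord]]:
    """A placement scenario separating DMR directions by TSS distance.

    Genes are packed into the first 4 Mb of each 10 Mb chromosome, leaving a
    gene desert; decreases are planted only >= ``far_kb`` from every TSS,
    increases only within ``near_bp`` of a TSS.  Coverage is high and the
    methylation noise binomial, so calls are dominated by the planted signal
    and the distance/context contrast between directions is attributable to
    the placement.  Used to validate the TSS-distance and genomic-context
    analyses against a known spatial ground truth.
    """
    gene_cfg = SimConfig(seed=seed, n_chroms=2, chrom_length=4_000_000, n_genes=300)
    genes = simulate_gene_annotation(gene_cfg)
    meth_cfg = SimConfig(
        seed=seed,
        coverage_mean=3_000,
        meth_precision=None,
        n_planted=n_planted,
        planted_width_cpgs=(3, 80),
    )
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {k: np.sort(np.asarray(v)) for k, v in tss_by_chrom.items()}

    def min_tss_distance(chrom: str, mid: int) -> float:
        arr = tss_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return float("inf")
        i = int(np.searchsorted(arr, mid))
        best = float("inf")
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                best = min(best, abs(mid - int(arr[j])))
        return best

    def placement(direction: str, chrom: str, start: int, end: int) -> bool:
        d = min_tss_distance(chrom, (start + end) // 2)
        if direction == "decreased":
            return d >= far_kb * 1000
        return d <= near_bp

    samples, truth = simulate_methylomes(meth_cfg, planted_filter=placement)
    return genes, samples, truth


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0) + 1)


def evaluate_recovery(
    calls: Sequence[DMRCall], truth: Sequence[TruthRecord]
) -> RecoveryMetrics:
    """Score DMR calls against the planted truth table.

    Sensitivity counts planted regions overlapped by a same-direction call;
    direction accuracy is among planted regions overlapped by any
    directional call; precision is over all directional calls; the delta
    RMSE is over (planted, best same-direction call) pairs, best = largest
    overlap.
    """
    if not truth:
        raise ValueError("empty truth table")
    directional = [c for c in calls if c.direction != "unchanged"]

    n_any = 0
    n_same = 0
    sq_errors = []
    confusion: dict[tuple[str, str], int] = {}
    for t in truth:
        hits = [
            c
            for c in directional
            if c.region.chrom == t.chrom
            and c.region.start <= t.end
            and t.start <= c.region.end
        ]
        same = [c for c in hits if c.direction == t.direction]
        if hits:
            n_any += 1
        if same:
            n_same += 1
            best = max(
                same,
                key=lambda c: _interval_overlap(
                    c.region.start, c.region.end, t.start, t.end
                ),
            )
            sq_errors.append((best.delta - t.true_delta) ** 2)
            call_dir = best.direction
        elif hits:
            call_dir = hits[0].direction
        else:
            call_dir = "none"
        confusion[(t.direction, call_dir)] = confusion.get((t.direction, call_dir), 0) + 1

    n_tp = 0
    for c in directional:
        for t in truth:
            if (
                c.region.chrom == t.chrom
                and c.region.start <= t.end
                and t.start <= c.region.end
                and c.direction == t.direction
            ):
                n_tp += 1
                break

    return RecoveryMetrics(
        n_planted=len(truth),
        n_detected_any=n_any,
        n_detected_same_direction=n_same,
        sensitivity=n_same / len(truth),
        direction_accuracy=n_same / n_any if n_any else float("nan"),
        n_calls_directional=len(directional),
        n_calls_true_positive=n_tp,
        precision=n_tp / len(directional) if directional else float("nan"),
        delta_rmse=float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("nan"),
        confusion=confusion,
    )
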