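"""Readers and writers for the file formats the pipeline touches.

Bismark coverage tables (the 6-column ``*.cov`` files emitted by
``bismark_methylation_extractor``) are the primary input: one line per CpG with
chromosome, 1-based position (start == end for CpG rows), a methylation
percentage, and methylated / unmethylated read counts.  Counts are the source
of truth; the percentage column is only cross-checked.

Gene models come in as BED12 (0-based half-open) or a minimal GTF dialect
(1-based inclusive ``transcript`` + ``exon`` rows).  Internally every
coordinate is 1-based inclusive; BED is converted at the boundary.
Chromosome names are compared as exact strings ("chr1" != "1").
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "CpGSite",
    "SampleMethylome",
    "GeneModel",
    "BismarkParseError",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_gene_models",
    "write_table",
]


class BismarkParseError(ValueError):
    """Raised for malformed or inconsistent Bismark coverage input."""


@dataclass(frozen=True)
class CpGSite:
    """One cytosine locus in one sample, as methylated/unmethylated read counts."""

    chrom: str
    pos: int  # 1-based position of the cytosine
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.meth_count}/{self.unmeth_count})"
            )

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass
class SampleMethylome:
    """All CpG sites of one sample, keyed by (chrom, pos).

    ``table`` has columns chrom (str), pos, meth, unmeth and is kept sorted by
    (chrom, pos); duplicate loci are rejected at construction.
    """

    sample_id: str
    group: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "meth", "unmeth"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        tab = self.table[required].copy()
        tab["chrom"] = tab["chrom"].astype(str)
        for c in ("pos", "meth", "unmeth"):
            tab[c] = tab[c].astype("int64")
        if (tab["meth"] < 0).any() or (tab["unmeth"] < 0).any():
            raise ValueError("negative read counts in sample table")
        if (tab["pos"] < 1).any():
            raise ValueError("CpG positions must be >= 1")
        tab = tab.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if tab.duplicated(["chrom", "pos"]).any():
            dup = tab[tab.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(
                f"duplicate CpG locus {dup['chrom']}:{dup['pos']} "
                f"in sample {self.sample_id}"
            )
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    def sites(self) -> Iterator[CpGSite]:
        """Yield sites in (chrom, pos) order."""
        for row in self.table.itertuples(index=False):
            yield CpGSite(row.chrom, row.pos, row.meth, row.unmeth)


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with exon structure; TSS follows the strand.

    All coordinates are 1-based inclusive.  ``tss`` equals ``span_start`` on
    the + strand and ``span_end`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.span_start > self.span_end:
            raise ValueError(f"inverted span for {self.gene_id}")
        for es, ee in self.exons:
            if es > ee or es < self.span_start or ee > self.span_end:
                raise ValueError(
                    f"exon [{es}, {ee}] outside transcript span "
                    f"[{self.span_start}, {self.span_end}] for {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_coverage(
    path: str | Path, sample_id: str, group: str
) -> SampleMethylome:
    """Parse a Bismark coverage table (plain or .gz) into a SampleMethylome.

    Counts (fields 5-6) win over the percentage field; a percentage deviating
    by more than 0.5 from ``100*meth/(meth+unmeth)`` raises a warning.
    Duplicate loci and malformed lines are errors naming the line number.
    """
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise BismarkParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
            try:
                pos = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise BismarkParseError(f"{path}:{lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise BismarkParseError(
                    f"{path}:{lineno}: negative read count ({meth}/{unmeth})"
                )
            if pos < 1:
                raise BismarkParseError(f"{path}:{lineno}: position {pos} < 1")
            cov = meth + unmeth
            if cov > 0 and abs(pct - 100.0 * meth / cov) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: reported methylation {pct}% disagrees "
                    f"with counts {meth}/{unmeth}; counts win",
                    stacklevel=2,
                )
            chroms.append(chrom)
            poss.append(pos)
            meths.append(meth)
            unmeths.append(unmeth)
    table = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "meth": meths, "unmeth": unmeths}
    )
    try:
        return SampleMethylome(sample_id=sample_id, group=group, table=table)
    except ValueError as exc:
        raise BismarkParseError(f"{path}: {exc}") from None


def write_bismark_coverage(sample: SampleMethylome, path: str | Path) -> None:
    """Write a sample back out in 6-column Bismark coverage layout (.gz aware).

    The percentage column is recomputed from counts to 2 decimals; zero-coverage
    sites (which Bismark never emits) are written with percentage 0.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for row in sample.table.itertuples(index=False):
            cov = row.meth + row.unmeth
            pct = 100.0 * row.meth / cov if cov else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.2f}\t"
                f"{row.meth}\t{row.unmeth}\n"
            )


def _parse_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            block_sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(block_sizes) != int(f[9]) or len(block_starts) != int(f[9]):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            # 0-based half-open -> 1-based inclusive
            span_start = chrom_start + 1
            span_end = chrom_end
            exons = tuple(
                (chrom_start + bs + 1, chrom_start + bs + sz)
                for bs, sz in zip(block_starts, block_sizes)
            )
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    span_start=span_start,
                    span_end=span_end,
                    exons=exons,
                )
            )
    return models


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().strip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) + 1 :].strip().strip('"')
    return None


def _parse_gtf_lite(path: str | Path) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GTF needs 9 fields, got {len(f)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = f[:9]
            if feature not in ("transcript", "exon"):
                continue
            tid = _gtf_attr(attrs, "transcript_id") or _gtf_attr(attrs, "gene_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: no transcript_id/gene_id attribute")
            rec = transcripts.setdefault(
                tid, {"chrom": chrom, "strand": strand, "span": None, "exons": []}
            )
            if tid not in order:
                order.append(tid)
            if feature == "transcript":
                rec["span"] = (int(start), int(end))
            else:
                rec["exons"].append((int(start), int(end)))
    models = []
    for tid in order:
        rec = transcripts[tid]
        if rec["span"] is None:
            if not rec["exons"]:
                continue
            rec["span"] = (
                min(s for s, _ in rec["exons"]),
                max(e for _, e in rec["exons"]),
            )
        models.append(
            GeneModel(
                gene_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                span_start=rec["span"][0],
                span_end=rec["span"][1],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return models


def read_gene_models(path: str | Path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GTF-lite, normalized to 1-based inclusive.

    Returned models are sorted by (chrom, span_start, gene_id).
    """
    dialect = dialect.lower().replace("-", "").replace("_", "")
    if dialect == "bed12":
        models = _parse_bed12(path)
    elif dialect in ("gtf", "gtflite"):
        models = _parse_gtf_lite(path)
    else:
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    return sorted(models, key=lambda g: (g.chrom, g.span_start, g.gene_id))


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a tabular output as TSV with a header; floats to 4 decimals.

    Coordinates are written as stored (1-based inclusive).  When ``sort_by``
    is given the rows are sorted stably on those columns first, so the file
    order is deterministic regardless of upstream ordering.
    """
    df = records.copy()
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
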