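"""Region reports: bp spans in Mb and gene content from BED annotation.

All coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read.  Overlap means at least one shared base —
no minimum-fraction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .roh_scan import HomozygousRun

logger = logging.getLogger(__name__)


def span_mb(start_bp: int, end_bp: int) -> float:
    """Inclusive span in megabases, rounded half-up to 2 decimals.

    span_mb(109334543, 115285275) == 5.95; span_mb(118884834, 119587883) == 0.70.
    """
    if end_bp < start_bp:
        raise ValueError(f"reversed coordinates ({start_bp} > {end_bp})")
    mb = Decimal(int(end_bp) - int(start_bp) + 1) / Decimal(10**6)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneSet:
    """Gene intervals (chromosome, start_bp, end_bp, gene_name), 1-based
    inclusive.  Names need not be unique (multi-part genes allowed)."""

    intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self):
        for chrom, start, end, name in self.intervals:
            if end < start:
                raise ValueError(f"gene {name!r}: start {start} > end {end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def on_chromosome(self, chrom: str) -> list[tuple[str, int, int, str]]:
        return [iv for iv in self.intervals if iv[0] == str(chrom)]


def read_bed(path) -> GeneSet:
    """Read gene intervals from BED (0-based half-open), converting to
    1-based inclusive.  Column 4, if present, is the gene name."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    names = (
        df.iloc[:, 3].astype(str)
        if df.shape[1] >= 4
        else pd.Series([f"feature_{i}" for i in range(len(df))])
    )
    intervals = tuple(
        (str(c), int(s) + 1, int(e), str(n))
        for c, s, e, n in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2], names)
    )
    logger.info("read %d BED intervals (converted 0-based half-open -> 1-based inclusive)", len(intervals))
    return GeneSet(intervals)


@dataclass(frozen=True)
class RegionReport:
    """One homozygous run annotated with its Mb span and overlapping genes."""

    run: HomozygousRun
    span_bp: int
    span_mb: float
    genes: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    @property
    def chromosome(self) -> str:
        return self.run.chromosome

    @property
    def start_bp(self) -> int:
        return self.run.start_bp

    @property
    def end_bp(self) -> int:
        return self.run.end_bp

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def report_region(run: HomozygousRun, genes: GeneSet | None = None) -> RegionReport:
    report = RegionReport(
        run=run,
        span_bp=run.end_bp - run.start_bp + 1,
        span_mb=span_mb(run.start_bp, run.end_bp),
    )
    if genes is not None:
        return RegionReport(
            run=report.run,
            span_bp=report.span_bp,
            span_mb=report.span_mb,
            genes=tuple(genes_in_region(report, genes)),
        )
    return report


def genes_in_region(region, genes: GeneSet) -> list[tuple[str, int, int]]:
    """All gene intervals overlapping the region (closed-interval
    intersection, >= 1 shared bp), sorted by start position.

    ``region`` is a RegionReport or HomozygousRun (anything exposing
    chromosome/start_bp/end_bp).
    """
    chrom = str(region.chromosome)
    lo, hi = int(region.start_bp), int(region.end_bp)
    hits = [
        (name, start, end)
        for _, start, end, name in genes.on_chromosome(chrom)
        if start <= hi and end >= lo
    ]
    hits.sort(key=lambda g: (g[1], g[2], g[0]))
    return hits


def separation_bp(earlier: HomozygousRun, later: HomozygousRun) -> int:
    """Gap between two runs: start of the later minus end of the earlier.

    Non-negative for disjoint runs in genomic order; computed from the
    boundary coordinates, not any printed summary.
    """
    return int(later.start_bp) - int(earlier.end_bp)


REGION_TSV_COLUMNS = (
    "chromosome",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_informative",
    "span_bp",
    "span_mb",
    "carrier_pass",
    "n_genes",
)


def write_regions_tsv(runs, path, genes: GeneSet | None = None) -> None:
    """Write runs (or RegionReports) as a TSV region table."""
    rows = []
    for item in runs:
        report = item if isinstance(item, RegionReport) else report_region(item, genes)
        run = report.run
        rows.append(
            {
                "chromosome": run.chromosome,
                "start_bp": run.start_bp,
                "end_bp": run.end_bp,
                "n_snps": run.n_snps,
                "n_informative": run.n_informative,
                "span_bp": report.span_bp,
                "span_mb": f"{report.span_mb:.2f}",
                "carrier_pass": _fmt_verdict(run.carrier_pass),
                "n_genes": report.n_genes if genes is not None else "",
            }
        )
    pd.DataFrame(rows, columns=REGION_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def _fmt_verdict(value: bool | None) -> str:
    return "undetermined" if value is None else str(value)
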