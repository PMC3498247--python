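"""Per-base coverage audit of candidate disease genes.

For an autosomal dominant disorder a heterozygous variant can only be called
at a base with enough high-quality reads, so a coverage *gap* in a known
disease gene can silently hide the causal mutation.  This module classifies
every base of each gene's CCDS+splice region (coding exons expanded by a
10-base splice flank on both sides, overlapping expansions merged) as passed
or failed per sample:

    failed  <=>  depth < depth_min  (default 10 filter-passing reads)
             or  site_qual < qual_min  (default 50)

"and/or" is an inclusive OR, and a base with no emitted record at all is
failed (the caller emits only confident sites, so absence means
non-confident).  Counts are aggregated per gene into per-sample failed
fractions and an all-samples failed fraction (bases failed in *every*
sample), with percentages rounded half-up to 2 decimals.

Coordinates are 1-based inclusive internally; BED input is converted from
0-based half-open on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_store import normalize_chrom


def round_half_up(value: float | Decimal, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value) if not isinstance(value, Decimal) else value)
                 .quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact-decimal percentage 100*num/den, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(numerator * 100) / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AuditConfig:
    """Thresholds of the failed-position definition.

    depth_min: minimum filter-passing reads (default 10).
    qual_min: minimum site confidence score (default 50).
    flank: splice-region width added on each side of every exon (default 10).
    report_thresholds: failed-percentage thresholds for summary reports.
    """

    depth_min: int = 10
    qual_min: float = 50.0
    flank: int = 10
    report_thresholds: tuple[float, ...] = (30.0, 50.0)

    def __post_init__(self) -> None:
        if self.depth_min <= 0 or self.qual_min <= 0 or self.flank <= 0:
            raise ValueError("depth_min, qual_min and flank must be strictly positive")
        if any(t <= 0 for t in self.report_thresholds):
            raise ValueError("report thresholds must be strictly positive")


@dataclass
class GeneIntervals:
    """Merged 1-based inclusive CCDS+splice intervals of one gene."""

    gene: str
    intervals: list[tuple[str, int, int]]

    @property
    def total_bases(self) -> int:
        return sum(end - start + 1 for _, start, end in self.intervals)

    def bases(self) -> Iterable[tuple[str, int]]:
        for chrom, start, end in self.intervals:
            for pos in range(start, end + 1):
                yield chrom, pos


def build_ccds_splice_intervals(
    gene: str,
    exons: Sequence[tuple[str, int, int]],
    flank: int = 10,
) -> GeneIntervals:
    """Expand each exon by ``flank`` bases on both sides and merge overlaps.

    Exons are (chrom, start, end) 1-based inclusive, all on one chromosome;
    the merged union guarantees no base is double-counted even when expanded
    exons overlap.  Expanded starts are clamped at position 1.
    """
    if not exons:
        return GeneIntervals(gene=gene, intervals=[])
    chroms = {normalize_chrom(c) for c, _, _ in exons}
    if len(chroms) > 1:
        raise ValueError(f"gene {gene}: exons span multiple chromosomes {sorted(chroms)}")
    chrom = chroms.pop()
    expanded = []
    for _, start, end in exons:
        if start > end:
            raise ValueError(f"gene {gene}: exon start {start} > end {end}")
        expanded.append((max(1, start - flank), end + flank))
    expanded.sort()
    merged: list[list[int]] = [list(expanded[0])]
    for start, end in expanded[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return GeneIntervals(gene=gene, intervals=[(chrom, s, e) for s, e in merged])


def load_gene_models(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Load per-gene exon coordinates from a 4-column TSV or a BED file.

    TSV columns: gene, chrom, start, end (1-based inclusive).  BED (``.bed``)
    rows are chrom, start, end, gene with 0-based half-open coordinates,
    converted on load.  Rows whose gene symbol is flagged ``withdrawn``
    (5th TSV column ``status``) are dropped before interval building.
    """
    path = Path(path)
    models: dict[str, list[tuple[str, int, int]]] = {}
    if path.suffix == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            models.setdefault(gene.upper(), []).append((normalize_chrom(chrom), start0 + 1, int(end)))
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if "status" in df.columns:
            df = df[df["status"].str.lower() != "withdrawn"]
        for row in df.itertuples(index=False):
            models.setdefault(str(row.gene).upper(), []).append(
                (normalize_chrom(str(row.chrom)), int(row.start), int(row.end)))
    return models


def classify_base(depth: int | None, site_qual: float | None, config: AuditConfig) -> bool:
    """True when the base is *failed* (insufficient depth and/or quality).

    A base with no quality score (no confident-site record emitted) is failed.
    """
    if depth is None or site_qual is None:
        return True
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return depth < config.depth_min or site_qual < config.qual_min


class BaseTrack:
    """Per-sample (chrom, pos) -> (depth, site_qual) lookup."""

    def __init__(self, records: Mapping[tuple[str, int], tuple[int, float]]):
        self._records = {(normalize_chrom(c), p): v for (c, p), v in records.items()}
        self.chroms = {c for c, _ in self._records}

    def lookup(self, chrom: str, pos: int) -> tuple[int, float] | None:
        return self._records.get((normalize_chrom(chrom), pos))

    def __len__(self) -> int:
        return len(self._records)


def load_track(path: str | Path) -> BaseTrack:
    """Load a per-base track TSV with columns chrom, pos, depth, qual."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = {
        (str(c), int(p)): (int(d), float(q))
        for c, p, d, q in zip(df["chrom"], df["pos"], df["depth"], df["qual"])
    }
    return BaseTrack(records)


@dataclass
class GeneCoverageReport:
    """Failed-base counts and percentages for one gene.

    ``failed_all_samples`` counts bases failed in *every* sample; it can never
    exceed any single sample's failed count.
    """

    gene: str
    total_bases: int
    failed_per_sample: dict[str, int]
    failed_all_samples: int
    pct_per_sample: dict[str, float] = field(default_factory=dict)
    pct_all_samples: float = 0.0

    @classmethod
    def from_counts(
        cls,
        gene: str,
        total_bases: int,
        failed_per_sample: Mapping[str, int],
        failed_all_samples: int,
    ) -> "GeneCoverageReport":
        return cls(
            gene=gene,
            total_bases=total_bases,
            failed_per_sample=dict(failed_per_sample),
            failed_all_samples=failed_all_samples,
            pct_per_sample={
                s: percent(n, total_bases) for s, n in failed_per_sample.items()
            },
            pct_all_samples=percent(failed_all_samples, total_bases),
        )


def audit_gene(
    intervals: GeneIntervals,
    tracks: Mapping[str, BaseTrack],
    config: AuditConfig,
) -> GeneCoverageReport:
    """Classify every interval base in every sample and aggregate per gene.

    A base absent from a sample's track is failed for that sample.  A track
    that is non-empty yet shares no chromosome with the gene indicates a
    naming mismatch and raises :class:`ValueError`.
    """
    gene_chroms = {c for c, _, _ in intervals.intervals}
    for sample, track in tracks.items():
        if intervals.intervals and len(track) and not (track.chroms & gene_chroms):
            raise ValueError(
                f"track for sample {sample!r} has no data on chromosome(s) "
                f"{sorted(gene_chroms)} of gene {intervals.gene}")
    failed_per_sample = {s: 0 for s in tracks}
    failed_all = 0
    for chrom, pos in intervals.bases():
        n_failed = 0
        for sample, track in tracks.items():
            rec = track.lookup(chrom, pos)
            failed = classify_base(rec[0], rec[1], config) if rec else True
            if failed:
                failed_per_sample[sample] += 1
                n_failed += 1
        if tracks and n_failed == len(tracks):
            failed_all += 1
    return GeneCoverageReport.from_counts(
        intervals.gene, intervals.total_bases, failed_per_sample, failed_all)


def genes_exceeding(
    reports: Sequence[GeneCoverageReport],
    threshold: float,
    scope: str = "any-sample",
) -> list[str]:
    """Genes whose failed percentage meets ``threshold`` under ``scope``.

    ``any-sample``: the max per-sample percentage >= threshold (the gene was
    inadequately screened in at least one individual).  ``all-samples``: the
    failed-in-every-sample percentage >= threshold.
    """
    out = []
    for rep in reports:
        if scope == "any-sample":
            value = max(rep.pct_per_sample.values(), default=0.0)
        elif scope == "all-samples":
            value = rep.pct_all_samples
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if value >= threshold:
            out.append(rep.gene)
    return sorted(out)


def overall_failed_fraction(reports: Sequence[GeneCoverageReport]) -> float:
    """Percentage of all gene-set bases failed in every sample (1 decimal)."""
    total = sum(r.total_bases for r in reports)
    if total == 0:
        raise ValueError("gene set has zero total bases")
    failed = sum(r.failed_all_samples for r in reports)
    return float((Decimal(failed * 100) / Decimal(total))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Published benchmark: per-gene coverage of 24 poorly covered muscle genes
# ---------------------------------------------------------------------------

def load_coverage_benchmark() -> pd.DataFrame:
    """Published per-gene CCDS+splice coverage benchmark.

    24 muscle-disease genes in which >=30% of CCDS+splice bases failed
    (<10 reads and/or site quality <50) in at least one of five affected
    exomes from two dominant limb-girdle muscular dystrophy families.
    Columns: gene, total_bases, failed_all_cases (bases failed in all five
    exomes), pct_all_cases, and the five per-exome failed percentages.
    """
    with resources.files("famexome.data").joinpath(
            "muscle_gene_coverage_benchmark.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def benchmark_reports() -> list[GeneCoverageReport]:
    """The benchmark table as :class:`GeneCoverageReport` objects.

    The all-samples percentage is *recomputed* from the printed base counts;
    per-sample percentages are taken as printed (their underlying counts were
    not published).
    """
    df = load_coverage_benchmark()
    sample_cols = [c for c in df.columns if c.startswith("pct_case_")]
    reports = []
    for row in df.itertuples(index=False):
        pct_per_sample = {c.removeprefix("pct_"): float(getattr(row, c)) for c in sample_cols}
        reports.append(GeneCoverageReport(
            gene=row.gene,
            total_bases=int(row.total_bases),
            failed_per_sample={},
            failed_all_samples=int(row.failed_all_cases),
            pct_per_sample=pct_per_sample,
            pct_all_samples=percent(int(row.failed_all_cases), int(row.total_bases)),
        ))
    return reports
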