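"""Data model and I/O for multi-sample variant tables, frequency panels and gene lists.

Variants are identified by (chromosome, position, ref allele, alt allele),
with chromosome names normalized by stripping a leading ``chr``.  Multi-allelic
VCF records are split into one record per alternate allele before anything else
touches them, so that population-frequency joins and control-exome exclusion
are allele-specific.

Two on-disk dialects are supported for variant tables:

* VCF 4.x, with functional annotation in the INFO keys ``GENE`` (gene symbol),
  ``FUNC`` (comma-separated functional terms) and ``DTS`` (distance to the
  nearest splice junction in bases), and per-sample ``GT:AD:DP``.
* a flat TSV with columns ``chrom, pos, ref, alt, gene, annotation,
  distance_to_splice, qual`` followed by ``<sample>.GT``, ``<sample>.AD`` and
  ``<sample>.DP`` columns per sample (``AD`` as "ref,alt").

Frequency panels are 5-column TSVs (``chrom, pos, ref, alt, freq``) and gene
sets are one-symbol-per-line text files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y"})

HOM_REF = "hom-ref"
HET = "het"
HOM_ALT = "hom-alt"
MISSING = "missing"
_GT_VALUES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr2`` and ``2`` are one name."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Allele-level variant identity: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(str(self.chrom)))
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_sex_chromosome(self) -> bool:
        return self.chrom in SEX_CHROMOSOMES

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse ``chrom:pos:ref:alt`` (e.g. ``2:220285071:A:G``)."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected chrom:pos:ref:alt, got {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref.upper(), alt.upper())


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one variant.

    ``gt`` is one of ``hom-ref``, ``het``, ``hom-alt`` or ``missing``.
    ``allele_depth`` is the (ref reads, alt reads) pair, ``depth`` the total
    filter-passing read count and ``site_qual`` the caller's site confidence;
    all three are optional.  No depth or quality is ever *required*: the
    filtering cascade deliberately applies no read-support thresholds.
    """

    gt: str
    allele_depth: tuple[int, int] | None = None
    depth: int | None = None
    site_qual: float | None = None

    def __post_init__(self) -> None:
        if self.gt not in _GT_VALUES:
            raise ValueError(f"unknown genotype {self.gt!r}")

    @property
    def carries_alt(self) -> bool:
        """True when the sample carries at least one alternate allele."""
        return self.gt in (HET, HOM_ALT)

    @property
    def is_missing(self) -> bool:
        return self.gt == MISSING


@dataclass
class AnnotatedVariant:
    """A called variant with functional annotation and per-sample genotypes."""

    key: VariantKey
    gene: str = ""
    annotation_terms: frozenset[str] = field(default_factory=frozenset)
    distance_to_splice: int | None = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene = self.gene.upper() if self.gene else ""
        self.annotation_terms = frozenset(t.lower() for t in self.annotation_terms)
        if not self.annotation_terms:
            raise ValueError(f"variant {self.key} has no annotation terms")
        if self.distance_to_splice is not None and self.distance_to_splice < 0:
            raise ValueError("distance_to_splice must be non-negative")

    @property
    def variant_class(self) -> str:
        return "indel" if self.key.is_indel else "SNV"

    def genotype(self, sample_id: str) -> GenotypeCall:
        return self.genotypes.get(sample_id, GenotypeCall(MISSING))

    def found_in_any(self, sample_ids: Iterable[str]) -> bool:
        return any(self.genotype(s).carries_alt for s in sample_ids)


@dataclass
class FrequencyPanel:
    """A population alternate-allele frequency table keyed by variant."""

    name: str
    freqs: dict[VariantKey, float] = field(default_factory=dict)

    def frequency(self, key: VariantKey) -> float | None:
        """Panel frequency for ``key``, or None when the panel lacks it."""
        return self.freqs.get(key)

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class CandidateGeneSet:
    """A case-normalized, duplicate-free set of candidate gene symbols."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("candidate gene set must be non-empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Genotype encoding helpers (VCF tuple <-> call, TSV string <-> call)
# ---------------------------------------------------------------------------

def _gt_from_alleles(alleles: tuple[int | None, ...] | None, alt_index: int) -> str:
    """Classify a VCF GT tuple relative to one alternate allele.

    The genotype is expressed as the number of copies of ``alt_index`` the
    sample carries; alleles pointing at *other* alternates at a multi-allelic
    site count as non-carrier for this split record.
    """
    if alleles is None or all(a is None for a in alleles):
        return MISSING
    copies = sum(1 for a in alleles if a == alt_index)
    if copies == 0:
        return HOM_REF
    if copies == 1:
        return HET
    return HOM_ALT

_GT_TO_VCF = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
_GT_TO_TSV = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_TSV_TO_GT = {v: k for k, v in _GT_TO_TSV.items()}


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_variant_table(path: str | Path, sample_ids: Sequence[str]) -> list[AnnotatedVariant]:
    """Load a multi-sample variant table (VCF or the flat TSV dialect).

    Returns one :class:`AnnotatedVariant` per (site, alternate allele); a
    multi-allelic VCF record is split into per-alt records sharing chrom, pos
    and ref.  Every requested sample gets a genotype (``missing`` when the
    file has none).  An unknown sample id raises :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".tsv", ".txt"):
        return _load_tsv(path, sample_ids)
    return _load_vcf(path, sample_ids)


def _load_vcf(path: Path, sample_ids: Sequence[str]) -> list[AnnotatedVariant]:
    vcf = pysam.VariantFile(str(path))
    present = set(vcf.header.samples)
    unknown = [s for s in sample_ids if s not in present]
    if unknown:
        raise ValueError(f"sample id(s) {unknown} not present in {path}")
    out: list[AnnotatedVariant] = []
    for n, rec in enumerate(vcf, start=1):
        try:
            out.extend(_split_record(rec, sample_ids))
        except Exception as exc:  # noqa: BLE001 - re-raise with record context
            raise ValueError(f"malformed record #{n} in {path}: {exc}") from exc
    vcf.close()
    return out


def _split_record(rec: "pysam.VariantRecord", sample_ids: Sequence[str]) -> list[AnnotatedVariant]:
    gene = rec.info.get("GENE", "")
    func = rec.info.get("FUNC", ())
    if isinstance(func, str):
        func = (func,)
    terms = frozenset(t for item in func for t in str(item).split(",") if t)
    dts = rec.info.get("DTS")
    dts = int(dts) if dts is not None else None
    qual = float(rec.qual) if rec.qual is not None else None
    variants = []
    alts = rec.alts or ()
    for i, alt in enumerate(alts, start=1):
        key = VariantKey(rec.chrom, rec.pos, rec.ref.upper(), str(alt).upper())
        genotypes: dict[str, GenotypeCall] = {}
        for sid in sample_ids:
            fmt = rec.samples[sid]
            gt = _gt_from_alleles(fmt.get("GT"), i)
            ad = fmt.get("AD")
            allele_depth = None
            if ad is not None and len(ad) > i and ad[0] is not None and ad[i] is not None:
                allele_depth = (int(ad[0]), int(ad[i]))
            dp = fmt.get("DP")
            genotypes[sid] = GenotypeCall(
                gt,
                allele_depth=allele_depth,
                depth=int(dp) if dp is not None else None,
                site_qual=qual,
            )
        variants.append(
            AnnotatedVariant(key, gene=str(gene), annotation_terms=terms,
                             distance_to_splice=dts, genotypes=genotypes)
        )
    return variants


def _load_tsv(path: Path, sample_ids: Sequence[str]) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for sid in sample_ids:
        if f"{sid}.GT" not in df.columns:
            raise ValueError(f"sample id {sid!r} not present in {path}")
    out: list[AnnotatedVariant] = []
    for n, (_, row) in enumerate(df.iterrows(), start=2):  # header = line 1
        try:
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"].upper(), row["alt"].upper())
            dts_raw = row.get("distance_to_splice", "")
            dts = int(dts_raw) if dts_raw != "" else None
            qual_raw = row.get("qual", "")
            qual = float(qual_raw) if qual_raw != "" else None
            genotypes = {}
            for sid in sample_ids:
                gt = _TSV_TO_GT[row[f"{sid}.GT"]]
                ad_raw = row.get(f"{sid}.AD", "")
                ad = None
                if ad_raw:
                    ref_reads, alt_reads = ad_raw.split(",")
                    ad = (int(ref_reads), int(alt_reads))
                dp_raw = row.get(f"{sid}.DP", "")
                dp = int(dp_raw) if dp_raw else None
                genotypes[sid] = GenotypeCall(gt, allele_depth=ad, depth=dp, site_qual=qual)
            out.append(AnnotatedVariant(
                key, gene=row.get("gene", ""),
                annotation_terms=frozenset(t for t in row["annotation"].split(",") if t),
                distance_to_splice=dts, genotypes=genotypes))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed record at line {n} of {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_variant_table(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    sample_ids: Sequence[str],
) -> None:
    """Write variants as VCF (``.vcf``) or the flat TSV dialect (``.tsv``)."""
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        _write_tsv(variants, path, sample_ids)
    else:
        _write_vcf(variants, path, sample_ids)


def _write_vcf(variants: Sequence[AnnotatedVariant], path: Path, sample_ids: Sequence[str]) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=FUNC,Number=.,Type=String,Description="Functional annotation terms">')
    header.add_line('##INFO=<ID=DTS,Number=1,Type=Integer,Description="Distance to nearest splice junction (bp)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    chrom_max: dict[str, int] = {}
    for v in variants:
        chrom_max[v.key.chrom] = max(chrom_max.get(v.key.chrom, 0), v.key.pos)

    def _chrom_sort(c: str) -> tuple[int, str]:
        return (0, f"{int(c):09d}") if c.isdigit() else (1, c)

    for chrom in sorted(chrom_max, key=_chrom_sort):
        header.contigs.add(chrom, length=chrom_max[chrom] + 10_000)
    for sid in sample_ids:
        header.add_sample(sid)

    out = pysam.VariantFile(str(path), "w", header=header)
    for v in sorted(variants, key=lambda v: (_chrom_sort(v.key.chrom), v.key.pos, v.key.ref, v.key.alt)):
        quals = [g.site_qual for g in v.genotypes.values() if g.site_qual is not None]
        rec = out.new_record(
            contig=v.key.chrom,
            start=v.key.pos - 1,
            stop=v.key.pos - 1 + len(v.key.ref),
            alleles=(v.key.ref, v.key.alt),
            qual=quals[0] if quals else None,
        )
        if v.gene:
            rec.info["GENE"] = v.gene
        rec.info["FUNC"] = ",".join(sorted(v.annotation_terms))
        if v.distance_to_splice is not None:
            rec.info["DTS"] = v.distance_to_splice
        for sid in sample_ids:
            call = v.genotype(sid)
            rec.samples[sid]["GT"] = _GT_TO_VCF[call.gt]
            if call.allele_depth is not None:
                rec.samples[sid]["AD"] = call.allele_depth
            if call.depth is not None:
                rec.samples[sid]["DP"] = call.depth
        out.write(rec)
    out.close()


def _write_tsv(variants: Sequence[AnnotatedVariant], path: Path, sample_ids: Sequence[str]) -> None:
    rows = []
    for v in variants:
        quals = [g.site_qual for g in v.genotypes.values() if g.site_qual is not None]
        row: dict[str, object] = {
            "chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
            "gene": v.gene, "annotation": ",".join(sorted(v.annotation_terms)),
            "distance_to_splice": "" if v.distance_to_splice is None else v.distance_to_splice,
            "qual": "" if not quals else quals[0],
        }
        for sid in sample_ids:
            call = v.genotype(sid)
            row[f"{sid}.GT"] = _GT_TO_TSV[call.gt]
            row[f"{sid}.AD"] = "" if call.allele_depth is None else f"{call.allele_depth[0]},{call.allele_depth[1]}"
            row[f"{sid}.DP"] = "" if call.depth is None else call.depth
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Frequency panels and gene sets
# ---------------------------------------------------------------------------

def load_frequency_panel(path: str | Path, name: str) -> FrequencyPanel:
    """Load a 5-column TSV (chrom, pos, ref, alt, freq) frequency panel.

    Duplicate keys are resolved last-wins with a logged warning; a frequency
    outside [0, 1] raises :class:`ValueError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel {path} missing columns {sorted(required - set(df.columns))}")
    freqs: dict[VariantKey, float] = {}
    for row in df.itertuples(index=False):
        freq = float(row.freq)
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"frequency {freq} outside [0,1] in panel {name} at {row.chrom}:{row.pos}")
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref).upper(), str(row.alt).upper())
        if key in freqs:
            log.warning("panel %s: duplicate key %s, keeping last frequency %s", name, key, freq)
        freqs[key] = freq
    return FrequencyPanel(name=name, freqs=freqs)


def write_frequency_panel(panel: FrequencyPanel, path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "freq": f}
        for k, f in sorted(panel.freqs.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "freq"]).to_csv(
        path, sep="\t", index=False)


def load_gene_set(path: str | Path) -> CandidateGeneSet:
    """Load a one-symbol-per-line gene list (case-normalized, deduplicated)."""
    symbols = [line.strip() for line in Path(path).read_text().splitlines()]
    symbols = [s for s in symbols if s and not s.startswith("#")]
    return CandidateGeneSet(frozenset(symbols))


def write_gene_set(genes: CandidateGeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes.genes)) + "\n")


# ---------------------------------------------------------------------------
# Merging per-case call sets
# ---------------------------------------------------------------------------

def merge_family_calls(
    per_case_tables: Sequence[Sequence[AnnotatedVariant]],
) -> list[AnnotatedVariant]:
    """Union per-case variant tables by :class:`VariantKey`.

    Genotype maps are merged; a sample genotyped discordantly (two different
    non-missing calls) for the same variant raises :class:`ValueError`.
    Output is sorted by key; idempotent and order-independent.
    """
    merged: dict[VariantKey, AnnotatedVariant] = {}
    for table in per_case_tables:
        for v in table:
            existing = merged.get(v.key)
            if existing is None:
                merged[v.key] = AnnotatedVariant(
                    v.key, gene=v.gene, annotation_terms=v.annotation_terms,
                    distance_to_splice=v.distance_to_splice, genotypes=dict(v.genotypes))
                continue
            for sid, call in v.genotypes.items():
                prior = existing.genotypes.get(sid)
                if prior is not None and not prior.is_missing and not call.is_missing \
                        and prior.gt != call.gt:
                    raise ValueError(
                        f"conflicting genotypes for sample {sid} at {v.key}: "
                        f"{prior.gt} vs {call.gt}")
                if prior is None or prior.is_missing:
                    existing.genotypes[sid] = call
            existing.annotation_terms = existing.annotation_terms | v.annotation_terms
            if existing.distance_to_splice is None:
                existing.distance_to_splice = v.distance_to_splice
    return [merged[k] for k in sorted(merged)]
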