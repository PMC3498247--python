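"""Synthetic family-exome bundles with planted truth.

Generates everything the triage pipeline consumes — pedigree, multi-sample
annotated variant table, population frequency panels, candidate gene set,
gene exon models and per-base coverage tracks — for a nuclear family with an
autosomal dominant myopathy, so that the filtering cascade, coverage audit
and segregation test can be exercised and verified without any sequencing
data.

The generator's statistical structure mirrors a dominant family-exome study
design:

* One causal variant is planted, by default emulating a non-canonical splice
  mutation: an *intronic* annotation 3 bases from the exon boundary in a
  candidate gene, shared heterozygous by all cases, absent from controls and
  from both frequency panels.  This is precisely the variant class that a
  functional-term filter alone would discard and that the
  distance-to-splice rule recovers.
* Optionally one false-positive artifact is planted: a missense call shared
  by all cases that orthogonal confirmation shows to be homozygous reference
  everywhere (or an untestable homopolymer-context indel).
* Background variants come in a common stratum — panel frequency drawn in
  [0.01, 0.5], genotypes sampled per sample from Hardy-Weinberg proportions
  at that frequency, so panels and family genotypes are mutually consistent —
  and a rare stratum with explicit control-artifact and case-sharing flags.
* Coverage tracks plant per-gene gap fractions as contiguous run-length
  blocks (capture-probe dropouts are contiguous, not i.i.d. bases), with a
  shared component failed in every sample plus private per-sample components.

Every variant's intended cascade fate (``survivor`` or ``removed-at-<stage>``)
is computed at construction time from its raw attributes — an evaluation
independent of the cascade implementation — and recorded in the bundle
manifest, which serves as the oracle for truth-tracking tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coverage_audit import build_ccds_splice_intervals
from .segregation import AFFECTED, UNAFFECTED, UNKNOWN, Pedigree, PedigreeMember
from .variant_store import (
    AnnotatedVariant,
    CandidateGeneSet,
    FrequencyPanel,
    GenotypeCall,
    HET,
    HOM_ALT,
    HOM_REF,
    VariantKey,
    write_frequency_panel,
    write_gene_set,
    write_variant_table,
)

PANEL_NAMES = ("1000G-EUR", "HapMap-CEU")

FUNCTIONAL_TERMS = ("missense", "nonsense", "stop-gain", "stop-lost", "frameshift")
NONFUNCTIONAL_TERMS = ("intron", "coding-synonymous", "3'utr", "5'utr", "near-gene")

# Known skeletal- and cardiac-muscle disease genes used to name the candidate
# panel (symbols only; coordinates are simulated).
MUSCLE_DISEASE_GENES = (
    "ABCC9", "ACTA1", "ACTC1", "ACTN2", "ANKRD1", "ANO5", "BAG3", "BIN1",
    "CAPN3", "CAV3", "CHKB", "COL6A1", "COL6A2", "COL6A3", "CRYAB", "CSRP3",
    "DAG1", "DES", "DMD", "DNAJB6", "DPM3", "DSC2", "DSG2", "DSP", "DYSF",
    "EMD", "FHL1", "FKRP", "FKTN", "FLNC", "GAA", "GLA", "GMPPB", "GNE",
    "HNRNPA1", "HNRNPDL", "ISPD", "ITGA7", "JUP", "KBTBD13", "KLHL40",
    "KLHL41", "LAMA2", "LAMP2", "LARGE", "LDB3", "LMNA", "LMOD3", "MATR3",
    "MSTN", "MYBPC3", "MYH2", "MYH3", "MYH6", "MYH7", "MYL2", "MYL3",
    "MYOT", "MYOZ1", "MYOZ2", "MYOZ3", "MYPN", "NEB", "NEXN", "PABPN1",
    "PKP2", "PLEC", "PLN", "POMGNT1", "POMK", "POMT1", "POMT2", "PRKAG2",
    "PTRF", "RYR1", "RYR2", "SCN5A", "SEPN1", "SGCA", "SGCB", "SGCD",
    "SGCG", "SIL1", "SMCHD1", "SMN1", "SQSTM1", "SYNE1", "SYNE2", "TAZ",
    "TCAP", "TIA1", "TMEM43", "TNNC1", "TNNI2", "TNNI3", "TNNT1", "TNNT2",
    "TNNT3", "TPM1", "TPM2", "TPM3", "TRIM32", "TTN", "TTR", "VCL", "VCP",
    "XK",
)

_KNOWN_CHROMS = {"DES": "2", "FLNC": "7", "LAMA2": "6", "DNAJB6": "7", "TTN": "2"}


@dataclass
class CausalSpec:
    """The planted causal variant.

    Defaults emulate a near-splice intronic substitution 3 bases from an exon
    boundary in *DES*, heterozygous in every case.  ``per_case_depths`` pins
    read depths per case (e.g. ``(16, 5)`` to exercise a low-coverage case);
    None draws depths like any other variant.
    """

    gene: str = "DES"
    annotation_term: str = "intron"
    distance_to_splice: int | None = 3
    ref: str = "A"
    alt: str = "G"
    per_case_depths: tuple[int, ...] | None = None


@dataclass
class FalsePositiveSpec:
    """A planted sequencing artifact shared by all cases.

    ``kind="missense"``: confirmable, orthogonal genotypes all hom-ref.
    ``kind="homopolymer-indel"``: a coding indel in a homopolymer context,
    orthogonal confirmation untestable.
    """

    kind: str = "missense"
    gene: str = "LAMA2"


@dataclass
class CoverageGapSpec:
    """Ranges of the per-gene failed-base fractions.

    ``shared_fraction_range`` draws the component failed in every sample
    (mean 6.5% under the default (0, 0.13)); ``private_fraction_range`` draws
    each sample's additional private gap.
    """

    shared_fraction_range: tuple[float, float] = (0.0, 0.13)
    private_fraction_range: tuple[float, float] = (0.0, 0.10)


@dataclass
class SimulationConfig:
    """Study-scale defaults for one simulated family.

    Variant counts are per family, counted as "found in at least one case"
    within the candidate genes (``candidate_snvs``/``candidate_indels``) and
    within background genes (a scaled-down exome-wide remainder).  The
    stratum fractions are derived from the funnel shape of a dominant
    family-exome design: most raw calls are shared with control exomes or
    common in the population, a small minority are likely functional, and
    nearly none of the functional rare ones are shared by all cases.
    """

    seed: int = 0
    n_cases: int = 3
    n_controls: int = 3
    n_candidate_genes: int = 102
    n_background_genes: int = 150
    candidate_snvs: int = 2004
    candidate_indels: int = 410
    background_snvs: int = 2000
    background_indels: int = 400
    common_variant_fraction: float = 0.85
    control_artifact_fraction: float = 0.611
    functional_fraction: float = 0.163
    shared_all_cases_fraction: float = 0.03
    causal_spec: CausalSpec = field(default_factory=CausalSpec)
    false_positive_spec: FalsePositiveSpec | None = field(default_factory=FalsePositiveSpec)
    coverage_gap_spec: CoverageGapSpec = field(default_factory=CoverageGapSpec)

    def __post_init__(self) -> None:
        for name in ("common_variant_fraction", "control_artifact_fraction",
                     "functional_fraction", "shared_all_cases_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.n_cases < 1:
            raise ValueError("need at least one case")

    @property
    def case_ids(self) -> list[str]:
        return [f"case_{i}" for i in range(1, self.n_cases + 1)]

    @property
    def control_ids(self) -> list[str]:
        return [f"control_{i}" for i in range(1, self.n_controls + 1)]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if isinstance(raw.get("causal_spec"), dict):
            spec = dict(raw["causal_spec"])
            if spec.get("per_case_depths") is not None:
                spec["per_case_depths"] = tuple(spec["per_case_depths"])
            raw["causal_spec"] = CausalSpec(**spec)
        if isinstance(raw.get("false_positive_spec"), dict):
            raw["false_positive_spec"] = FalsePositiveSpec(**raw["false_positive_spec"])
        if isinstance(raw.get("coverage_gap_spec"), dict):
            spec = {k: tuple(v) for k, v in raw["coverage_gap_spec"].items()}
            raw["coverage_gap_spec"] = CoverageGapSpec(**spec)
        return cls(**raw)


@dataclass
class GeneModel:
    gene: str
    chrom: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, disjoint

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(
    config: SimulationConfig,
) -> tuple[dict[str, GeneModel], CandidateGeneSet]:
    """Simulate exon structures for candidate and background genes.

    Candidate genes take real muscle-disease symbols; per-gene CCDS totals
    spread over roughly 300-16,000 bases.  Background genes are mostly
    autosomal with a few on X and Y so the sex-chromosome filter has work
    to do.  Genes on one chromosome never overlap.
    """
    rng = np.random.default_rng(config.seed)
    candidates = list(MUSCLE_DISEASE_GENES[: config.n_candidate_genes])
    for i in range(len(candidates), config.n_candidate_genes):
        candidates.append(f"MUSC{i + 1:03d}")
    # the planted genes always belong to the candidate panel
    planted = [config.causal_spec.gene]
    if config.false_positive_spec is not None:
        planted.append(config.false_positive_spec.gene)
    for gene in planted:
        if gene not in candidates:
            evictable = [g for g in candidates if g not in planted]
            candidates.remove(evictable[-1])
            candidates.append(gene)
    candidates = sorted(candidates)
    backgrounds = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]

    def chrom_for(gene: str, background: bool) -> str:
        if gene in _KNOWN_CHROMS:
            return _KNOWN_CHROMS[gene]
        if background:
            u = rng.random()
            if u < 0.05:
                return "X"
            if u < 0.07:
                return "Y"
        return str(rng.integers(1, 23))

    cursors: dict[str, int] = {}
    models: dict[str, GeneModel] = {}
    for gene, background in [(g, False) for g in candidates] + [(g, True) for g in backgrounds]:
        chrom = chrom_for(gene, background)
        n_exons = int(1 + rng.poisson(5))
        lengths = np.clip(rng.lognormal(np.log(130), 0.7, size=n_exons), 50, 2500).astype(int)
        while lengths.sum() > 16_000:
            lengths = lengths[:-1]
        if lengths.sum() < 300:
            lengths = np.append(lengths, 300 - lengths.sum() + 50)
        start = cursors.get(chrom, 1_000_000)
        exons = []
        pos = start
        for length in lengths:
            exons.append((pos, pos + int(length) - 1))
            pos += int(length) + int(rng.integers(100, 3001))
        cursors[chrom] = pos + 50_000
        models[gene] = GeneModel(gene=gene, chrom=chrom, exons=exons)
    return models, CandidateGeneSet(frozenset(candidates))


def write_gene_models(models: Mapping[str, GeneModel], tsv_path: Path, bed_path: Path | None = None) -> None:
    rows = [
        {"gene": m.gene, "chrom": m.chrom, "start": s, "end": e, "status": "public"}
        for m in sorted(models.values(), key=lambda m: m.gene)
        for s, e in m.exons
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        lines = [f"{m.chrom}\t{s - 1}\t{e}\t{m.gene}"
                 for m in sorted(models.values(), key=lambda m: m.gene)
                 for s, e in m.exons]
        bed_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variants, panels and the truth manifest
# ---------------------------------------------------------------------------

def _expected_fate(
    *,
    gene: str,
    chrom: str,
    in_candidate_set: bool,
    case_carriers: Sequence[bool],
    control_carriers: Sequence[bool],
    panel_freqs: Sequence[float | None],
    terms: frozenset[str],
    distance_to_splice: int | None,
    is_indel: bool,
    freq_cutoff: float = 0.01,
    splice_cutoff: int = 10,
) -> str:
    """Intended candidate-gene-mode fate, from raw attributes only.

    This re-derives each cascade predicate directly so the manifest is an
    oracle independent of the cascade implementation.
    """
    if not any(case_carriers):
        return "not-in-cases"
    if not in_candidate_set:
        return "outside-candidate-genes"
    if any(control_carriers) or chrom in ("X", "Y"):
        return "removed-at-ii"
    if any(f is not None and f >= freq_cutoff for f in panel_freqs):
        return "removed-at-iii"
    functional = bool(terms & {"nonsense", "stop-gain", "stop-lost", "frameshift", "missense"})
    near_splice = distance_to_splice is not None and distance_to_splice <= splice_cutoff
    coding_indel = is_indel and bool(terms & {"coding", "coding-indel", "coding-synonymous",
                                              "frameshift", "missense", "nonsense",
                                              "stop-gain", "stop-lost", "synonymous"})
    if not (functional or near_splice or coding_indel):
        return "removed-at-iv"
    if not all(case_carriers):
        return "removed-at-v"
    return "survivor"


def _draw_call(rng: np.random.Generator, gt: str, depth: int | None = None,
               qual: float | None = None) -> GenotypeCall:
    d = int(depth) if depth is not None else int(rng.poisson(60) + 1)
    if gt == HET:
        alt = int(rng.binomial(d, 0.5))
        alt = min(max(alt, 1), d)
        ad = (d - alt, alt)
    elif gt == HOM_ALT:
        ad = (0, d)
    else:
        ad = (d, 0)
    return GenotypeCall(gt, allele_depth=ad, depth=d, site_qual=qual)


class _PositionAllocator:
    """Unique positions inside (or, for intronic picks, between) gene exons."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def allocate(self, model: GeneModel, near_splice: bool = False,
                 distance: int | None = None) -> int:
        lo, hi = model.span
        for _ in range(200):
            if near_splice and distance is not None:
                exon = model.exons[int(self.rng.integers(0, len(model.exons)))]
                pos = exon[1] + distance if self.rng.random() < 0.5 else max(1, exon[0] - distance)
            else:
                pos = int(self.rng.integers(lo, hi + 1))
            if (model.chrom, pos) not in self.used:
                self.used.add((model.chrom, pos))
                return pos
        raise RuntimeError(f"could not allocate a unique position in {model.gene}")


def simulate_family_variants(
    config: SimulationConfig,
    models: Mapping[str, GeneModel],
    candidate_genes: CandidateGeneSet,
) -> tuple[list[AnnotatedVariant], list[FrequencyPanel], list[dict]]:
    """Simulate the multi-sample variant table, panels and truth records.

    Returns (variants, [two frequency panels], truth records), where each
    truth record carries the variant key, its planted role (``causal``,
    ``false-positive`` or ``background``) and its intended candidate-gene-mode
    cascade fate.
    """
    if config.causal_spec.gene not in models:
        raise ValueError(f"causal gene {config.causal_spec.gene!r} absent from gene models")
    if config.causal_spec.gene not in candidate_genes:
        raise ValueError(f"causal gene {config.causal_spec.gene!r} not in the candidate set")
    rng = np.random.default_rng(config.seed + 1)
    alloc = _PositionAllocator(rng)
    cases, controls = config.case_ids, config.control_ids
    panel_freqs: tuple[dict[VariantKey, float], dict[VariantKey, float]] = ({}, {})
    variants: list[AnnotatedVariant] = []
    truth: list[dict] = []
    bases = np.array(list("ACGT"))

    def snv_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(4, size=2, replace=False)
        return str(bases[ref]), str(bases[alt])

    def indel_alleles() -> tuple[str, str]:
        anchor = str(bases[rng.integers(0, 4)])
        tail = "".join(bases[rng.integers(0, 4, size=int(rng.integers(1, 6)))])
        return (anchor, anchor + tail) if rng.random() < 0.5 else (anchor + tail, anchor)

    def assign_panels(key: VariantKey, common: bool) -> None:
        if common:
            f = float(rng.uniform(0.01, 0.5))
            which = rng.random()
            if which < 0.6:
                panel_freqs[0][key] = round(f, 4)
                panel_freqs[1][key] = round(float(np.clip(f + rng.normal(0, 0.02), 0.01, 1.0)), 4)
            elif which < 0.8:
                panel_freqs[0][key] = round(f, 4)
            else:
                panel_freqs[1][key] = round(f, 4)
        elif rng.random() < 0.5:
            panel_freqs[int(rng.integers(0, 2))][key] = round(float(rng.uniform(0.0002, 0.009)), 4)

    def record(variant: AnnotatedVariant, role: str, in_candidate: bool) -> None:
        key = variant.key
        fate = _expected_fate(
            gene=variant.gene, chrom=key.chrom, in_candidate_set=in_candidate,
            case_carriers=[variant.genotype(s).carries_alt for s in cases],
            control_carriers=[variant.genotype(s).carries_alt for s in controls],
            panel_freqs=[panel_freqs[0].get(key), panel_freqs[1].get(key)],
            terms=variant.annotation_terms,
            distance_to_splice=variant.distance_to_splice,
            is_indel=key.is_indel,
        )
        variants.append(variant)
        truth.append({"key": str(key), "gene": variant.gene, "class": variant.variant_class,
                      "role": role, "fate": fate})

    # --- planted causal -----------------------------------------------------
    spec = config.causal_spec
    model = models[spec.gene]
    near = spec.distance_to_splice is not None
    pos = alloc.allocate(model, near_splice=near, distance=spec.distance_to_splice)
    causal_key = VariantKey(model.chrom, pos, spec.ref, spec.alt)
    qual = round(float(rng.uniform(100, 2500)), 2)
    genotypes = {}
    for i, sid in enumerate(cases):
        depth = None
        if spec.per_case_depths is not None:
            depth = spec.per_case_depths[i % len(spec.per_case_depths)]
        genotypes[sid] = _draw_call(rng, HET, depth=depth, qual=qual)
    for sid in controls:
        genotypes[sid] = _draw_call(rng, HOM_REF, qual=qual)
    record(AnnotatedVariant(causal_key, gene=spec.gene,
                            annotation_terms=frozenset({spec.annotation_term}),
                            distance_to_splice=spec.distance_to_splice,
                            genotypes=genotypes),
           role="causal", in_candidate=True)

    # --- planted false positive --------------------------------------------
    confirmation: dict[str, str] = {}
    if config.false_positive_spec is not None:
        fspec = config.false_positive_spec
        fmodel = models.get(fspec.gene)
        if fmodel is None:
            raise ValueError(f"false-positive gene {fspec.gene!r} absent from gene models")
        fpos = alloc.allocate(fmodel)
        qual = round(float(rng.uniform(60, 500)), 2)
        if fspec.kind == "homopolymer-indel":
            fkey = VariantKey(fmodel.chrom, fpos, "A", "AA")
            terms = frozenset({"coding-indel"})
            confirmation = {sid: "untestable" for sid in cases}
        else:
            ref, alt = snv_alleles()
            fkey = VariantKey(fmodel.chrom, fpos, ref, alt)
            terms = frozenset({"missense"})
            confirmation = {sid: HOM_REF for sid in cases}
        genotypes = {sid: _draw_call(rng, HET, qual=qual) for sid in cases}
        genotypes.update({sid: _draw_call(rng, HOM_REF, qual=qual) for sid in controls})
        record(AnnotatedVariant(fkey, gene=fspec.gene, annotation_terms=terms,
                                genotypes=genotypes),
               role="false-positive",
               in_candidate=fspec.gene in candidate_genes)

    # --- background strata --------------------------------------------------
    candidate_models = sorted(g for g in models if g in candidate_genes)
    background_models = sorted(g for g in models if g not in candidate_genes)

    def background_variant(gene_pool: list[str], is_indel: bool, in_candidate: bool) -> None:
        gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
        model = models[gene]
        common = rng.random() < config.common_variant_fraction
        functional = rng.random() < config.functional_fraction
        near_splice = functional and not is_indel and rng.random() < 0.2
        dts: int | None = None
        if near_splice:
            terms = frozenset({str(rng.choice(["intron", "coding-synonymous"]))})
            dts = int(rng.integers(0, 11))
        elif functional:
            if is_indel:
                terms = frozenset({str(rng.choice(["frameshift", "coding-indel"]))})
            else:
                terms = frozenset({str(rng.choice(FUNCTIONAL_TERMS, p=[0.75, 0.1, 0.05, 0.02, 0.08]))})
        else:
            terms = frozenset({str(rng.choice(NONFUNCTIONAL_TERMS))})
            if rng.random() < 0.3:
                dts = int(rng.integers(11, 5001))
        pos = alloc.allocate(model, near_splice=near_splice, distance=dts if near_splice else None)
        ref, alt = indel_alleles() if is_indel else snv_alleles()
        key = VariantKey(model.chrom, pos, ref, alt)
        assign_panels(key, common)
        qual = round(float(rng.uniform(50, 3000)), 2)
        genotypes: dict[str, GenotypeCall] = {}
        if common:
            f = panel_freqs[0].get(key) or panel_freqs[1].get(key) or 0.05
            probs = ((1 - f) ** 2, 2 * f * (1 - f), f ** 2)
            gt_labels = (HOM_REF, HET, HOM_ALT)
            for _ in range(20):
                gts = [gt_labels[int(rng.choice(3, p=probs))] for _ in cases + controls]
                if any(g != HOM_REF for g in gts[: len(cases)]):
                    break
            else:
                # condition on the site being called in >=1 case
                gts[int(rng.integers(0, len(cases)))] = HET
            genotypes = {sid: _draw_call(rng, gt, qual=qual)
                         for sid, gt in zip(cases + controls, gts)}
        else:
            shared = rng.random() < config.shared_all_cases_fraction or len(cases) == 1
            if shared:
                carrier_idx = set(range(len(cases)))
            else:
                k = int(rng.integers(1, len(cases)))
                carrier_idx = set(rng.choice(len(cases), size=k, replace=False).tolist())
            in_control = rng.random() < config.control_artifact_fraction and controls
            ctrl_idx = {int(rng.integers(0, len(controls)))} if in_control else set()
            for i, sid in enumerate(cases):
                genotypes[sid] = _draw_call(rng, HET if i in carrier_idx else HOM_REF, qual=qual)
            for i, sid in enumerate(controls):
                genotypes[sid] = _draw_call(rng, HET if i in ctrl_idx else HOM_REF, qual=qual)
        record(AnnotatedVariant(key, gene=gene, annotation_terms=terms,
                                distance_to_splice=dts, genotypes=genotypes),
               role="background", in_candidate=in_candidate)

    for _ in range(config.candidate_snvs - 1 - (0 if config.false_positive_spec is None else 1)):
        background_variant(candidate_models, is_indel=False, in_candidate=True)
    for _ in range(config.candidate_indels):
        background_variant(candidate_models, is_indel=True, in_candidate=True)
    if background_models:
        for _ in range(config.background_snvs):
            background_variant(background_models, is_indel=False, in_candidate=False)
        for _ in range(config.background_indels):
            background_variant(background_models, is_indel=True, in_candidate=False)

    panels = [FrequencyPanel(name=n, freqs=f) for n, f in zip(PANEL_NAMES, panel_freqs)]
    if confirmation:
        truth_fp = next(t for t in truth if t["role"] == "false-positive")
        truth_fp["confirmation_genotypes"] = confirmation
    return variants, panels, truth


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, dict[str, str]]:
    """Build a three-generation dominant pedigree and causal genotypes.

    The affected founder transmits to the exome-sequenced cases; a married-in
    spouse of case_1 doubles as the first control exome, and their child is a
    *young unaffected carrier* whose age at last exam (27) sits below the
    family's oldest onset age — the configuration the age allowance exists
    for.  Remaining controls are unrelated unaffected individuals.
    """
    rng = np.random.default_rng(config.seed + 2)
    onset = sorted(int(a) for a in rng.integers(30, 53, size=config.n_cases + 1))
    members = [
        PedigreeMember("founder_aff", "FAM1", sex="male", affection=AFFECTED,
                       onset_age=float(onset[-1]), age_last_exam=float(onset[-1] + 20)),
        PedigreeMember("founder_sp", "FAM1", sex="female", affection=UNAFFECTED,
                       married_in=True, age_last_exam=float(onset[-1] + 18)),
    ]
    causal_gts: dict[str, str] = {"founder_aff": HET, "founder_sp": HOM_REF}
    for i, sid in enumerate(config.case_ids):
        members.append(PedigreeMember(
            sid, "FAM1", father="founder_aff", mother="founder_sp",
            sex="female" if i % 2 else "male", affection=AFFECTED,
            onset_age=float(onset[i]), age_last_exam=float(onset[i] + 8)))
        causal_gts[sid] = HET
    if config.n_controls >= 1:
        members.append(PedigreeMember("control_1", "FAM1", sex="female",
                                      affection=UNAFFECTED, married_in=True,
                                      age_last_exam=55.0))
        causal_gts["control_1"] = HOM_REF
        members.append(PedigreeMember(
            "young_carrier", "FAM1", father=config.case_ids[0], mother="control_1",
            sex="female", affection=UNAFFECTED, age_last_exam=27.0))
        causal_gts["young_carrier"] = HET
    for sid in config.control_ids[1:]:
        members.append(PedigreeMember(sid, f"CTRL_{sid}", sex="male",
                                      affection=UNAFFECTED, age_last_exam=60.0))
        causal_gts[sid] = HOM_REF
    return Pedigree(members), causal_gts


def write_pedigree(pedigree: Pedigree, ped_path: Path, meta_path: Path) -> None:
    ped_lines = []
    meta_rows = []
    for m in pedigree.members:
        sex = {"male": "1", "female": "2"}.get(m.sex, "0")
        pheno = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}[m.affection]
        ped_lines.append(f"{m.family}\t{m.id}\t{m.father or 0}\t{m.mother or 0}\t{sex}\t{pheno}")
        meta_rows.append({
            "sample": m.id,
            "age_last_exam": "" if m.age_last_exam is None else f"{m.age_last_exam:g}",
            "onset_age": "" if m.onset_age is None else f"{m.onset_age:g}",
            "married_in": "1" if m.married_in else "0",
        })
    ped_path.write_text("\n".join(ped_lines) + "\n")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def simulate_coverage_profiles(
    config: SimulationConfig,
    models: Mapping[str, GeneModel],
    candidate_genes: CandidateGeneSet,
    samples: Sequence[str] | None = None,
    flank: int = 10,
    depth_min: int = 10,
    qual_min: float = 50.0,
) -> tuple[dict[str, pd.DataFrame], dict[str, dict]]:
    """Per-sample base tracks over the candidate genes with planted gaps.

    Each gene draws a shared-gap fraction (bases failed in every sample, one
    contiguous block) and per-sample private-gap fractions (additional
    contiguous blocks), so ``failed in all <= failed per sample`` holds by
    construction.  Returns (sample -> track frame, gene -> planted truth with
    exact failed counts).
    """
    rng = np.random.default_rng(config.seed + 3)
    if samples is None:
        samples = config.case_ids
    gap = config.coverage_gap_spec
    frames: dict[str, list[pd.DataFrame]] = {s: [] for s in samples}
    truth: dict[str, dict] = {}
    for gene in sorted(g for g in models if g in candidate_genes):
        model = models[gene]
        intervals = build_ccds_splice_intervals(
            gene, [(model.chrom, s, e) for s, e in model.exons], flank=flank)
        positions = np.concatenate(
            [np.arange(s, e + 1) for _, s, e in intervals.intervals])
        n = positions.size
        shared_frac = float(rng.uniform(*gap.shared_fraction_range))
        shared = np.zeros(n, dtype=bool)
        k = int(round(shared_frac * n))
        if k:
            start = int(rng.integers(0, n - k + 1))
            shared[start:start + k] = True
        per_sample_failed: dict[str, int] = {}
        masks = {}
        for sample in samples:
            private = np.zeros(n, dtype=bool)
            kp = int(round(float(rng.uniform(*gap.private_fraction_range)) * n))
            if kp:
                start = int(rng.integers(0, n - kp + 1))
                private[start:start + kp] = True
            failed = shared | private
            masks[sample] = failed
            per_sample_failed[sample] = int(failed.sum())
            depth = rng.poisson(60, size=n) + depth_min
            qual = np.round(rng.uniform(qual_min + 50, 3000, size=n), 1)
            mode = rng.random(size=n)
            low_depth = failed & (mode < 0.6)
            low_qual = failed & ~low_depth
            depth = np.where(low_depth, rng.integers(0, depth_min, size=n), depth)
            qual = np.where(low_qual, np.round(rng.uniform(0.5, qual_min - 0.1, size=n), 1), qual)
            # a failed base must fail at least one criterion; low_qual keeps depth
            frames[sample].append(pd.DataFrame({
                "chrom": model.chrom, "pos": positions,
                "depth": depth.astype(int), "qual": qual}))
        all_failed = np.logical_and.reduce([masks[s] for s in samples]) if samples else shared
        truth[gene] = {
            "total_bases": int(n),
            "failed_per_sample": per_sample_failed,
            "failed_all_samples": int(all_failed.sum()),
        }
    tracks = {s: pd.concat(parts, ignore_index=True) for s, parts in frames.items()}
    return tracks, truth


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Paths and manifest of one generated on-disk dataset."""

    root: Path
    vcf: Path
    ped: Path
    meta: Path
    gene_set: Path
    gene_models_tsv: Path
    gene_models_bed: Path
    panels: dict[str, Path]
    tracks: dict[str, Path]
    manifest_path: Path
    manifest: dict

    @classmethod
    def load(cls, root: str | Path) -> "FixtureBundle":
        root = Path(root)
        manifest = json.loads((root / "manifest.json").read_text())
        return cls(
            root=root,
            vcf=root / "variants.vcf",
            ped=root / "pedigree.ped",
            meta=root / "pedigree_meta.tsv",
            gene_set=root / "candidate_genes.txt",
            gene_models_tsv=root / "gene_models.tsv",
            gene_models_bed=root / "gene_models.bed",
            panels={n: root / f"panel_{n}.tsv" for n in manifest["panel_names"]},
            tracks={s: root / "tracks" / f"{s}.tsv" for s in manifest["track_samples"]},
            manifest_path=root / "manifest.json",
            manifest=manifest,
        )


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def write_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> FixtureBundle:
    """Generate and write a complete bundle; fully determined by the config.

    The manifest records the config echo, per-file checksums, every variant's
    intended cascade fate, the planted coverage truth and the causal
    variant's genotypes across the full pedigree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)

    models, candidate_genes = simulate_gene_models(config)
    variants, panels, truth = simulate_family_variants(config, models, candidate_genes)
    pedigree, causal_gts = simulate_pedigree(config)
    tracks, coverage_truth = simulate_coverage_profiles(config, models, candidate_genes)

    sample_ids = config.case_ids + config.control_ids
    paths = {
        "vcf": outdir / "variants.vcf",
        "ped": outdir / "pedigree.ped",
        "meta": outdir / "pedigree_meta.tsv",
        "gene_set": outdir / "candidate_genes.txt",
        "gene_models_tsv": outdir / "gene_models.tsv",
        "gene_models_bed": outdir / "gene_models.bed",
    }
    write_variant_table(variants, paths["vcf"], sample_ids)
    write_pedigree(pedigree, paths["ped"], paths["meta"])
    write_gene_set(candidate_genes, paths["gene_set"])
    write_gene_models(models, paths["gene_models_tsv"], paths["gene_models_bed"])
    panel_paths = {}
    for panel in panels:
        p = outdir / f"panel_{panel.name}.tsv"
        write_frequency_panel(panel, p)
        panel_paths[panel.name] = p
    track_paths = {}
    for sample in sorted(tracks):
        p = outdir / "tracks" / f"{sample}.tsv"
        tracks[sample].to_csv(p, sep="\t", index=False, float_format="%.1f")
        track_paths[sample] = p

    causal = next(t for t in truth if t["role"] == "causal")
    fp = next((t for t in truth if t["role"] == "false-positive"), None)
    all_paths = {**paths, **panel_paths, **track_paths}
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "case_ids": config.case_ids,
        "control_ids": config.control_ids,
        "panel_names": [p.name for p in panels],
        "track_samples": sorted(tracks),
        "causal": {**causal, "pedigree_genotypes": causal_gts},
        "false_positive": fp,
        "variant_truth": truth,
        "coverage_truth": coverage_truth,
        "checksums": {str(p.relative_to(outdir)): _md5(p) for p in all_paths.values()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return FixtureBundle(
        root=outdir, vcf=paths["vcf"], ped=paths["ped"], meta=paths["meta"],
        gene_set=paths["gene_set"], gene_models_tsv=paths["gene_models_tsv"],
        gene_models_bed=paths["gene_models_bed"], panels=panel_paths,
        tracks=track_paths, manifest_path=manifest_path, manifest=manifest)
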