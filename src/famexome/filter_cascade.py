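"""Staged variant filtering for one family under a dominant rare-disease model.

The cascade reduces raw multi-sample exome calls to a short candidate list in
five stages:

(i)   variants found in *any* affected case (optionally restricted to a
      candidate gene set first, in ``candidate-genes`` mode);
(ii)  remove variants seen in any control exome (sequencing/processing
      artifacts) and variants on the X or Y chromosome (families with affected
      females and male-to-male transmission exclude sex linkage);
(iii) remove variants at >= 1% alternate-allele frequency in *any* population
      frequency panel;
(iv)  keep likely-functional variants: qualifying functional terms (nonsense,
      stop-gain, stop-lost, frameshift, missense), or within 10 bp of a splice
      junction, or coding indels;
(v)   keep variants shared by *all* cases.

Deliberately, no read-depth or quality threshold is applied at any stage: a
causal variant supported by as few as 5 reads in one case survives as long as
it was genotyped.  The frequency-based removal at stage (iii) is only
appropriate for dominant disease; for recessive disease it could discard
pathogenic alleles present in unaffected carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variant_store import (
    AnnotatedVariant,
    CandidateGeneSet,
    FrequencyPanel,
    VariantKey,
)

#: Functional annotation terms that qualify a variant at stage (iv).
DEFAULT_FUNCTIONAL_TERMS = frozenset(
    {"nonsense", "stop-gain", "stop-lost", "frameshift", "missense"}
)

#: Terms counted as "coding" for the coding-indel rule at stage (iv).
DEFAULT_CODING_TERMS = frozenset(
    {"coding", "coding-indel", "coding-synonymous", "frameshift", "missense",
     "nonsense", "stop-gain", "stop-lost", "synonymous"}
)

STAGE_LABELS = ("i", "ii", "iii", "iv", "v")

MODE_CANDIDATE = "candidate-genes"
MODE_EXOME_WIDE = "exome-wide"


@dataclass
class CascadeConfig:
    """Parameters of the filtering cascade.

    ``freq_cutoff`` (default 0.01): a variant at panel frequency >= cutoff in
    any panel is removed.  ``splice_distance_cutoff`` (default 10 bases):
    variants this close to an exon boundary qualify at stage (iv) regardless
    of functional term — the route by which non-canonical splice mutations
    are recovered.
    """

    case_ids: list[str]
    control_ids: list[str] = field(default_factory=list)
    mode: str = MODE_CANDIDATE
    freq_cutoff: float = 0.01
    splice_distance_cutoff: int = 10
    functional_terms: frozenset[str] = DEFAULT_FUNCTIONAL_TERMS
    coding_terms: frozenset[str] = DEFAULT_CODING_TERMS

    def __post_init__(self) -> None:
        if not self.case_ids:
            raise ValueError("case_ids must be non-empty")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case_ids and control_ids must be disjoint")
        if not 0.0 < self.freq_cutoff <= 1.0:
            raise ValueError(f"freq_cutoff must be in (0,1], got {self.freq_cutoff}")
        if self.splice_distance_cutoff < 0:
            raise ValueError("splice_distance_cutoff must be >= 0")
        if self.mode not in (MODE_CANDIDATE, MODE_EXOME_WIDE):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.functional_terms = frozenset(t.lower() for t in self.functional_terms)
        self.coding_terms = frozenset(t.lower() for t in self.coding_terms)


@dataclass(frozen=True)
class StageCount:
    snv: int
    indel: int

    @property
    def total(self) -> int:
        return self.snv + self.indel


@dataclass
class CascadeReport:
    """Per-stage SNV/indel/total counts and surviving variant sets."""

    stage_labels: tuple[str, ...]
    stage_counts: dict[str, StageCount]
    survivors: list[AnnotatedVariant]
    per_stage_survivors: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage_labels": list(self.stage_labels),
            "stage_counts": {
                label: {"snv": c.snv, "indel": c.indel, "total": c.total}
                for label, c in self.stage_counts.items()
            },
            "survivors": [str(v.key) for v in self.survivors],
        }


def _count(variants: Iterable[AnnotatedVariant]) -> StageCount:
    snv = indel = 0
    for v in variants:
        if v.key.is_indel:
            indel += 1
        else:
            snv += 1
    return StageCount(snv=snv, indel=indel)


# ---------------------------------------------------------------------------
# Individual filter stages
# ---------------------------------------------------------------------------

def restrict_to_genes(
    variants: Sequence[AnnotatedVariant], genes: CandidateGeneSet
) -> list[AnnotatedVariant]:
    """Keep only variants inside the candidate gene set (empty gene fails)."""
    return [v for v in variants if v.gene and v.gene in genes]


def exclude_in_controls(
    variants: Sequence[AnnotatedVariant], control_variant_keys: set[VariantKey]
) -> list[AnnotatedVariant]:
    """Remove variants whose key was carried by any control sample."""
    return [v for v in variants if v.key not in control_variant_keys]


def exclude_sex_chromosomes(variants: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Remove X- and Y-chromosome variants."""
    return [v for v in variants if not v.key.is_sex_chromosome]


def exclude_common(
    variants: Sequence[AnnotatedVariant],
    panels: Sequence[FrequencyPanel],
    cutoff: float,
) -> list[AnnotatedVariant]:
    """Remove variants at frequency >= cutoff in at least one panel.

    A variant absent from every panel is retained: in a rare-disease design a
    novel allele must survive, so missing is never treated as common.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0,1], got {cutoff}")

    def is_common(v: AnnotatedVariant) -> bool:
        for panel in panels:
            freq = panel.frequency(v.key)
            if freq is not None and freq >= cutoff:
                return True
        return False

    return [v for v in variants if not is_common(v)]


def keep_likely_functional(
    variants: Sequence[AnnotatedVariant], config: CascadeConfig
) -> list[AnnotatedVariant]:
    """Keep variants that are likely functional or near a splice junction.

    A variant survives when any of its annotation terms qualifies, when its
    distance-to-splice is within the cutoff (this admits synonymous and
    intronic variants on purpose), or when it is an indel annotated as coding.
    """
    def qualifies(v: AnnotatedVariant) -> bool:
        if v.annotation_terms & config.functional_terms:
            return True
        if (v.distance_to_splice is not None
                and v.distance_to_splice <= config.splice_distance_cutoff):
            return True
        if v.key.is_indel and v.annotation_terms & config.coding_terms:
            return True
        return False

    return [v for v in variants if qualifies(v)]


def keep_shared_all_cases(
    variants: Sequence[AnnotatedVariant], case_ids: Sequence[str]
) -> list[AnnotatedVariant]:
    """Keep variants carried (non-hom-ref, non-missing) by every case.

    A missing genotype fails sharing: loss of coverage in one case removes
    the variant here, which is why downstream review of stage-(iv) survivors
    remains advisable.
    """
    if not case_ids:
        raise ValueError("case_ids must be non-empty")
    return [
        v for v in variants
        if all(v.genotype(s).carries_alt for s in case_ids)
    ]


def control_keys_from_variants(
    variants: Sequence[AnnotatedVariant], control_ids: Sequence[str]
) -> set[VariantKey]:
    """Keys at which any control sample carries an alternate allele."""
    return {
        v.key for v in variants
        if any(v.genotype(s).carries_alt for s in control_ids)
    }


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    variants: Sequence[AnnotatedVariant],
    config: CascadeConfig,
    panels: Sequence[FrequencyPanel] = (),
    genes: CandidateGeneSet | None = None,
    control_keys: set[VariantKey] | None = None,
    keep_per_stage: bool = True,
) -> CascadeReport:
    """Run the five-stage cascade and record per-stage counts.

    ``control_keys`` defaults to the keys carried by ``config.control_ids``
    within ``variants`` themselves (the usual case when cases and controls
    share one multi-sample table).
    """
    if config.mode == MODE_CANDIDATE and genes is None:
        raise ValueError("candidate-genes mode requires a candidate gene set")
    genotyped_samples: set[str] = set()
    for v in variants:
        genotyped_samples.update(v.genotypes)
    if variants:
        absent = [s for s in config.case_ids if s not in genotyped_samples]
        if absent:
            raise ValueError(f"case sample(s) {absent} absent from every variant record")

    if control_keys is None:
        control_keys = control_keys_from_variants(variants, config.control_ids)

    # Stage (i): variants found in at least one case, within the candidate
    # gene set when in candidate-genes mode.
    current = [v for v in variants if v.found_in_any(config.case_ids)]
    if config.mode == MODE_CANDIDATE:
        current = restrict_to_genes(current, genes)  # type: ignore[arg-type]

    counts: dict[str, StageCount] = {}
    per_stage: dict[str, list[AnnotatedVariant]] = {}

    def record(label: str, survivors: list[AnnotatedVariant]) -> None:
        counts[label] = _count(survivors)
        if keep_per_stage:
            per_stage[label] = list(survivors)

    record("i", current)
    current = exclude_sex_chromosomes(exclude_in_controls(current, control_keys))
    record("ii", current)
    current = exclude_common(current, panels, config.freq_cutoff)
    record("iii", current)
    current = keep_likely_functional(current, config)
    record("iv", current)
    current = keep_shared_all_cases(current, config.case_ids)
    record("v", current)

    return CascadeReport(
        stage_labels=STAGE_LABELS,
        stage_counts=counts,
        survivors=list(current),
        per_stage_survivors=per_stage,
    )
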