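"""Dominant segregation testing with an age-aware penetrance allowance,
and exome-vs-orthogonal-confirmation genotype concordance.

Under a fully penetrant autosomal dominant model every affected individual
must carry the candidate allele and every unaffected individual must not.
Real late-onset myopathies are not that clean: an unaffected carrier who is
still *younger than the oldest onset age observed in the family* may simply
not have manifested yet, so such carriers are excused rather than counted as
violations.  Individuals of unknown affection status contribute no
constraint, and missing genotypes (DNA unavailable) are ignored.

Orthogonal confirmation (typically Sanger sequencing) of exome calls is
compared per sample: a variant called heterozygous by the exome but
homozygous reference on confirmation carries the signature of a sequencing
false positive.  Samples whose confirmation assay is uninterpretable (e.g.
the variant sits in a homopolymer stretch) are marked untestable and excluded
from the concordance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .variant_store import GenotypeCall, HET, HOM_ALT, HOM_REF, MISSING

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_PED_PHENO = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


@dataclass
class PedigreeMember:
    id: str
    family: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    affection: str = UNKNOWN
    age_last_exam: float | None = None
    onset_age: float | None = None
    married_in: bool = False


@dataclass
class Pedigree:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        self.by_id = {m.id: m for m in self.members}
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            if (m.family, m.id) in seen:
                raise ValueError(f"duplicate sample id {m.id} in family {m.family}")
            seen.add((m.family, m.id))
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent and parent not in self.by_id:
                    raise ValueError(f"member {m.id}: parent {parent} not in pedigree")

    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.affection == AFFECTED]

    def onset_ages(self) -> dict[str, float]:
        return {m.id: m.onset_age for m in self.members
                if m.affection == AFFECTED and m.onset_age is not None}


def load_pedigree(ped_path: str | Path, meta_path: str | Path | None = None) -> Pedigree:
    """Load a PED file plus an optional metadata TSV.

    PED columns: family, id, father, mother, sex (1=male, 2=female),
    phenotype (1=unaffected, 2=affected, 0/-9=unknown).  The metadata TSV has
    columns ``sample, age_last_exam, onset_age, married_in`` (blank fields
    allowed).
    """
    members: list[PedigreeMember] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has {len(fields)} fields, expected >= 6: {line!r}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        members.append(PedigreeMember(
            id=iid, family=fam,
            father=None if father == "0" else father,
            mother=None if mother == "0" else mother,
            sex={"1": "male", "2": "female"}.get(sex, "unknown"),
            affection=_PED_PHENO.get(pheno, UNKNOWN),
        ))
    ped = Pedigree(members)
    if meta_path is not None:
        import pandas as pd

        meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
        for row in meta.itertuples(index=False):
            member = ped.by_id.get(str(row.sample))
            if member is None:
                continue
            if getattr(row, "age_last_exam", "") != "":
                member.age_last_exam = float(row.age_last_exam)
            if getattr(row, "onset_age", "") != "":
                member.onset_age = float(row.onset_age)
            if getattr(row, "married_in", "") != "":
                member.married_in = str(row.married_in).lower() in ("1", "true", "yes")
    return ped


@dataclass
class SegregationVerdict:
    """Outcome of a dominant co-segregation check.

    ``segregates`` is true exactly when no violation was found.  Unaffected
    carriers younger than the family's oldest onset age are listed in
    ``excused_carriers`` as (sample, age, max_onset_age); carriers of unknown
    affection are recorded informationally and never violate.
    """

    segregates: bool
    violations: list[tuple[str, str]] = field(default_factory=list)
    excused_carriers: list[tuple[str, float, float]] = field(default_factory=list)
    unknown_carriers: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "segregates": self.segregates,
            "violations": [list(v) for v in self.violations],
            "excused_carriers": [list(e) for e in self.excused_carriers],
            "unknown_carriers": list(self.unknown_carriers),
        }


def _gt_of(call: GenotypeCall | str) -> str:
    return call.gt if isinstance(call, GenotypeCall) else call


def check_dominant_segregation(
    variant_genotypes: Mapping[str, GenotypeCall | str],
    pedigree: Pedigree,
    onset_ages: Mapping[str, float] | None = None,
) -> SegregationVerdict:
    """Test co-segregation of one variant under a dominant model.

    Violations: an affected individual homozygous reference, or an unaffected
    carrier whose age at last exam is at or above the family's maximum onset
    age (married-in status does not exempt a carrier from this rule — it is
    reported in the reason only).  An unaffected carrier with no recorded
    exam age is a violation too: the allowance cannot be applied blind.
    Missing genotypes and ungenotyped individuals impose no constraint.
    """
    if onset_ages is None:
        onset_ages = pedigree.onset_ages()
    genotyped_affected = [
        s for s, g in variant_genotypes.items()
        if s in pedigree.by_id and pedigree.by_id[s].affection == AFFECTED
        and _gt_of(g) != MISSING
    ]
    if not genotyped_affected:
        raise ValueError("no genotyped affected individual: segregation undefined")
    max_onset = max(onset_ages.values()) if onset_ages else None

    violations: list[tuple[str, str]] = []
    excused: list[tuple[str, float, float]] = []
    unknown_carriers: list[str] = []
    for sample, call in sorted(variant_genotypes.items()):
        member = pedigree.by_id.get(sample)
        if member is None:
            continue
        gt = _gt_of(call)
        if gt == MISSING:
            continue
        carrier = gt in (HET, HOM_ALT)
        if member.affection == AFFECTED:
            if gt == HOM_REF:
                violations.append((sample, "affected individual does not carry the variant"))
        elif member.affection == UNAFFECTED and carrier:
            if max_onset is None:
                raise ValueError(
                    "unaffected carrier present but no onset ages recorded: "
                    "age allowance undefined")
            tag = " (married-in)" if member.married_in else ""
            if member.age_last_exam is None:
                violations.append(
                    (sample, f"unaffected carrier with unknown exam age{tag}"))
            elif member.age_last_exam >= max_onset:
                violations.append(
                    (sample,
                     f"unaffected carrier aged {member.age_last_exam:g} >= "
                     f"max onset age {max_onset:g}{tag}"))
            else:
                excused.append((sample, member.age_last_exam, max_onset))
        elif member.affection == UNKNOWN and carrier:
            unknown_carriers.append(sample)
    return SegregationVerdict(
        segregates=not violations,
        violations=violations,
        excused_carriers=excused,
        unknown_carriers=unknown_carriers,
    )


UNTESTABLE = "untestable"


@dataclass(frozen=True)
class ConcordanceRecord:
    sample: str
    exome_gt: str
    confirm_gt: str
    concordant: bool | None  # None when the confirmation assay was untestable


def genotype_concordance(
    exome_genotypes: Mapping[str, GenotypeCall | str],
    confirm_genotypes: Mapping[str, GenotypeCall | str],
) -> list[ConcordanceRecord]:
    """Compare exome genotypes with orthogonal-confirmation genotypes.

    Only samples present in both maps are compared.  A confirmation genotype
    of ``untestable`` (or missing) excludes the sample from the concordance
    denominator without calling it discordant.
    """
    overlap = sorted(set(exome_genotypes) & set(confirm_genotypes))
    if not overlap:
        raise ValueError("no overlapping samples between exome and confirmation calls")
    records = []
    for sample in overlap:
        exome_gt = _gt_of(exome_genotypes[sample])
        confirm_gt = _gt_of(confirm_genotypes[sample])
        if confirm_gt in (UNTESTABLE, MISSING):
            records.append(ConcordanceRecord(sample, exome_gt, confirm_gt, None))
        else:
            records.append(ConcordanceRecord(sample, exome_gt, confirm_gt,
                                             exome_gt == confirm_gt))
    return records


def is_false_positive(records: Sequence[ConcordanceRecord]) -> bool:
    """True when the exome call pattern has the false-positive signature.

    Every testable sample the exome called as a carrier came back homozygous
    reference on confirmation, and at least one such discordance exists.
    """
    carrier_records = [
        r for r in records
        if r.exome_gt in (HET, HOM_ALT) and r.concordant is not None
    ]
    if not carrier_records:
        return False
    return all(r.confirm_gt == HOM_REF for r in carrier_records)
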