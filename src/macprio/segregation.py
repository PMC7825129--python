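"""Pedigree-aware genotype logic: segregation classification, de novo
confirmation, and STR-marker parentage checks.

Segregation follows clinical practice for dominant eye-malformation
pedigrees with known reduced penetrance: a variant segregates when every
genotyped affected family member carries it; an affected non-carrier
breaks segregation; unaffected or unknown-status carriers are recorded
but do not break segregation (a strict mode treats unaffected carriers
as nonsegregation).  De novo candidates (child carrier, both parents
reference) are upgraded to confirmed only when STR-marker parentage is
consistent with the stated trio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import enum
from typing import Optional, Union

from .model import (
    Affection,
    CARRIER_GENOTYPES,
    CnvEvent,
    Genotype,
    Individual,
    VariantRecord,
)

Variantlike = Union[VariantRecord, CnvEvent]


class SegregationStatus(enum.Enum):
    SEGREGATES = "segregates"
    NONSEGREGATING = "nonsegregating"
    DE_NOVO_CANDIDATE = "de_novo_candidate"
    DE_NOVO_CONFIRMED = "de_novo_confirmed"
    UNINFORMATIVE = "uninformative"


class InheritanceMode(enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNSPECIFIED = "unspecified"


@dataclass
class SegregationResult:
    variant_key: str
    family: str
    status: SegregationStatus
    carriers: list[str] = field(default_factory=list)
    noncarrier_affected: list[str] = field(default_factory=list)
    unaffected_carriers: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class StrProfile:
    """STR genotypes of one individual: marker -> unordered allele pair."""

    individual: str
    genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def markers(self) -> set[str]:
        return set(self.genotypes)


@dataclass
class ParentageResult:
    typed_markers: int
    consistent_markers: int
    parentage_confirmed: bool
    low_confidence: bool = False
    warnings: list[str] = field(default_factory=list)


def _recessive_carrier(gt: Genotype) -> bool:
    # Biallelic carriage: homozygous, or an SNV hemizygous over a deletion.
    return gt in (Genotype.HOM, Genotype.HEMI)


def segregation_status(
    v: Variantlike,
    pedigree: list[Individual],
    mode: InheritanceMode = InheritanceMode.UNSPECIFIED,
    strict_unaffected: bool = False,
) -> SegregationResult:
    """Classify co-segregation of ``v`` with disease in one family."""
    family = pedigree[0].family if pedigree else ""
    by_id = {ind.id: ind for ind in pedigree}
    genotyped = {s: g for s, g in v.genotypes.items() if s in by_id and g is not Genotype.MISSING}
    if not genotyped:
        raise ValueError(f"{v.key}: variant absent from all genotype maps of family {family}")

    carries = (
        _recessive_carrier
        if mode is InheritanceMode.RECESSIVE
        else (lambda gt: gt in CARRIER_GENOTYPES)
    )
    carriers = [s for s, g in genotyped.items() if g in CARRIER_GENOTYPES]
    noncarrier_affected = [
        s
        for s, g in genotyped.items()
        if by_id[s].affection is Affection.AFFECTED and not carries(g)
    ]
    unaffected_carriers = [
        s
        for s in carriers
        if by_id[s].affection
        in (Affection.UNAFFECTED, Affection.ASYMPTOMATIC_CARRIER, Affection.UNKNOWN)
    ]
    affected_genotyped = [
        s for s in genotyped if by_id[s].affection is Affection.AFFECTED
    ]

    notes = []
    unknown_carriers = [
        s for s in carriers if by_id[s].affection is Affection.UNKNOWN
    ]
    if unknown_carriers:
        notes.append(
            "carriers with unknown disease status: " + ", ".join(sorted(unknown_carriers))
        )

    if noncarrier_affected:
        status = SegregationStatus.NONSEGREGATING
    elif strict_unaffected and any(
        by_id[s].affection in (Affection.UNAFFECTED, Affection.ASYMPTOMATIC_CARRIER)
        for s in carriers
    ):
        status = SegregationStatus.NONSEGREGATING
        notes.append("strict mode: unaffected carrier treated as nonsegregation")
    elif len(affected_genotyped) <= 1 and len(genotyped) <= 1:
        status = SegregationStatus.UNINFORMATIVE
    elif not affected_genotyped:
        status = SegregationStatus.UNINFORMATIVE
    else:
        status = SegregationStatus.SEGREGATES

    return SegregationResult(
        variant_key=v.key,
        family=family,
        status=status,
        carriers=sorted(carriers),
        noncarrier_affected=sorted(noncarrier_affected),
        unaffected_carriers=sorted(unaffected_carriers),
        notes=notes,
    )


def parentage_check(
    index: StrProfile,
    father: StrProfile,
    mother: StrProfile,
    max_mismatches: int = 1,
) -> ParentageResult:
    """Mendelian consistency of a trio over shared STR markers.

    A marker is consistent when the child's allele pair can be
    partitioned with one allele present in the father's pair and the
    other in the mother's pair.  Parentage is confirmed when the number
    of inconsistent markers is at most ``max_mismatches`` (one mismatch
    tolerated by default, allowing a single-step mutation).
    """
    shared = index.markers() & father.markers() & mother.markers()
    consistent = 0
    for marker in shared:
        c1, c2 = index.genotypes[marker]
        pat = set(father.genotypes[marker])
        mat = set(mother.genotypes[marker])
        if (c1 in pat and c2 in mat) or (c2 in pat and c1 in mat):
            consistent += 1
    typed = len(shared)
    warnings = []
    low_confidence = typed < 20
    if low_confidence:
        warnings.append(f"only {typed} shared typed markers (<20): low confidence")
    confirmed = typed > 0 and (typed - consistent) <= max_mismatches
    return ParentageResult(
        typed_markers=typed,
        consistent_markers=consistent,
        parentage_confirmed=confirmed,
        low_confidence=low_confidence,
        warnings=warnings,
    )


def confirm_de_novo(
    v: Variantlike,
    child: Individual,
    pedigree: list[Individual],
    str_result: Optional[ParentageResult] = None,
) -> SegregationResult:
    """De novo status of ``v`` in ``child`` given trio genotypes.

    Candidate when the child carries the variant and both genotyped
    parents are reference; confirmed only when STR parentage is
    confirmed.  A missing parental genotype leaves the call a candidate
    with an explanatory note.
    """
    family = child.family
    child_gt = v.genotypes.get(child.id, Genotype.MISSING)
    if child_gt not in CARRIER_GENOTYPES:
        return SegregationResult(
            v.key, family, SegregationStatus.UNINFORMATIVE,
            notes=[f"{child.id} does not carry the variant"],
        )
    parent_gts = {}
    for pid in (child.father_id, child.mother_id):
        if pid is not None:
            parent_gts[pid] = v.genotypes.get(pid, Genotype.MISSING)
    if len(parent_gts) < 2:
        return SegregationResult(
            v.key, family, SegregationStatus.UNINFORMATIVE,
            carriers=[child.id], notes=["both parents required for de novo assessment"],
        )
    if any(g in CARRIER_GENOTYPES for g in parent_gts.values()):
        inherited_from = sorted(p for p, g in parent_gts.items() if g in CARRIER_GENOTYPES)
        return SegregationResult(
            v.key, family, SegregationStatus.UNINFORMATIVE,
            carriers=[child.id] + inherited_from,
            notes=[f"inherited from {', '.join(inherited_from)}"],
        )
    if any(g is Genotype.MISSING for g in parent_gts.values()):
        return SegregationResult(
            v.key, family, SegregationStatus.DE_NOVO_CANDIDATE,
            carriers=[child.id], notes=["parental genotype missing"],
        )
    if str_result is not None and str_result.parentage_confirmed:
        status = SegregationStatus.DE_NOVO_CONFIRMED
        notes = [
            f"STR parentage: {str_result.consistent_markers}/{str_result.typed_markers} "
            "markers consistent"
        ]
    else:
        status = SegregationStatus.DE_NOVO_CANDIDATE
        notes = (
            ["STR parentage not confirmed"]
            if str_result is not None
            else ["STR parentage not performed"]
        )
    return SegregationResult(
        v.key, family, status, carriers=[child.id], notes=notes
    )
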