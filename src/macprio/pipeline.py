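"""End-to-end orchestration: cascade -> segregation/de novo -> CNV merge
-> classification -> cohort summary.

The pipeline assembles one :class:`~macprio.classify.EvidenceBundle`
per cascade-passing candidate from the cohort's pedigrees, genotypes
and STR profiles.  Judgment-call evidence the data cannot encode
(functional assay outcomes, reviewed nonsegregation, an established
alternative cause in the family) is supplied as per-variant overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .cascade import FilterConfig, FilterVerdict, run_cascade
from .classify import (
    Category,
    ClassificationResult,
    CohortSummary,
    DeNovoStatus,
    EvidenceBundle,
    FunctionalEvidence,
    InheritanceFit,
    categorize,
    summarize_cohort,
)
from .cnv import CnvCall, CopyState
from .model import (
    Affection,
    CnvEvent,
    GenePanel,
    Genotype,
    GenomicDeletion,
    Individual,
    PriorReport,
    VariantRecord,
)
from .segregation import (
    InheritanceMode,
    SegregationStatus,
    StrProfile,
    confirm_de_novo,
    parentage_check,
    segregation_status,
)

Variantlike = Union[VariantRecord, CnvEvent]


@dataclass
class EvidenceOverride:
    """Reviewer-supplied evidence for one candidate."""

    segregation: Optional[SegregationStatus] = None
    functional: FunctionalEvidence = FunctionalEvidence.UNTESTED
    functional_ref: str = ""
    alternative_cause_in_family: bool = False


@dataclass
class PipelineResult:
    verdicts: list[FilterVerdict]
    classifications: list[ClassificationResult]
    summary: CohortSummary

    @property
    def causal(self) -> list[ClassificationResult]:
        return [
            c
            for c in self.classifications
            if c.category is Category.POTENTIALLY_DISEASE_CAUSING
        ]


def cnv_events_from_calls(
    calls: Sequence[CnvCall], min_exons: int = 2
) -> list[CnvEvent]:
    """Merge per-sample deletion calls into candidate events.

    Calls of the same gene(s) and exon span across samples become one
    event with het/hom genotypes per called sample.
    """
    grouped: dict[tuple, dict[str, Genotype]] = {}
    meta: dict[tuple, CnvCall] = {}
    for call in calls:
        if call.copy_state not in (CopyState.HET_DEL, CopyState.HOM_DEL):
            continue
        if call.n_targets < min_exons:
            continue
        key = (call.genes, call.first_exon, call.last_exon)
        gt = Genotype.HET if call.copy_state is CopyState.HET_DEL else Genotype.HOM
        grouped.setdefault(key, {})[call.sample] = gt
        meta[key] = call
    events = []
    for key, genotypes in grouped.items():
        call = meta[key]
        events.append(
            CnvEvent(
                genes=call.genes,
                deletion=GenomicDeletion(call.chrom, call.start, call.end),
                exon_span=call.exon_span,
                genotypes=genotypes,
                label=f"{call.genes[0]}:del({call.exon_span})",
            )
        )
    return events


def _family_of(v: Variantlike, sample_family: dict[str, str]) -> Optional[str]:
    for sample in v.carriers():
        fam = sample_family.get(sample)
        if fam is not None:
            return fam
    return None


def _de_novo_status(
    v: Variantlike,
    members: list[Individual],
    str_profiles: dict[str, StrProfile],
    max_str_mismatches: int,
) -> DeNovoStatus:
    by_id = {m.id: m for m in members}
    carriers = [by_id[c] for c in v.carriers() if c in by_id]
    # prefer the index patient, then any affected carrier with known parents
    carriers.sort(key=lambda m: (not m.is_index, m.id))
    for child in carriers:
        if child.father_id is None or child.mother_id is None:
            continue
        str_result = None
        trio = (child.id, child.father_id, child.mother_id)
        if all(p in str_profiles for p in trio):
            str_result = parentage_check(
                str_profiles[trio[0]],
                str_profiles[trio[1]],
                str_profiles[trio[2]],
                max_mismatches=max_str_mismatches,
            )
        result = confirm_de_novo(v, child, members, str_result)
        if result.status is SegregationStatus.DE_NOVO_CONFIRMED:
            return DeNovoStatus.CONFIRMED
        if result.status is SegregationStatus.DE_NOVO_CANDIDATE:
            return DeNovoStatus.CANDIDATE
    return DeNovoStatus.NO


def _biallelic_fit(
    v: Variantlike, members: list[Individual], candidates: Sequence[Variantlike]
) -> bool:
    affected = {m.id for m in members if m.affection is Affection.AFFECTED}
    if isinstance(v, VariantRecord):
        return any(
            v.genotypes.get(s) in (Genotype.HOM, Genotype.HEMI) for s in affected
        )
    # CNV: biallelic when an affected carrier also carries an SNV of the
    # same gene hemizygously (in trans with the deletion) or homozygously.
    cnv_carriers = set(v.carriers()) & affected
    for other in candidates:
        if other is v or not isinstance(other, VariantRecord):
            continue
        if other.gene in v.genes:
            for s in cnv_carriers:
                if other.genotypes.get(s) in (Genotype.HEMI, Genotype.HOM):
                    return True
    return any(v.genotypes.get(s) is Genotype.HOM for s in cnv_carriers)


def build_evidence(
    v: Variantlike,
    members: list[Individual],
    candidates: Sequence[Variantlike] = (),
    str_profiles: Optional[dict[str, StrProfile]] = None,
    override: Optional[EvidenceOverride] = None,
    mode: InheritanceMode = InheritanceMode.UNSPECIFIED,
    max_str_mismatches: int = 1,
) -> EvidenceBundle:
    """Assemble the evidence bundle for one candidate in one family."""
    str_profiles = str_profiles or {}
    override = override or EvidenceOverride()
    seg = segregation_status(v, members, mode=mode)
    seg_status = override.segregation or seg.status
    de_novo = _de_novo_status(v, members, str_profiles, max_str_mismatches)
    affected_ids = {m.id for m in members if m.affection is Affection.AFFECTED}
    n_affected_carriers = len(set(seg.carriers) & affected_ids)
    fit = InheritanceFit.NONE
    if _biallelic_fit(v, members, candidates):
        fit = InheritanceFit.BIALLELIC_FIT
    elif de_novo is DeNovoStatus.CONFIRMED or (
        seg_status is SegregationStatus.SEGREGATES and n_affected_carriers >= 2
    ):
        fit = InheritanceFit.DOMINANT_FIT
    prior = v.prior_report if isinstance(v, VariantRecord) else PriorReport.NONE
    return EvidenceBundle(
        de_novo=de_novo,
        segregation=seg_status,
        prior_report=prior,
        functional=override.functional,
        functional_ref=override.functional_ref,
        inheritance_fit=fit,
        alternative_cause_in_family=override.alternative_cause_in_family,
    )


def prioritize_cohort(
    variants: Sequence[VariantRecord],
    cohort: Sequence[Individual],
    panel: Optional[GenePanel],
    cfg: Optional[FilterConfig] = None,
    cnv_events: Sequence[CnvEvent] = (),
    str_profiles: Optional[dict[str, StrProfile]] = None,
    overrides: Optional[dict[str, EvidenceOverride]] = None,
    combining_table: Optional[dict] = None,
    mode: InheritanceMode = InheritanceMode.UNSPECIFIED,
) -> PipelineResult:
    """Run the full prioritization pipeline on one cohort.

    SNV/indel records go through the filter cascade; CNV events (from
    :func:`cnv_events_from_calls` or supplied directly) join the
    cascade survivors for evidence assembly and classification.
    """
    cfg = cfg or FilterConfig()
    overrides = overrides or {}
    verdicts = run_cascade(variants, panel, cfg)
    sample_family = {ind.id: ind.family for ind in cohort}
    by_family: dict[str, list[Individual]] = {}
    for ind in cohort:
        by_family.setdefault(ind.family, []).append(ind)

    candidates: list[Variantlike] = [v.variant for v in verdicts if v.passed]
    candidates.extend(cnv_events)
    verdict_by_key = {v.variant.key: v for v in verdicts if v.passed}

    classifications: list[ClassificationResult] = []
    for cand in candidates:
        family = _family_of(cand, sample_family)
        if family is None:
            continue
        members = by_family[family]
        family_candidates = [
            c for c in candidates if _family_of(c, sample_family) == family
        ]
        evidence = build_evidence(
            cand,
            members,
            candidates=family_candidates,
            str_profiles=str_profiles,
            override=overrides.get(cand.key),
            mode=mode,
        )
        classifications.append(
            categorize(
                cand,
                evidence,
                family,
                verdict=verdict_by_key.get(cand.key),
                table=combining_table,
                cfg=cfg,
            )
        )
    summary = summarize_cohort(cohort, classifications)
    return PipelineResult(
        verdicts=verdicts, classifications=classifications, summary=summary
    )
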