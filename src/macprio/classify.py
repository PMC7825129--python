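"""Evidence combination and cohort summary statistics.

Cascade-passing candidates are combined with family evidence (confirmed
de novo status, co-segregation, prior reports, functional assay
outcomes, co-occurring explanatory variants) into a reduced ACMG-style
class (P/LP/VUS/LB/B) and a final category:

* ``potentially_disease_causing`` — P/LP, or a VUS supported by at
  least one of: confirmed de novo occurrence, co-segregation under a
  fitting inheritance model, a prior report of the same variant with a
  comparable phenotype, or biallelic carriage — and not refuted or
  incidental;
* ``excluded`` — nonsegregation, functional refutation, or an
  incidental finding (an alternative molecular cause established in the
  family outweighs lower-tier evidence);
* ``additional_variant`` — passed the cascade but the evidence is
  insufficient either way.

The combining table is shipped as editable YAML
(``macprio/data/acmg_rules.yaml``) and documents where it deviates from
a strict Richards-2015 reading.  Detection-rate percentages are integers
rounded half away from zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from math import floor
from typing import Optional, Sequence, Union

import yaml

from .cascade import FilterVerdict, FilterConfig, predictor_consensus
from .model import (
    Affection,
    CnvEvent,
    Individual,
    NULL_CONSEQUENCES,
    PriorReport,
    VariantRecord,
)
from .segregation import SegregationStatus

Variantlike = Union[VariantRecord, CnvEvent]


class AcmgClass(enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


#: Ordering used by monotonicity checks (benign -> pathogenic).
ACMG_RANK = {
    AcmgClass.B: 0,
    AcmgClass.LB: 1,
    AcmgClass.VUS: 2,
    AcmgClass.LP: 3,
    AcmgClass.P: 4,
}

PATHOGENIC_CODES = frozenset({"PVS1", "PS2", "PM2", "PM5", "PP1", "PP3"})
BENIGN_CODES = frozenset({"BS4", "BP5"})


class DeNovoStatus(enum.Enum):
    CONFIRMED = "confirmed"
    CANDIDATE = "candidate"
    NO = "no"


class FunctionalEvidence(enum.Enum):
    SUPPORTS = "supports"
    REFUTES = "refutes"
    UNTESTED = "untested"


class InheritanceFit(enum.Enum):
    DOMINANT_FIT = "dominant_fit"
    BIALLELIC_FIT = "biallelic_fit"
    NONE = "none"


class Category(enum.Enum):
    POTENTIALLY_DISEASE_CAUSING = "potentially_disease_causing"
    ADDITIONAL_VARIANT = "additional_variant"
    EXCLUDED = "excluded"


@dataclass
class EvidenceBundle:
    de_novo: DeNovoStatus = DeNovoStatus.NO
    segregation: Optional[SegregationStatus] = None
    prior_report: PriorReport = PriorReport.NONE
    functional: FunctionalEvidence = FunctionalEvidence.UNTESTED
    functional_ref: str = ""
    inheritance_fit: InheritanceFit = InheritanceFit.NONE
    alternative_cause_in_family: bool = False

    def __post_init__(self) -> None:
        if self.functional is FunctionalEvidence.REFUTES and not self.functional_ref:
            raise ValueError("functional=refutes requires a recorded assay reference")


@dataclass
class ClassificationResult:
    variant: Variantlike
    family: str
    acmg: AcmgClass
    category: Category
    triggered_rules: list[str] = field(default_factory=list)
    evidence: Optional[EvidenceBundle] = None

    @property
    def incidental(self) -> bool:
        return "incidental" in self.triggered_rules


# ---------------------------------------------------------------------------
# Combining table

def load_combining_table(path=None) -> dict:
    if path is None:
        text = (resources.files("macprio") / "data" / "acmg_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    if "rules" not in table:
        raise ValueError("combining table must define 'rules'")
    table.setdefault("default", "VUS")
    return table


_DEFAULT_TABLE: Optional[dict] = None


def _default_table() -> dict:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_combining_table()
    return _DEFAULT_TABLE


def combine_codes(codes: set[str], table: Optional[dict] = None) -> AcmgClass:
    table = table or _default_table()
    for rule in table["rules"]:
        if rule.get("all") and not set(rule["all"]) <= codes:
            continue
        if rule.get("any") and not set(rule["any"]) & codes:
            continue
        if rule.get("none") and set(rule["none"]) & codes:
            continue
        return AcmgClass(rule["class"])
    return AcmgClass(table["default"])


def evidence_codes(
    v: Variantlike,
    e: EvidenceBundle,
    cfg: Optional[FilterConfig] = None,
    pm2_het_af_max: float = 1e-4,
) -> set[str]:
    """Derive the reduced evidence-code set for one candidate."""
    cfg = cfg or FilterConfig()
    codes: set[str] = set()
    if isinstance(v, CnvEvent):
        codes.add("PVS1")  # multi-exon deletion treated as a null allele
        codes.add("PM2")
    else:
        if v.consequence in NULL_CONSEQUENCES:
            codes.add("PVS1")
        if v.het_af <= pm2_het_af_max:
            codes.add("PM2")
        if e.prior_report is PriorReport.SAME_RESIDUE_DIFFERENT_CHANGE:
            codes.add("PM5")
        _, consensus = predictor_consensus(v.predictions, cfg)
        if consensus:
            codes.add("PP3")
    if e.de_novo is DeNovoStatus.CONFIRMED:
        codes.add("PS2")
    if e.segregation is SegregationStatus.SEGREGATES:
        codes.add("PP1")
    if e.segregation is SegregationStatus.NONSEGREGATING:
        codes.add("BS4")
    if e.alternative_cause_in_family:
        codes.add("BP5")
    return codes


def acmg_lite(
    v: Variantlike,
    e: EvidenceBundle,
    table: Optional[dict] = None,
    cfg: Optional[FilterConfig] = None,
) -> tuple[AcmgClass, list[str]]:
    codes = evidence_codes(v, e, cfg=cfg)
    return combine_codes(codes, table), sorted(codes)


def categorize(
    v: Variantlike,
    e: EvidenceBundle,
    family: str,
    verdict: Optional[FilterVerdict] = None,
    table: Optional[dict] = None,
    cfg: Optional[FilterConfig] = None,
) -> ClassificationResult:
    """Final category from the ACMG-style class plus family evidence."""
    if verdict is not None and not verdict.passed:
        raise ValueError(f"{v.key}: cannot categorize a cascade-failing variant")
    acmg, codes = acmg_lite(v, e, table=table, cfg=cfg)
    rules = list(codes)
    if e.segregation is SegregationStatus.NONSEGREGATING:
        rules.append("excluded:nonsegregation")
        return ClassificationResult(v, family, acmg, Category.EXCLUDED, rules, e)
    if e.functional is FunctionalEvidence.REFUTES:
        rules.append("excluded:functional-refuted")
        return ClassificationResult(v, family, acmg, Category.EXCLUDED, rules, e)
    if e.alternative_cause_in_family and acmg not in (AcmgClass.P, AcmgClass.LP):
        rules.append("incidental")
        rules.append("excluded:incidental")
        return ClassificationResult(v, family, acmg, Category.EXCLUDED, rules, e)

    causal = acmg in (AcmgClass.P, AcmgClass.LP)
    # splice-region variants without a predicted splice alteration are
    # fallback candidates only and are never upgraded on family evidence
    fallback_only = verdict is not None and verdict.fallback_only
    if not causal and acmg is AcmgClass.VUS and not fallback_only:
        triggers = []
        if e.de_novo is DeNovoStatus.CONFIRMED:
            triggers.append("vus+de-novo-confirmed")
        if (
            e.segregation is SegregationStatus.SEGREGATES
            and e.inheritance_fit is not InheritanceFit.NONE
        ):
            triggers.append("vus+segregation-with-fit")
        if e.prior_report is PriorReport.SAME_VARIANT_COMPARABLE_PHENOTYPE:
            triggers.append("vus+prior-same-variant")
        if e.inheritance_fit is InheritanceFit.BIALLELIC_FIT:
            triggers.append("vus+biallelic")
        if triggers:
            rules.extend(triggers)
            causal = True
    category = (
        Category.POTENTIALLY_DISEASE_CAUSING if causal else Category.ADDITIONAL_VARIANT
    )
    return ClassificationResult(v, family, acmg, category, rules, e)


# ---------------------------------------------------------------------------
# Cohort summary

@dataclass
class StratumCount:
    total: int
    solved: int

    @property
    def percent(self) -> int:
        return round_half_away(100.0 * self.solved / self.total) if self.total else 0


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


@dataclass
class CohortSummary:
    families: StratumCount
    strata: dict[str, StratumCount]
    n_potentially_disease_causing: int
    n_additional_findings: int
    n_incidental: int

    @property
    def family_detection_percent(self) -> int:
        return self.families.percent


def summarize_cohort(
    cohort: Sequence[Individual],
    classifications: Sequence[ClassificationResult],
) -> CohortSummary:
    """Detection-rate statistics over families and phenotype strata.

    A family is solved when at least one of its candidates is
    potentially disease-causing; an affected patient counts as solved
    when they carry such a candidate.  Strata follow the clinical-table
    flags: all affected, extraocular manifestations at enrollment,
    isolated ocular phenotype, coloboma without microphthalmia, and
    colobomatous microphthalmia.  "Additional findings" are
    cascade-passing candidates that are neither disease-causing nor
    incidental.
    """
    families = sorted({ind.family for ind in cohort})
    for fam in families:
        if not any(ind.is_index for ind in cohort if ind.family == fam):
            raise ValueError(f"family {fam} has no index patient")
    causal = [
        c
        for c in classifications
        if c.category is Category.POTENTIALLY_DISEASE_CAUSING
    ]
    solved_families = {c.family for c in causal}
    causal_carriers: set[str] = set()
    for c in causal:
        causal_carriers.update(c.variant.carriers())

    affected = [ind for ind in cohort if ind.affection is Affection.AFFECTED]

    def stratum(members: list[Individual]) -> StratumCount:
        return StratumCount(
            total=len(members),
            solved=sum(ind.id in causal_carriers for ind in members),
        )

    strata = {
        "affected": stratum(affected),
        "extraocular": stratum([i for i in affected if i.extraocular_at_enrollment]),
        "isolated_ocular": stratum(
            [i for i in affected if not i.extraocular_at_enrollment]
        ),
        "coloboma_only": stratum([i for i in affected if not i.has_microphthalmia]),
        "colobomatous_microphthalmia": stratum(
            [i for i in affected if i.has_microphthalmia]
        ),
    }
    n_incidental = sum(c.incidental for c in classifications)
    n_additional = sum(
        1
        for c in classifications
        if c.category is not Category.POTENTIALLY_DISEASE_CAUSING and not c.incidental
    )
    return CohortSummary(
        families=StratumCount(total=len(families), solved=len(solved_families)),
        strata=strata,
        n_potentially_disease_causing=len(causal),
        n_additional_findings=n_additional,
        n_incidental=n_incidental,
    )


# ---------------------------------------------------------------------------
# Report rendering

def _sort_key(c: ClassificationResult):
    pos = c.variant.pos if isinstance(c.variant, VariantRecord) else c.variant.deletion.first_deleted
    return (c.family, pos, c.variant.key)


def render_report(
    summary: CohortSummary,
    classifications: Sequence[ClassificationResult],
    fmt: str = "tsv",
) -> str:
    """Deterministic cohort report (TSV or Markdown)."""
    ordered = sorted(classifications, key=_sort_key)
    if fmt == "tsv":
        lines = ["FAMILY\tVARIANT\tACMG\tCATEGORY\tRULES"]
        for c in ordered:
            lines.append(
                f"{c.family}\t{c.variant.key}\t{c.acmg.value}\t"
                f"{c.category.value}\t{';'.join(c.triggered_rules)}"
            )
        return "\n".join(lines) + "\n"
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")
    out = ["# Cohort prioritization report", ""]
    fam = summary.families
    out.append(
        f"Families solved: {fam.solved}/{fam.total} ({fam.percent}%)"
    )
    out.append("")
    out.append("| stratum | solved/total | % |")
    out.append("|---|---|---|")
    for name, s in summary.strata.items():
        out.append(f"| {name} | {s.solved}/{s.total} | {s.percent} |")
    out.append("")
    sections = [
        ("Potentially disease-causing", Category.POTENTIALLY_DISEASE_CAUSING),
        ("Additional variants", None),
    ]
    for title, cat in sections:
        out.append(f"## {title}")
        out.append("")
        for c in ordered:
            if cat is Category.POTENTIALLY_DISEASE_CAUSING:
                keep = c.category is cat
            else:
                keep = c.category is not Category.POTENTIALLY_DISEASE_CAUSING and not c.incidental
            if keep:
                out.append(
                    f"- {c.family}: {c.variant.key} [{c.acmg.value}] "
                    f"{c.category.value} ({'; '.join(c.triggered_rules)})"
                )
        out.append("")
    incidentals = [c for c in ordered if c.incidental]
    if incidentals:
        out.append("## Incidental findings")
        out.append("")
        for c in incidentals:
            out.append(f"- {c.family}: {c.variant.key} [{c.acmg.value}]")
        out.append("")
    return "\n".join(out) + "\n"
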