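"""Stepwise variant filter: panel restriction, frequency gates, type
routing, predictor consensus, and the splice-region window.

The cascade mirrors the screening strategy of panel-restricted exome
analysis for developmental eye disease: variants are excluded when too
common (heterozygous gnomAD frequency above 1%, or any appreciable
homozygous frequency), then routed by consequence class.  Null alleles
(frameshift, nonsense, canonical splice) pass unconditionally; missense
variants need a deleterious consensus from at least three of the five
predictors (Align-GVGD, FATHMM-MKL, CADD, MutationTaster, SIFT);
synonymous and intronic variants pass only within +/-30 bp of an
exon-intron boundary, flagged "prioritized" when a splice-strength
change is annotated and "fallback-only" otherwise.  UTR/other variants
fail unless rescued by a prior report of the same variant or residue
with a comparable phenotype (rescues are always logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    NULL_CONSEQUENCES,
    Consequence,
    GenePanel,
    GvgdGrade,
    MutationTasterCall,
    PredictionProfile,
    PriorReport,
    VariantRecord,
)


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    ``hom_af_max`` defaults to 1e-7 — a literal percentage reading of
    the ">0.00001%" homozygote bound; set it to 1e-5 if your input
    already stores that bound as a fraction.  ``cadd_min`` 15.0 and
    ``gvgd_min_grade`` C15 are conventional deleteriousness cutoffs for
    the two predictors whose thresholds the screening criteria leave to
    the cited score interpretations.
    """

    het_af_max: float = 0.01
    hom_af_max: float = 1e-7
    splice_window: int = 30
    consensus_required: int = 3
    predictors_total: int = 5
    sift_max: float = 0.05
    fathmm_min: float = 0.5
    cadd_min: float = 15.0
    gvgd_min_grade: GvgdGrade = GvgdGrade.C15

    def __post_init__(self) -> None:
        for name in ("het_af_max", "hom_af_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if not 1 <= self.consensus_required <= self.predictors_total:
            raise ValueError("consensus_required must be in [1, predictors_total]")

    @classmethod
    def from_dict(cls, data: dict) -> "FilterConfig":
        if "gvgd_min_grade" in data and isinstance(data["gvgd_min_grade"], str):
            data = dict(data, gvgd_min_grade=GvgdGrade[data["gvgd_min_grade"].upper()])
        return cls(**data)


@dataclass
class StageResult:
    stage: str
    passed: bool
    reason: str


@dataclass
class FilterVerdict:
    variant: VariantRecord
    passed: bool
    stage_log: list[StageResult] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def fallback_only(self) -> bool:
        return "fallback-only" in self.flags

    @property
    def prioritized(self) -> bool:
        return "prioritized" in self.flags

    @property
    def rescued(self) -> bool:
        return any(s.stage == "prior-report-rescue" and s.passed for s in self.stage_log)


def restrict_to_panel(
    variants: Iterable[VariantRecord], panel: GenePanel
) -> list[VariantRecord]:
    """Keep only variants whose gene symbol is on the panel (order kept)."""
    return [v for v in variants if v.gene in panel]


def frequency_gate(v: VariantRecord, cfg: FilterConfig) -> StageResult:
    """Exclude variants above the heterozygous or homozygous bound.

    A missing frequency is treated as 0 (absent from gnomAD).
    """
    if v.het_af < 0 or v.hom_af < 0:
        raise ValueError(f"{v.key}: negative allele frequency")
    if v.het_af > cfg.het_af_max:
        return StageResult(
            "frequency", False, f"het_af {v.het_af:g} > {cfg.het_af_max:g}"
        )
    if v.hom_af > cfg.hom_af_max:
        return StageResult(
            "frequency", False, f"hom_af {v.hom_af:g} > {cfg.hom_af_max:g}"
        )
    return StageResult("frequency", True, "rare")


def predictor_consensus(
    p: PredictionProfile, cfg: FilterConfig
) -> tuple[int, bool]:
    """Count deleterious votes over the five predictors.

    Missing predictors count as non-deleterious votes, keeping the
    denominator at five.
    """
    votes = 0
    if p.sift is not None and p.sift <= cfg.sift_max:
        votes += 1
    if p.mutation_taster is MutationTasterCall.DISEASE_CAUSING:
        votes += 1
    if p.fathmm_mkl is not None and p.fathmm_mkl >= cfg.fathmm_min:
        votes += 1
    if p.cadd_phred is not None and p.cadd_phred >= cfg.cadd_min:
        votes += 1
    if p.align_gvgd is not None and p.align_gvgd >= cfg.gvgd_min_grade:
        votes += 1
    return votes, votes >= cfg.consensus_required


def positional_gate(v: VariantRecord, cfg: FilterConfig) -> StageResult:
    """Splice-region window for synonymous/intronic variants."""
    if v.consequence not in (Consequence.SYNONYMOUS, Consequence.INTRONIC):
        raise ValueError(
            f"{v.key}: positional gate applies to synonymous/intronic only"
        )
    if v.boundary_distance is None:
        raise ValueError(f"{v.key}: boundary_distance missing")
    dist = abs(v.boundary_distance)
    if dist <= cfg.splice_window:
        return StageResult(
            "position", True, f"|{v.boundary_distance}| <= {cfg.splice_window} bp"
        )
    return StageResult(
        "position", False, f"|{v.boundary_distance}| > {cfg.splice_window} bp"
    )


def route_variant(v: VariantRecord, cfg: FilterConfig) -> FilterVerdict:
    """Type/position routing applied after the panel and frequency gates."""
    log: list[StageResult] = []
    flags: list[str] = []
    csq = v.consequence
    if csq in NULL_CONSEQUENCES:
        log.append(StageResult("type", True, f"LoF ({csq.value})"))
        passed = True
    elif csq is Consequence.MISSENSE:
        votes, ok = predictor_consensus(v.predictions, cfg)
        log.append(
            StageResult(
                "consensus",
                ok,
                f"{votes}/{cfg.predictors_total} deleterious votes "
                f"(need {cfg.consensus_required})",
            )
        )
        passed = ok
    elif csq in (Consequence.SYNONYMOUS, Consequence.INTRONIC):
        pos = positional_gate(v, cfg)
        log.append(pos)
        passed = pos.passed
        if passed:
            if v.splice_delta is not None and v.splice_delta != 0:
                flags.append("prioritized")
                log.append(
                    StageResult(
                        "splice-prediction", True,
                        f"predicted splice alteration (delta {v.splice_delta:g})",
                    )
                )
            else:
                flags.append("fallback-only")
                log.append(
                    StageResult(
                        "splice-prediction", True,
                        "no predicted alteration; considered in the absence "
                        "of other candidates",
                    )
                )
    elif csq in (Consequence.UTR, Consequence.OTHER, Consequence.INFRAME_INDEL):
        if v.prior_report is not PriorReport.NONE:
            log.append(
                StageResult(
                    "prior-report-rescue", True,
                    f"rescued by prior report ({v.prior_report.value})",
                )
            )
            flags.append("rescued")
            passed = True
        else:
            log.append(StageResult("type", False, f"{csq.value} without prior report"))
            passed = False
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"{v.key}: unknown consequence {csq!r}")
    return FilterVerdict(variant=v, passed=passed, stage_log=log, flags=flags)


def evaluate_variant(
    v: VariantRecord, panel: Optional[GenePanel], cfg: FilterConfig
) -> FilterVerdict:
    """Full per-variant cascade: panel -> frequency -> type routing."""
    log: list[StageResult] = []
    if panel is not None:
        in_panel = v.gene in panel
        log.append(
            StageResult("panel", in_panel, f"{v.gene} {'in' if in_panel else 'not in'} panel")
        )
        if not in_panel:
            return FilterVerdict(variant=v, passed=False, stage_log=log)
    freq = frequency_gate(v, cfg)
    log.append(freq)
    if not freq.passed:
        return FilterVerdict(variant=v, passed=False, stage_log=log)
    verdict = route_variant(v, cfg)
    verdict.stage_log = log + verdict.stage_log
    return verdict


def run_cascade(
    variants: Iterable[VariantRecord],
    panel: Optional[GenePanel],
    cfg: Optional[FilterConfig] = None,
) -> list[FilterVerdict]:
    """Apply the stepwise filter to every variant.

    Verdicts are per-variant deterministic functions of (record, panel,
    config); the "fallback-only" flag is resolved at classification
    time, not here.
    """
    cfg = cfg or FilterConfig()
    return [evaluate_variant(v, panel, cfg) for v in variants]
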