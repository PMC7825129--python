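"""Evidence combination, categories, cohort summary, report rendering."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_variant
from macprio import (
    AcmgClass,
    Category,
    EvidenceBundle,
    FunctionalEvidence,
    acmg_lite,
    categorize,
    render_report,
    round_half_away,
    summarize_cohort,
)
from macprio.classify import ACMG_RANK, DeNovoStatus, InheritanceFit
from macprio.model import Consequence, PriorReport
from macprio.pipeline import prioritize_cohort
from macprio.segregation import SegregationStatus


class TestAcmgLite:
    def test_de_novo_null_variant_is_pathogenic(self):
        v = make_variant(consequence=Consequence.FRAMESHIFT, het_af=0.0)
        e = EvidenceBundle(de_novo=DeNovoStatus.CONFIRMED)
        acmg, codes = acmg_lite(v, e)
        assert acmg is AcmgClass.P
        assert {"PVS1", "PS2", "PM2"} <= set(codes)

    def test_rare_residue_matched_missense_is_likely_pathogenic(self):
        v = make_variant(votes=4, het_af=8.2e-6)
        e = EvidenceBundle(prior_report=PriorReport.SAME_RESIDUE_DIFFERENT_CHANGE)
        acmg, codes = acmg_lite(v, e)
        assert acmg is AcmgClass.LP
        assert {"PM2", "PM5", "PP3"} <= set(codes)

    def test_de_novo_missense_stays_vus(self):
        v = make_variant(votes=3, het_af=0.0)
        e = EvidenceBundle(de_novo=DeNovoStatus.CONFIRMED)
        acmg, _ = acmg_lite(v, e)
        assert acmg is AcmgClass.VUS

    def test_nonsegregating_missense_is_likely_benign(self):
        v = make_variant(votes=3, het_af=0.0)
        e = EvidenceBundle(segregation=SegregationStatus.NONSEGREGATING)
        acmg, codes = acmg_lite(v, e)
        assert acmg is AcmgClass.LB and "BS4" in codes

    def test_null_variant_on_rarity_alone_stays_vus(self):
        v = make_variant(consequence=Consequence.FRAMESHIFT, het_af=0.0)
        acmg, _ = acmg_lite(v, EvidenceBundle())
        assert acmg is AcmgClass.VUS


class TestCategorize:
    def test_vus_with_confirmed_de_novo_and_prior_report_is_causal(self):
        v = make_variant(votes=3, het_af=0.0,
                         prior=PriorReport.SAME_VARIANT_COMPARABLE_PHENOTYPE)
        e = EvidenceBundle(
            de_novo=DeNovoStatus.CONFIRMED,
            prior_report=PriorReport.SAME_VARIANT_COMPARABLE_PHENOTYPE,
        )
        res = categorize(v, e, family="2")
        assert res.category is Category.POTENTIALLY_DISEASE_CAUSING
        assert res.acmg is AcmgClass.VUS

    def test_functional_refutation_excludes(self):
        v = make_variant(
            consequence=Consequence.INTRONIC, boundary_distance=-15, het_af=0.0
        )
        e = EvidenceBundle(
            functional=FunctionalEvidence.REFUTES, functional_ref="minigene assay"
        )
        res = categorize(v, e, family="8")
        assert res.category is Category.EXCLUDED
        assert "excluded:functional-refuted" in res.triggered_rules

    def test_alternative_cause_makes_lower_tier_variant_incidental(self):
        v = make_variant(votes=3, het_af=0.0)
        e = EvidenceBundle(
            segregation=SegregationStatus.SEGREGATES,
            inheritance_fit=InheritanceFit.DOMINANT_FIT,
            alternative_cause_in_family=True,
        )
        res = categorize(v, e, family="1")
        assert res.category is Category.EXCLUDED and res.incidental

    def test_unsupported_vus_is_additional(self):
        v = make_variant(votes=3, het_af=0.0)
        res = categorize(v, EvidenceBundle(), family="9")
        assert res.category is Category.ADDITIONAL_VARIANT

    def test_functional_refutes_requires_assay_reference(self):
        with pytest.raises(ValueError, match="assay"):
            EvidenceBundle(functional=FunctionalEvidence.REFUTES)


# -- monotonicity properties -------------------------------------------------

_CATEGORY_RANK = {
    Category.EXCLUDED: 0,
    Category.ADDITIONAL_VARIANT: 1,
    Category.POTENTIALLY_DISEASE_CAUSING: 2,
}

_evidence_strategy = st.builds(
    EvidenceBundle,
    de_novo=st.sampled_from(list(DeNovoStatus)),
    segregation=st.sampled_from(
        [None, SegregationStatus.SEGREGATES, SegregationStatus.UNINFORMATIVE,
         SegregationStatus.NONSEGREGATING]
    ),
    prior_report=st.sampled_from(list(PriorReport)),
    inheritance_fit=st.sampled_from(list(InheritanceFit)),
    alternative_cause_in_family=st.booleans(),
)

_variant_strategy = st.builds(
    make_variant,
    consequence=st.sampled_from([Consequence.MISSENSE, Consequence.FRAMESHIFT]),
    votes=st.integers(min_value=0, max_value=5),
    het_af=st.floats(min_value=0, max_value=0.01),
)


@given(v=_variant_strategy, e=_evidence_strategy)
@settings(max_examples=200, deadline=None)
def test_supporting_evidence_never_demotes(v, e):
    base = categorize(v, e, family="F")
    stronger = EvidenceBundle(
        de_novo=DeNovoStatus.CONFIRMED,
        segregation=(
            e.segregation
            if e.segregation is SegregationStatus.NONSEGREGATING
            else SegregationStatus.SEGREGATES
        ),
        prior_report=e.prior_report,
        functional=e.functional,
        functional_ref=e.functional_ref,
        inheritance_fit=(
            e.inheritance_fit
            if e.inheritance_fit is not InheritanceFit.NONE
            else InheritanceFit.DOMINANT_FIT
        ),
        alternative_cause_in_family=e.alternative_cause_in_family,
    )
    boosted = categorize(v, stronger, family="F")
    assert _CATEGORY_RANK[boosted.category] >= _CATEGORY_RANK[base.category]
    assert ACMG_RANK[boosted.acmg] >= ACMG_RANK[base.acmg]


@given(v=_variant_strategy, e=_evidence_strategy)
@settings(max_examples=200, deadline=None)
def test_benign_evidence_never_promotes(v, e):
    base = categorize(v, e, family="F")
    weaker = EvidenceBundle(
        de_novo=e.de_novo,
        segregation=SegregationStatus.NONSEGREGATING,
        prior_report=e.prior_report,
        functional=FunctionalEvidence.REFUTES,
        functional_ref="assay",
        inheritance_fit=e.inheritance_fit,
        alternative_cause_in_family=e.alternative_cause_in_family,
    )
    demoted = categorize(v, weaker, family="F")
    assert _CATEGORY_RANK[demoted.category] <= _CATEGORY_RANK[base.category]


@pytest.mark.parametrize(
    "solved,total,expected",
    [(4, 6, 67), (6, 13, 46), (7, 15, 47), (7, 12, 58), (3, 7, 43)],
)
def test_percentages_round_half_away_from_zero(solved, total, expected):
    assert round_half_away(100.0 * solved / total) == expected


class TestSummary:
    def test_zero_classifications_zero_rates(self, fixture_bundle):
        summary = summarize_cohort(fixture_bundle.cohort, [])
        assert summary.families.solved == 0
        assert summary.families.percent == 0
        assert summary.strata["affected"].total == 19

    def test_family_without_index_rejected(self, fixture_bundle):
        cohort = [i for i in fixture_bundle.cohort if not i.is_index]
        with pytest.raises(ValueError, match="index"):
            summarize_cohort(cohort, [])


@pytest.fixture(scope="module")
def result(fixture_bundle):
    return prioritize_cohort(
        fixture_bundle.variants,
        fixture_bundle.cohort,
        fixture_bundle.panel,
        cnv_events=fixture_bundle.cnv_events,
        str_profiles=fixture_bundle.str_profiles,
        overrides=fixture_bundle.overrides,
    )


class TestReport:
    def test_causal_section_lists_the_eight_events(self, result):
        text = render_report(result.summary, result.classifications, fmt="markdown")
        section = text.split("## Potentially disease-causing")[1].split("## ")[0]
        assert section.count("\n- ") == 8
        for gene in ("CRIM1", "CHD7", "FAT1", "PTCH1", "PUF60", "BRPF1", "TGFB2"):
            assert gene in section

    def test_reports_are_deterministic(self, result):
        once = render_report(result.summary, result.classifications, fmt="tsv")
        twice = render_report(
            result.summary, list(reversed(result.classifications)), fmt="tsv"
        )
        assert once == twice

    def test_empty_cohort_report_is_header_only(self, fixture_bundle):
        summary = summarize_cohort(fixture_bundle.cohort, [])
        text = render_report(summary, [], fmt="tsv")
        assert text == "FAMILY\tVARIANT\tACMG\tCATEGORY\tRULES\n"
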