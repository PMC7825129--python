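"""Filter cascade: gates, routing, oracle equivalence, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_variant
from macprio import (
    FilterConfig,
    frequency_gate,
    positional_gate,
    predictor_consensus,
    restrict_to_panel,
    route_variant,
    run_cascade,
)
from macprio.model import (
    Consequence,
    GenePanel,
    GvgdGrade,
    MutationTasterCall,
    PredictionProfile,
    PriorReport,
)


class TestFrequencyGate:
    def test_ultra_rare_passes(self, default_config):
        v = make_variant(het_af=8.2e-6, hom_af=0.0)
        assert frequency_gate(v, default_config).passed

    def test_common_het_fails(self, default_config):
        v = make_variant(het_af=0.02)
        res = frequency_gate(v, default_config)
        assert not res.passed and "het_af" in res.reason

    def test_hom_gate_literal_percent_reading(self, default_config):
        # 1e-6 exceeds the 1e-7 default (0.00001% read as a percentage)
        v = make_variant(het_af=0.005, hom_af=1e-6)
        res = frequency_gate(v, default_config)
        assert not res.passed and "hom_af" in res.reason

    def test_hom_gate_fraction_reading_configurable(self):
        cfg = FilterConfig(hom_af_max=1e-5)
        v = make_variant(het_af=0.005, hom_af=1e-6)
        assert frequency_gate(v, cfg).passed


class TestPredictorConsensus:
    def test_three_of_five_like_chd7(self, default_config):
        p = PredictionProfile(
            mutation_taster=MutationTasterCall.DISEASE_CAUSING,
            fathmm_mkl=0.95,
            cadd_phred=15.4,
            sift=0.4,
            align_gvgd=GvgdGrade.C0,
        )
        assert predictor_consensus(p, default_config) == (3, True)

    def test_four_of_five_like_tgfb2(self, default_config):
        p = PredictionProfile(
            sift=0.0,
            mutation_taster=MutationTasterCall.DISEASE_CAUSING,
            fathmm_mkl=0.98,
            cadd_phred=35.0,
            align_gvgd=GvgdGrade.C0,
        )
        assert predictor_consensus(p, default_config) == (4, True)

    def test_all_missing_fails(self, default_config):
        assert predictor_consensus(PredictionProfile(), default_config) == (0, False)


class TestPositionalGate:
    @pytest.mark.parametrize("dist,expected", [(-15, True), (-18, True), (-30, True), (-31, False)])
    def test_splice_window(self, default_config, dist, expected):
        v = make_variant(consequence=Consequence.INTRONIC, boundary_distance=dist)
        assert positional_gate(v, default_config).passed is expected

    def test_applies_only_to_splice_region_classes(self, default_config):
        with pytest.raises(ValueError):
            positional_gate(make_variant(), default_config)


class TestRouting:
    def test_frameshift_passes_as_lof(self, default_config):
        verdict = route_variant(
            make_variant(consequence=Consequence.FRAMESHIFT), default_config
        )
        assert verdict.passed
        assert any("LoF" in s.reason for s in verdict.stage_log)

    def test_missense_below_consensus_fails(self, default_config):
        verdict = route_variant(make_variant(votes=2), default_config)
        assert not verdict.passed

    def test_intronic_without_predicted_alteration_is_fallback_only(self, default_config):
        v = make_variant(
            consequence=Consequence.INTRONIC, boundary_distance=-15, splice_delta=0.0
        )
        verdict = route_variant(v, default_config)
        assert verdict.passed and verdict.fallback_only and not verdict.prioritized

    def test_intronic_with_predicted_alteration_is_prioritized(self, default_config):
        v = make_variant(
            consequence=Consequence.INTRONIC, boundary_distance=-18, splice_delta=-0.2
        )
        verdict = route_variant(v, default_config)
        assert verdict.passed and verdict.prioritized

    def test_utr_rescued_only_by_prior_report(self, default_config):
        fails = route_variant(make_variant(consequence=Consequence.UTR), default_config)
        rescued = route_variant(
            make_variant(
                consequence=Consequence.UTR,
                prior=PriorReport.SAME_VARIANT_COMPARABLE_PHENOTYPE,
            ),
            default_config,
        )
        assert not fails.passed
        assert rescued.passed and rescued.rescued


def test_panel_restriction_preserves_order():
    panel = GenePanel(entries=frozenset({"CRIM1", "PAX6"}))
    kept = make_variant(gene="CRIM1", pos=10)
    dropped = make_variant(gene="NOTPANEL", pos=20)
    kept2 = make_variant(gene="PAX6", pos=30)
    assert restrict_to_panel([kept, dropped, kept2], panel) == [kept, kept2]
    assert restrict_to_panel([], panel) == []


def _benign_rows():
    """50 deterministic benign rows that the cascade must reject."""
    rows = []
    for i in range(20):  # missense without consensus
        rows.append(make_variant(gene="PAX6", votes=i % 3, pos=10_000 + i))
    for i in range(15):  # too common
        rows.append(make_variant(gene="SOX2", votes=5, het_af=0.05, pos=20_000 + i))
    for i in range(15):  # intronic far from the boundary
        rows.append(
            make_variant(
                gene="OTX2",
                consequence=Consequence.INTRONIC,
                boundary_distance=-40 - i,
                pos=30_000 + i,
            )
        )
    return rows


class TestRunCascade:
    def test_fixture_rows_all_pass(self, fixture_bundle, default_config):
        verdicts = run_cascade(
            fixture_bundle.variants, fixture_bundle.panel, default_config
        )
        assert sum(v.passed for v in verdicts) == 13

    def test_fixture_plus_benign_background_passes_exactly_13(
        self, fixture_bundle, default_config
    ):
        variants = fixture_bundle.variants + _benign_rows()
        verdicts = run_cascade(variants, fixture_bundle.panel, default_config)
        assert sum(v.passed for v in verdicts) == 13

    def test_common_cohort_yields_zero_passes(self, fixture_bundle, default_config):
        variants = [
            make_variant(gene=g, het_af=0.5, pos=i)
            for i, g in enumerate(["CRIM1", "CHD7", "PAX6"], start=1)
        ]
        verdicts = run_cascade(variants, fixture_bundle.panel, default_config)
        assert sum(v.passed for v in verdicts) == 0

    def test_single_candidate_row_in_isolation(self, fixture_bundle, default_config):
        puf60 = [v for v in fixture_bundle.variants if v.gene == "PUF60"]
        verdicts = run_cascade(puf60, fixture_bundle.panel, default_config)
        assert [v.passed for v in verdicts] == [True]


# ---------------------------------------------------------------------------
# Properties

def _oracle(v, panel, cfg):
    """Direct evaluation of the written rule table, independent of the
    cascade implementation."""
    if panel is not None and v.gene not in panel.entries:
        return False
    if v.het_af > cfg.het_af_max or v.hom_af > cfg.hom_af_max:
        return False
    c = v.consequence
    if c in (Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.CANONICAL_SPLICE):
        return True
    if c is Consequence.MISSENSE:
        p = v.predictions
        votes = sum(
            [
                p.sift is not None and p.sift <= cfg.sift_max,
                p.mutation_taster is MutationTasterCall.DISEASE_CAUSING,
                p.fathmm_mkl is not None and p.fathmm_mkl >= cfg.fathmm_min,
                p.cadd_phred is not None and p.cadd_phred >= cfg.cadd_min,
                p.align_gvgd is not None and p.align_gvgd >= cfg.gvgd_min_grade,
            ]
        )
        return votes >= cfg.consensus_required
    if c in (Consequence.SYNONYMOUS, Consequence.INTRONIC):
        return abs(v.boundary_distance) <= cfg.splice_window
    return v.prior_report is not PriorReport.NONE


_variant_strategy = st.builds(
    make_variant,
    gene=st.sampled_from(["CRIM1", "PAX6", "SOX2", "NOTPANEL"]),
    consequence=st.sampled_from(
        [
            Consequence.MISSENSE,
            Consequence.FRAMESHIFT,
            Consequence.NONSENSE,
            Consequence.UTR,
            Consequence.OTHER,
        ]
    ),
    het_af=st.floats(min_value=0, max_value=0.05),
    hom_af=st.floats(min_value=0, max_value=1e-5),
    votes=st.integers(min_value=0, max_value=5),
    prior=st.sampled_from(list(PriorReport)),
) | st.builds(
    make_variant,
    gene=st.sampled_from(["CRIM1", "PAX6"]),
    consequence=st.sampled_from([Consequence.SYNONYMOUS, Consequence.INTRONIC]),
    boundary_distance=st.integers(min_value=-60, max_value=60),
    het_af=st.floats(min_value=0, max_value=0.05),
    splice_delta=st.one_of(st.none(), st.floats(min_value=-1, max_value=0)),
)

_panel = GenePanel(entries=frozenset({"CRIM1", "PAX6", "SOX2"}))


@settings(max_examples=200, deadline=None)
@given(v=_variant_strategy)
def test_cascade_matches_brute_force_oracle(v, default_config):
    (verdict,) = run_cascade([v], _panel, default_config)
    assert verdict.passed == _oracle(v, _panel, default_config)


@settings(max_examples=100, deadline=None)
@given(
    v=_variant_strategy,
    d_af=st.floats(min_value=0, max_value=0.009),
    d_votes=st.integers(min_value=0, max_value=2),
    d_window=st.integers(min_value=0, max_value=25),
)
def test_tightening_thresholds_never_grows_pass_set(v, d_af, d_votes, d_window):
    loose = FilterConfig()
    tight = FilterConfig(
        het_af_max=loose.het_af_max - d_af,
        consensus_required=min(5, loose.consensus_required + d_votes),
        splice_window=loose.splice_window - d_window,
    )
    (loose_v,) = run_cascade([v], _panel, loose)
    (tight_v,) = run_cascade([v], _panel, tight)
    assert not (tight_v.passed and not loose_v.passed)


def test_verdicts_independent_of_input_order(fixture_bundle, default_config):
    variants = fixture_bundle.variants + _benign_rows()
    fwd = run_cascade(variants, fixture_bundle.panel, default_config)
    rev = run_cascade(variants[::-1], fixture_bundle.panel, default_config)
    fwd_map = {v.variant.key: v.passed for v in fwd}
    rev_map = {v.variant.key: v.passed for v in rev}
    assert fwd_map == rev_map
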