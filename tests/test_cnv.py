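"""CNV calling, junction/microhomology resolution, multiplex span math."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from macprio import (
    CopyState,
    GenomicDeletion,
    JunctionRead,
    Primer,
    call_cnvs,
    deletion_span,
    multiplex_fragments,
    normalize_depth,
    resolve_junction,
    simulate_junction,
)


def _matrix(n_genes=3, exons=20, samples=("S1", "S2", "S3", "S4"), depth=100.0):
    targets = []
    for g in range(n_genes):
        gene = f"G{g}"
        for e in range(1, exons + 1):
            start = 1_000_000 * (g + 1) + 1_000 * e
            targets.append((gene, e, "2", start, start + 150))
    index = pd.MultiIndex.from_tuples(
        targets, names=["GENE", "EXON", "CHROM", "START", "END"]
    )
    return pd.DataFrame(
        {s: np.full(len(targets), depth) for s in samples}, index=index
    )


class TestNormalize:
    def test_constant_matrix_gives_unit_ratios(self):
        norm, excluded = normalize_depth(_matrix())
        assert excluded == []
        assert np.allclose(norm.values, 1.0)

    def test_per_sample_scaling_invariance(self):
        m = _matrix()
        m["S2"] *= 2.0
        norm, _ = normalize_depth(m)
        assert np.allclose(norm.values, 1.0)

    def test_spiked_exons_near_half(self):
        m = _matrix()
        m.iloc[14:17, m.columns.get_loc("S1")] = 50.0  # exons 15-17 of G0
        norm, _ = normalize_depth(m)
        assert np.allclose(norm["S1"].values[14:17], 0.5, atol=0.02)

    def test_zero_median_target_excluded(self):
        m = _matrix()
        m.iloc[0, :] = 0.0
        norm, excluded = normalize_depth(m)
        assert len(excluded) == 1 and len(norm) == len(m) - 1

    def test_requires_reference(self):
        m = _matrix(samples=("S1",))
        with pytest.raises(ValueError, match="reference"):
            normalize_depth(m)


class TestCallCnvs:
    def test_het_deletion_spanning_exons_15_17(self):
        m = _matrix()
        m.iloc[14:17, m.columns.get_loc("S1")] = 50.0
        norm, _ = normalize_depth(m)
        calls = call_cnvs(norm)
        assert len(calls) == 1
        (call,) = calls
        assert call.sample == "S1"
        assert call.copy_state is CopyState.HET_DEL
        assert (call.first_exon, call.last_exon) == (15, 17)
        assert call.genes == ("G0",)

    def test_quiet_matrix_yields_no_calls(self):
        norm, _ = normalize_depth(_matrix())
        assert call_cnvs(norm) == []

    def test_single_exon_event_below_min_exons_not_called(self):
        m = _matrix()
        m.iloc[4, m.columns.get_loc("S1")] = 50.0
        norm, _ = normalize_depth(m)
        assert call_cnvs(norm) == []

    def test_calls_invariant_to_depth_scaling(self):
        m = _matrix()
        m.iloc[14:17, m.columns.get_loc("S1")] = 50.0
        norm1, _ = normalize_depth(m)
        norm2, _ = normalize_depth(m * 3.7)
        c1, c2 = call_cnvs(norm1), call_cnvs(norm2)
        assert [(c.sample, c.first_exon, c.last_exon, c.copy_state) for c in c1] == [
            (c.sample, c.first_exon, c.last_exon, c.copy_state) for c in c2
        ]

    def test_recall_on_planted_deletions_with_depth_noise(self):
        """100 spiked 3-exon het deletions at 10% depth CV: recall >= 0.95
        and at most one false call in any sample."""
        rng = np.random.default_rng(2024)
        n_genes, exons, n_samples = 20, 8, 100
        targets = []
        for g in range(n_genes):
            for e in range(1, exons + 1):
                targets.append((f"G{g:02d}", e, "1", 10_000 * g + 100 * e, 10_000 * g + 100 * e + 80))
        index = pd.MultiIndex.from_tuples(
            targets, names=["GENE", "EXON", "CHROM", "START", "END"]
        )
        truth = {}
        cols = {}
        for i in range(n_samples):
            sample = f"S{i:03d}"
            copies = np.full(len(targets), 2.0)
            gene = int(rng.integers(n_genes))
            first = int(rng.integers(1, exons - 2))
            sl = slice(gene * exons + first - 1, gene * exons + first + 2)
            copies[sl] = 1.0
            truth[sample] = (f"G{gene:02d}", first, first + 2)
            mu = 100.0 * copies / 2
            cols[sample] = np.clip(rng.normal(mu, 0.10 * mu), 0, None)
        matrix = pd.DataFrame(cols, index=index)
        norm, _ = normalize_depth(matrix)
        calls = call_cnvs(norm)
        by_sample = {}
        for c in calls:
            by_sample.setdefault(c.sample, []).append(c)
        hits = 0
        for sample, (gene, first, last) in truth.items():
            found = any(
                c.copy_state is CopyState.HET_DEL
                and gene in c.genes
                and c.first_exon <= first
                and c.last_exon >= last - 0  # allow boundary jitter of the run
                or (
                    c.copy_state is CopyState.HET_DEL
                    and gene in c.genes
                    and c.n_targets >= 2
                    and not (c.last_exon < first or c.first_exon > last)
                )
                for c in by_sample.get(sample, [])
            )
            hits += found
            false_calls = [
                c
                for c in by_sample.get(sample, [])
                if gene not in c.genes
            ]
            assert len(false_calls) <= 1
        assert hits / n_samples >= 0.95


# ---------------------------------------------------------------------------
# Junction resolution

def brute_force_resolve(j: JunctionRead):
    """Enumerate every split of the junction read; the oracle for
    resolve_junction."""
    n = len(j.sequence)
    valid = []
    for a in range(n + 1):
        b = a + len(j.distal_seq) - n
        if b < 0 or b > len(j.distal_seq) or a > len(j.proximal_seq):
            continue
        if j.sequence == j.proximal_seq[:a] + j.distal_seq[b:]:
            valid.append((a, b))
    if not valid:
        return None
    a_lo = min(a for a, _ in valid)
    a_hi = max(a for a, _ in valid)
    b_hi = a_hi + len(j.distal_seq) - n
    return {
        "microhomology": j.sequence[a_lo:a_hi],
        "first_deleted": j.proximal_offset + a_hi,
        "last_deleted": j.distal_offset + b_hi - 1,
    }


class TestResolveJunction:
    def test_ct_microhomology_like_crim1(self):
        _, junction, truth = simulate_junction(
            reference_length=400, deletion_span=150, microhomology_length=2,
            seed=11, motif="CT",
        )
        resolved = resolve_junction(junction)
        assert resolved.microhomology == "CT"
        assert (resolved.first_deleted, resolved.last_deleted) == (
            truth.first_deleted, truth.last_deleted,
        )

    def test_zero_microhomology(self):
        _, junction, truth = simulate_junction(400, 100, 0, seed=3)
        resolved = resolve_junction(junction)
        assert resolved.microhomology == ""
        assert resolved.first_deleted == truth.first_deleted

    def test_inconsistent_read_is_an_error(self):
        j = JunctionRead(
            sequence="AAAATTTT",
            proximal_seq="CCCCCCCC",
            proximal_offset=1,
            distal_seq="GGGGGGGG",
            distal_offset=100,
        )
        with pytest.raises(ValueError, match="junction"):
            resolve_junction(j)

    @given(
        span=st.integers(min_value=30, max_value=300),
        k=st.integers(min_value=0, max_value=6),
        seed=st.integers(min_value=0, max_value=10**6),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_brute_force_oracle(self, span, k, seed):
        _, junction, truth = simulate_junction(
            reference_length=2 * span + 400, deletion_span=span,
            microhomology_length=k, seed=seed,
        )
        resolved = resolve_junction(junction)
        oracle = brute_force_resolve(junction)
        assert oracle is not None
        assert resolved.microhomology == oracle["microhomology"]
        assert resolved.first_deleted == oracle["first_deleted"]
        assert resolved.last_deleted == oracle["last_deleted"]
        assert len(resolved.microhomology) == k
        assert resolved.first_deleted == truth.first_deleted
        assert resolved.last_deleted == truth.last_deleted


# ---------------------------------------------------------------------------
# Multiplex PCR arithmetic

class TestMultiplexFragments:
    def test_deleted_allele_product_is_reference_minus_span(self, fixture_bundle):
        primers = fixture_bundle.crim1_primers()
        deletion = fixture_bundle.crim1_deletion()
        products, warnings = multiplex_fragments(primers, deletion)
        ref = {(p.forward, p.length) for p in products if p.allele == "reference"}
        dele = {(p.forward, p.length) for p in products if p.allele == "deleted"}
        assert ("CRIM1_int13_F", 22_240) in ref
        assert ("CRIM1_int15_F", 9_612) in ref
        assert ("CRIM1_int13_F", 13_232) in dele
        # internal forward primer sits inside the deletion: no deleted product
        assert not any(f == "CRIM1_int15_F" for f, _ in dele)
        assert any("CRIM1_int15_F" in w for w in warnings)

    def test_no_deletion_reference_products_only(self, fixture_bundle):
        products, warnings = multiplex_fragments(fixture_bundle.crim1_primers(), None)
        assert warnings == []
        assert {p.allele for p in products} == {"reference"}

    @given(
        f_pos=st.integers(min_value=1, max_value=1000),
        gap=st.integers(min_value=200, max_value=5000),
        del_start=st.integers(min_value=50, max_value=150),
        del_len=st.integers(min_value=1, max_value=40),
    )
    @settings(max_examples=100, deadline=None)
    def test_spanned_deletion_shrinks_product_by_span(self, f_pos, gap, del_start, del_len):
        r_pos = f_pos + gap
        deletion = GenomicDeletion("1", f_pos + del_start, f_pos + del_start + del_len - 1)
        primers = [Primer("F", f_pos, "+"), Primer("R", r_pos, "-")]
        products, _ = multiplex_fragments(primers, deletion)
        ref = next(p for p in products if p.allele == "reference")
        dele = next(p for p in products if p.allele == "deleted")
        assert ref.length - dele.length == deletion_span(deletion)
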