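"""indel_catalog: normalization, group-common sets, specific selection,
densities — each checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from indelmark import indel_catalog
from indelmark.errors import DesignError, ReferenceMismatchError
from indelmark.genome_io import ReferenceGenome, SampleCallSet, VariantCall
from indelmark.indel_catalog import (
    IndelVariant,
    between_group_diff,
    density_table,
    group_common,
    normalize,
    specific_indels,
)
from indelmark.synthetic_data import GROUP_A, GROUP_B


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1:pos - 1 + len(ref)] == ref
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def oracle_normalize(seq: str, edited: str) -> tuple[int, str, str]:
    """Canonical left-aligned InDel between two strings differing by one
    indel: longest common prefix/suffix, then the VCF anchor-base form."""
    # maximize the common suffix first: that is what left-alignment means
    lcs = 0
    while (lcs < min(len(seq), len(edited))
           and seq[len(seq) - 1 - lcs] == edited[len(edited) - 1 - lcs]):
        lcs += 1
    lcp = 0
    while (lcp < min(len(seq), len(edited)) - lcs
           and seq[lcp] == edited[lcp]):
        lcp += 1
    ref_core = seq[lcp:len(seq) - lcs]
    alt_core = edited[lcp:len(edited) - lcs]
    anchor = seq[lcp - 1]
    return lcp, anchor + ref_core, anchor + alt_core


class TestNormalize:
    def test_left_shift_through_repeat_run(self):
        """An insertion anchored mid-run must shift to the leftmost
        equivalent anchor; the expectation comes from the string-diff oracle."""
        seq = "GGGGGGGGGT" + "AAAA" + "CGGGGGGGGG"
        ref_g = ReferenceGenome({"chr1": seq})
        # insert "AA" anchored at the 3rd A (pos 13, 1-based)
        v = normalize("chr1", 13, "A", "AAA", ref_g)
        edited = apply_variant(seq, 13, "A", "AAA")
        pos, ref, alt = oracle_normalize(seq, edited)
        assert (v.pos, v.ref, v.alt) == (pos, ref, alt)
        assert v.pos == 10 and v.ref == "T"  # anchored on the base before the run

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_string_diff_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        seq = seq[:200] + "ATATATATAT" + seq[200:]  # a repeat to shift through
        ref_g = ReferenceGenome({"c": seq})
        pos = int(rng.integers(150, 250))
        if rng.random() < 0.5:
            length = int(rng.integers(1, 12))
            ref, alt = seq[pos - 1], seq[pos - 1] + "".join(
                rng.choice(list("ACGT"), size=length))
        else:
            length = int(rng.integers(1, 12))
            ref, alt = seq[pos - 1:pos + length], seq[pos - 1]
        v = normalize("c", pos, ref, alt, ref_g)
        opos, oref, oalt = oracle_normalize(seq, apply_variant(seq, pos, ref, alt))
        assert (v.pos, v.ref, v.alt) == (opos, oref, oalt)

    def test_idempotent(self):
        ref_g = ReferenceGenome({"c": "GGTAAAACCC"})
        v = normalize("c", 3, "TA", "T", ref_g)
        v2 = normalize(v.chromosome, v.pos, v.ref, v.alt, ref_g)
        assert v == v2

    def test_equal_length_rejected(self):
        ref_g = ReferenceGenome({"c": "ACGTACGT"})
        with pytest.raises(DesignError, match="not an InDel"):
            normalize("c", 1, "ACGT", "ACGA", ref_g)

    def test_reference_mismatch_names_site(self):
        ref_g = ReferenceGenome({"c": "ACGTACGT"})
        with pytest.raises(ReferenceMismatchError, match="c:2"):
            normalize("c", 2, "TT", "T", ref_g)


def _cohort_from_matrix(reference, variants, presence, group):
    """Build SampleCallSets from a variant × sample presence matrix."""
    call_sets = []
    for s, col in enumerate(presence.T):
        calls = [
            VariantCall(v.chromosome, v.pos, v.ref, v.alt)
            for v, present in zip(variants, col) if present
        ]
        call_sets.append(
            SampleCallSet(sample_id=f"{group}{s}", group=group, variants=calls)
        )
    return call_sets


@pytest.fixture()
def toy_reference():
    rng = np.random.default_rng(99)
    return ReferenceGenome({"c1": "".join(rng.choice(list("ACGT"), size=5000))})


def _toy_variants(reference, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pos = 50 + i * 90
        length = int(rng.integers(5, 20))
        seq = reference.sequences["c1"]
        out.append(normalize("c1", pos, seq[pos - 1:pos + length],
                             seq[pos - 1], reference))
    return out


class TestGroupCommon:
    def test_all_members_required(self, toy_reference):
        variants = _toy_variants(toy_reference, 2, 0)
        presence = np.array([[1, 1, 1], [1, 1, 0]], dtype=bool)
        cat = group_common(
            _cohort_from_matrix(toy_reference, variants, presence, "g"),
            toy_reference)
        assert cat.common == {variants[0]}

    def test_empty_group_rejected(self, toy_reference):
        with pytest.raises(DesignError, match="empty"):
            group_common([], toy_reference)

    def test_planted_cohort_common_count(self, tiny_catalogs, tiny_design):
        d = tiny_design
        assert len(tiny_catalogs[GROUP_B].common) == (
            d.n_group_specific + d.n_group_common_shared + d.n_sub_threshold)
        assert len(tiny_catalogs[GROUP_A].common) == d.n_group_common_shared

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_presence_matrix_oracle(self, toy_reference, seed):
        """On <=5 samples x <=50 variants, group_common and specific_indels
        agree with a direct scan of the presence matrix."""
        rng = np.random.default_rng(seed)
        variants = _toy_variants(toy_reference, int(rng.integers(10, 50)), seed)
        n_a, n_b = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pres_a = rng.random((len(variants), n_a)) < 0.6
        pres_b = rng.random((len(variants), n_b)) < 0.6
        cat_a = group_common(
            _cohort_from_matrix(toy_reference, variants, pres_a, "A"),
            toy_reference)
        cat_b = group_common(
            _cohort_from_matrix(toy_reference, variants, pres_b, "B"),
            toy_reference)
        # oracle: row-wise scan
        expect_common_b = {v for v, row in zip(variants, pres_b) if row.all()}
        assert cat_b.common == expect_common_b
        expect_spec = {
            v for v, ra, rb in zip(variants, pres_a, pres_b)
            if rb.all() and not ra.any() and abs(v.length) > 10
        }
        got = specific_indels(cat_b, cat_a, min_len=10)
        assert set(got.variants) == expect_spec

    def test_subset_group_grows_common(self, tiny_cohort, tiny_reference):
        call_sets, _ = tiny_cohort
        members = [cs for cs in call_sets if cs.group == GROUP_B]
        full = group_common(members, tiny_reference).common
        subset = group_common(members[:2], tiny_reference).common
        assert full <= subset


class TestSpecificIndels:
    def test_planted_specifics_recovered(self, tiny_catalogs, tiny_cohort):
        _, truth = tiny_cohort
        spec = specific_indels(tiny_catalogs[GROUP_B], tiny_catalogs[GROUP_A])
        expect = {
            (r.chromosome, r.position_1based, r.ref, r.alt)
            for r in truth[truth["eligible"]].itertuples()
        }
        assert {v.key for v in spec.variants} == expect
        assert all(spec.rule_trace[v.key] for v in spec.variants)

    def test_shared_variants_excluded(self, tiny_catalogs, tiny_cohort):
        _, truth = tiny_cohort
        spec = specific_indels(tiny_catalogs[GROUP_B], tiny_catalogs[GROUP_A])
        shared = {
            (r.chromosome, r.position_1based)
            for r in truth[truth["class"] == "group_common_shared"].itertuples()
        }
        assert not {(v.chromosome, v.pos) for v in spec.variants} & shared

    def test_length_exactly_10_excluded(self, toy_reference):
        """The size filter is strict: 'larger than 10 bp' keeps 11 and drops 10."""
        seq = toy_reference.sequences["c1"]
        v10 = normalize("c1", 100, seq[99:110], seq[99], toy_reference)
        v11 = normalize("c1", 300, seq[299:311], seq[299], toy_reference)
        assert abs(v10.length) == 10 and abs(v11.length) == 11
        pres_b = np.ones((2, 3), dtype=bool)
        cat_b = group_common(
            _cohort_from_matrix(toy_reference, [v10, v11], pres_b, "B"),
            toy_reference)
        cat_a = group_common(
            [SampleCallSet(f"A{i}", "A", []) for i in range(2)], toy_reference)
        spec = specific_indels(cat_b, cat_a, min_len=10)
        assert [v.length for v in spec.variants] == [v11.length]

    def test_mutually_exclusive_between_directions(self, tiny_catalogs):
        b_spec = specific_indels(tiny_catalogs[GROUP_B], tiny_catalogs[GROUP_A])
        a_spec = specific_indels(tiny_catalogs[GROUP_A], tiny_catalogs[GROUP_B])
        assert not set(b_spec.variants) & set(a_spec.variants)


class TestDensityTable:
    def _uniform_variants(self, n, chrom_len):
        step = chrom_len // n
        return [IndelVariant("c", 1 + i * step, "AT", "A") for i in range(n)]

    def test_uniform_density_arithmetic(self):
        table = density_table(self._uniform_variants(50, 500_000),
                              {"c": 500_000})
        row = table.per_chromosome.iloc[0]
        assert row["count"] == 50
        assert row["density_per_mb"] == pytest.approx(100.0)
        assert len(table.windows) == 5
        assert table.windows["count"].sum() == 50
        table.check()

    def test_empty_set_all_zero(self):
        table = density_table([], {"c": 250_000})
        assert (table.windows["count"] == 0).all()
        assert table.per_chromosome.iloc[0]["count"] == 0
        table.check()

    def test_window_boundary_pos_100000_in_window_0(self):
        """1-based 100,000 is 0-based 99,999 → window [0, 100000) → index 0;
        1-based 100,001 starts window 1."""
        t = density_table([IndelVariant("c", 100_000, "AT", "A")],
                          {"c": 300_000})
        hit = t.windows[t.windows["count"] > 0]
        assert list(hit["window_index"]) == [0]
        t2 = density_table([IndelVariant("c", 100_001, "AT", "A")],
                           {"c": 300_000})
        assert list(t2.windows[t2.windows["count"] > 0]["window_index"]) == [1]

    def test_last_window_truncated(self):
        t = density_table([], {"c": 250_000})
        last = t.windows.iloc[-1]
        assert (last["start_1based"], last["end_1based"]) == (200_001, 250_000)

    def test_variant_beyond_chromosome_rejected(self):
        with pytest.raises(DesignError, match="beyond"):
            density_table([IndelVariant("c", 600_000, "AT", "A")],
                          {"c": 500_000})

    def test_bookkeeping_on_planted_cohort(self, tiny_catalogs, tiny_reference):
        t = density_table(tiny_catalogs[GROUP_B].common,
                          tiny_reference.lengths)
        t.check()
        assert t.per_chromosome["count"].sum() == len(
            tiny_catalogs[GROUP_B].common)


class TestBetweenGroupDiff:
    def test_disjoint_catalogs_sum(self, toy_reference):
        variants = _toy_variants(toy_reference, 7, 1)
        cat_a = group_common(
            _cohort_from_matrix(toy_reference, variants[:3],
                                np.ones((3, 2), dtype=bool), "A"),
            toy_reference)
        cat_b = group_common(
            _cohort_from_matrix(toy_reference, variants[3:],
                                np.ones((4, 2), dtype=bool), "B"),
            toy_reference)
        out = between_group_diff(cat_a, cat_b, ["c1"])
        assert out.iloc[0]["n_differing"] == 7
        assert out.iloc[-1]["n_differing"] == 7  # mean over one chromosome

    def test_identical_catalogs_zero(self, toy_reference):
        variants = _toy_variants(toy_reference, 5, 2)
        mk = lambda g: group_common(
            _cohort_from_matrix(toy_reference, variants,
                                np.ones((5, 2), dtype=bool), g),
            toy_reference)
        out = between_group_diff(mk("A"), mk("B"), ["c1"])
        assert (out["n_differing"] == 0).all()

    def test_planted_cohort_matches_truth(self, tiny_catalogs, tiny_cohort,
                                          tiny_design):
        """Symmetric difference of common sets = specific + sub-threshold
        classes (shared variants cancel; privates are never group-common)."""
        _, truth = tiny_cohort
        out = between_group_diff(tiny_catalogs[GROUP_A],
                                 tiny_catalogs[GROUP_B],
                                 ["chr1", "chr2"])
        total = out[out["chromosome"] != "mean"]["n_differing"].sum()
        assert total == (tiny_design.n_group_specific
                         + tiny_design.n_sub_threshold)
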