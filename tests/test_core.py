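"""Classifier unit and property tests.

The reference for every property is the independent end-point-membership
oracle in ``oracles.py``, never the screening conditions themselves.
"""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisnat import (
    CisNatPair,
    GeneRecord,
    GeneTable,
    OverlapType,
    classify_candidate,
    dedup_unordered,
    find_cisnats,
    screening_condition,
    summarize_types,
    tss_of,
    tts_of,
)
from cisnat.core import PairSet

from .conftest import gene
from .oracles import oracle_classify, oracle_find

EB, FO, HH, TT = OverlapType.EB, OverlapType.FO, OverlapType.HH, OverlapType.TT


@pytest.mark.parametrize(
    "strand,start,end,tss,tts",
    [
        ("+", 100, 200, 100, 200),
        ("-", 100, 200, 200, 100),
        ("-", 102_503_972, 102_526_860, 102_526_860, 102_503_972),  # Xist-like span
        ("+", 5, 5, 5, 5),
    ],
)
def test_tss_tts_strand_convention(strand, start, end, tss, tts):
    g = gene("g", strand, start, end)
    assert tss_of(g) == tss
    assert tts_of(g) == tts


class TestScreeningCondition:
    def test_fully_overlapped_screen_for_minus_strand_target(self):
        """FO screen of a minus-strand target bounds the candidate's TSS
        above by the target start and its TTS below by the target end."""
        xist = gene("Xist", "-", 102_503_972, 102_526_860, chrom="X")
        cond = screening_condition(xist, FO)
        assert cond.candidate_strand == "+"
        assert cond.tss_bound == ("tss", "<=", 102_503_972)
        assert cond.tts_bound == ("tts", ">=", 102_526_860)
        # Tsix-like candidate covering the whole span passes the screen
        assert cond.satisfied_by(gene("Tsix", "+", 102_500_000, 102_530_000, chrom="X"))
        assert not cond.satisfied_by(gene("late", "+", 102_510_000, 102_530_000, chrom="X"))

    def test_embedded_screen_is_containment(self):
        cond = screening_condition(gene("t", "+", 100, 200), EB)
        assert cond.candidate_strand == "-"
        assert cond.satisfied_by(gene("c", "-", 100, 200))
        assert cond.satisfied_by(gene("c", "-", 120, 180))
        assert not cond.satisfied_by(gene("c", "-", 99, 180))

    def test_head_to_head_screen_strict_bounds(self):
        # target "+", candidate "-": a < S <= b < E
        cond = screening_condition(gene("t", "+", 100, 200), HH)
        assert cond.satisfied_by(gene("c", "-", 50, 150))
        assert cond.satisfied_by(gene("c", "-", 99, 100))  # single-base 5' touch
        assert not cond.satisfied_by(gene("c", "-", 100, 150))  # a == S not partial
        assert not cond.satisfied_by(gene("c", "-", 50, 200))  # b == E not partial

    def test_candidate_strand_is_opposite(self):
        for t in OverlapType:
            assert screening_condition(gene("t", "+", 10, 20), t).candidate_strand == "-"
            assert screening_condition(gene("t", "-", 10, 20), t).candidate_strand == "+"


@pytest.mark.parametrize(
    "t_strand,t_iv,c_strand,c_iv,expected",
    [
        ("+", (100, 200), "-", (120, 180), {EB}),
        ("+", (100, 200), "-", (50, 250), {FO}),
        ("+", (100, 200), "-", (50, 150), {HH}),
        ("+", (100, 200), "-", (150, 250), {TT}),
        ("-", (100, 200), "+", (50, 150), {TT}),  # strand flip swaps HH/TT
        ("-", (100, 200), "+", (150, 250), {HH}),
        ("+", (100, 200), "-", (100, 200), {EB, FO}),  # identical spans
        ("+", (100, 200), "+", (120, 180), set()),  # same strand
        ("+", (100, 200), "-", (300, 400), set()),  # no shared base
        ("+", (100, 200), "-", (200, 300), {TT}),  # single-base 3' touch
        ("+", (100, 200), "-", (50, 100), {HH}),  # single-base 5' touch
        ("+", (100, 200), "-", (100, 250), {FO}),  # shared start, non-strict
        ("+", (100, 200), "-", (100, 180), {EB}),
    ],
)
def test_classify_candidate_geometries(t_strand, t_iv, c_strand, c_iv, expected):
    target = gene("t", t_strand, *t_iv)
    cand = gene("c", c_strand, *c_iv)
    assert classify_candidate(target, cand) == expected
    assert oracle_classify(target, cand) == expected


def test_classify_candidate_different_chromosome():
    assert classify_candidate(
        gene("t", "+", 100, 200, chrom="chr1"), gene("c", "-", 100, 200, chrom="chr2")
    ) == set()


coords = st.integers(min_value=1, max_value=60)


@given(
    s1=coords, e1=coords, s2=coords, e2=coords,
    strands=st.sampled_from([("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]),
)
@settings(max_examples=400, deadline=None)
def test_classification_matches_end_membership_oracle(s1, e1, s2, e2, strands):
    """Exhaustive-ish enumeration over coordinate orderings: the
    screening conditions agree with the independent oracle, overlapping
    opposite-strand pairs get exactly one type (two iff identical
    spans), and everything else gets none."""
    t = gene("t", strands[0], min(s1, e1), max(s1, e1))
    c = gene("c", strands[1], min(s2, e2), max(s2, e2))
    got = classify_candidate(t, c)
    assert got == oracle_classify(t, c)
    opposite = t.strand != c.strand
    overlapping = not (c.end < t.start or c.start > t.end)
    if opposite and overlapping:
        identical = (t.start, t.end) == (c.start, c.end)
        assert len(got) == (2 if identical else 1)
    else:
        assert got == set()


class TestFindCisnats:
    def test_containment_duality(self, containment_table):
        pairs = find_cisnats(containment_table).as_set()
        assert pairs == {
            CisNatPair("inner", "outer", FO),
            CisNatPair("outer", "inner", EB),
        }

    def test_empty_table(self):
        assert len(find_cisnats(GeneTable([]))) == 0

    def test_single_strand_yields_nothing(self):
        table = GeneTable([gene(f"g{i}", "+", 10 * i + 1, 10 * i + 16) for i in range(10)])
        assert len(find_cisnats(table)) == 0

    def test_provenance_names_type_and_direction(self, containment_table):
        pairs = find_cisnats(containment_table)
        prov = {pairs.provenance_of(p) for p in pairs}
        assert prov == {"EB, plus-to-minus", "FO, minus-to-plus"}

    def test_one_gene_many_partners(self):
        """A hub gene pairs with every opposite-strand overlapper."""
        hub = gene("hub", "+", 100, 1000)
        partners = [gene(f"p{i}", "-", 150 + 100 * i, 180 + 100 * i) for i in range(5)]
        pairs = find_cisnats(GeneTable([hub] + partners))
        assert sum(1 for p in pairs if p.target_id == "hub") == 5
        assert len(pairs) == 10  # plus the 5 duals


@st.composite
def random_tables(draw):
    n = draw(st.integers(min_value=0, max_value=40))
    genes = []
    for i in range(n):
        start = draw(st.integers(min_value=1, max_value=500))
        length = draw(st.integers(min_value=0, max_value=120))
        genes.append(
            GeneRecord(
                f"g{i}",
                f"chr{draw(st.integers(min_value=1, max_value=3))}",
                draw(st.sampled_from("+-")),
                start,
                start + length,
            )
        )
    return GeneTable(genes)


@given(table=random_tables())
@settings(max_examples=150, deadline=None)
def test_find_cisnats_equals_brute_force(table):
    assert find_cisnats(table).as_set() == oracle_find(table)


@given(table=random_tables())
@settings(max_examples=100, deadline=None)
def test_pair_duality(table):
    """Every directed pair has exactly one reversed dual: EB<->FO,
    HH and TT with themselves."""
    pairs = find_cisnats(table).as_set()
    for p in pairs:
        assert CisNatPair(p.antisense_id, p.target_id, p.type.dual) in pairs
    assert dedup_unordered(pairs) == {
        frozenset((p.target_id, p.antisense_id)) for p in pairs
    }
    # dual collapse at most halves; exactly halves when no identical spans
    assert 2 * len(dedup_unordered(pairs)) <= len(
        {(p.target_id, p.antisense_id) for p in pairs}
    ) * 2


@given(table=random_tables())
@settings(max_examples=100, deadline=None)
def test_mirror_reflection_swaps_hh_and_tt(table):
    """Reflecting all coordinates (keeping strand labels) turns
    divergent geometry into convergent and vice versa, and fixes
    containment."""
    C = 2_000
    reflected = GeneTable(
        [
            GeneRecord(g.gene_id, g.chrom, g.strand, C - g.end, C - g.start)
            for g in table
        ]
    )
    swap = {EB: EB, FO: FO, HH: TT, TT: HH}
    expected = {
        CisNatPair(p.target_id, p.antisense_id, swap[p.type])
        for p in find_cisnats(table)
    }
    assert find_cisnats(reflected).as_set() == expected


def test_dedup_halves_dual_representations():
    pairs = PairSet(
        [
            CisNatPair("A", "B", EB),
            CisNatPair("B", "A", FO),
            CisNatPair("C", "D", HH),
            CisNatPair("D", "C", HH),
        ]
    )
    assert dedup_unordered(pairs) == {frozenset("AB"), frozenset("CD")}
    assert dedup_unordered(PairSet([])) == set()


class TestSummarizeTypes:
    def test_containment_fixture_counts(self, containment_table):
        summary = summarize_types(find_cisnats(containment_table), containment_table)
        assert summary["EB"] == {"gene_count": 1, "percentage": 50.0}
        assert summary["FO"] == {"gene_count": 1, "percentage": 50.0}
        assert summary["HH"]["gene_count"] == 0
        assert summary["any"] == {"gene_count": 2, "percentage": 100.0}

    def test_empty_pairs_all_zero(self):
        table = GeneTable([gene(f"g{i}", "+", 10 * i + 1, 10 * i + 6) for i in range(10)])
        summary = summarize_types(PairSet([]), table)
        for label, vals in summary.items():
            assert vals == {"gene_count": 0, "percentage": 0.0}

    def test_gene_with_two_partner_types_counted_in_each(self):
        # mid "+" has an embedded partner and a tail-to-tail partner
        table = GeneTable(
            [
                gene("mid", "+", 100, 300),
                gene("emb", "-", 150, 250),
                gene("conv", "-", 280, 400),
            ]
        )
        summary = summarize_types(find_cisnats(table), table)
        assert summary["EB"]["gene_count"] == 1  # mid as target
        assert summary["TT"]["gene_count"] == 2  # mid and conv both targets
        assert summary["FO"]["gene_count"] == 1  # emb as target
        assert summary["any"]["gene_count"] == 3

    @given(table=random_tables())
    @settings(max_examples=60, deadline=None)
    def test_summary_bounds(self, table):
        summary = summarize_types(find_cisnats(table), table)
        per_type = [summary[t.value]["gene_count"] for t in OverlapType]
        assert 0 <= summary["any"]["percentage"] <= 100
        if per_type:
            assert max(per_type) <= summary["any"]["gene_count"] <= sum(per_type)
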