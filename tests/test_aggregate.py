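"""Borda scoring, tie policy and consensus ordering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirank.aggregate import (
    BordaRecord,
    aggregate_scope,
    borda_score,
    consensus,
    tie_scores,
    top_k,
)
from mirank.ingest import RankEntry, StudyRanking
from mirank.nomenclature import CanonicalMiRNA


def mk(name):
    return CanonicalMiRNA(f"miR-{name}", "5p")


def ballot(study, product, names, start=1, top_n=10):
    entries = [RankEntry(start + i, mk(n)) for i, n in enumerate(names)]
    return StudyRanking(study, product, entries, top_n=top_n)


@pytest.mark.parametrize(
    "position, top_n, expected",
    [(1, 10, 10.0), (10, 10, 1.0), (11, 10, 0.0), (5, 10, 6.0), (1, 3, 3.0), (25, 10, 0.0)],
)
def test_borda_score(position, top_n, expected):
    assert borda_score(position, top_n) == expected


def test_borda_score_rejects_bad_inputs():
    with pytest.raises(ValueError):
        borda_score(0, 10)
    with pytest.raises(ValueError):
        borda_score(1, 0)


@pytest.mark.parametrize(
    "span, top_n, expected",
    [([10, 11], 10, 0.5), ([1, 2], 10, 9.5), ([5], 10, 6.0), ([9, 10, 11], 10, 1.0)],
)
def test_tie_scores_mean_of_span(span, top_n, expected):
    assert tie_scores(span, top_n) == pytest.approx(expected)


def test_tie_scores_rejects_non_contiguous_span():
    with pytest.raises(ValueError):
        tie_scores([3, 5], 10)


def test_single_study_scores_descend():
    names = list("ABCDEFGHIJ")
    records = aggregate_scope([ballot("s1", "p", names)], {"p"})
    by_name = {r.mirna: r for r in records}
    for i, n in enumerate(names):
        assert by_name[mk(n)].total_score == 10 - i


def test_two_identical_studies_double_scores():
    names = list("ABCDEFGHIJ")
    one = aggregate_scope([ballot("s1", "p", names)], {"p"})
    two = aggregate_scope([ballot("s1", "p", names), ballot("s2", "p", names)], {"p"})
    assert {r.mirna: r.total_score for r in two} == {
        r.mirna: 2 * r.total_score for r in one
    }


def test_summation_recurrence_best_position():
    b1 = ballot("s1", "p", ["X"] + list("BCDEFGHIJ"))  # X at 1 -> 10
    b2 = ballot("s2", "p", list("BCD") + ["X"] + list("EFGHIJ"))  # X at 4 -> 7
    records = {r.mirna: r for r in aggregate_scope([b1, b2], {"p"})}
    x = records[mk("X")]
    assert (x.total_score, x.recurrence, x.best_position) == (17.0, 2, 1)


def test_group_scope_pools_products():
    b1 = ballot("s1", "p1", ["X"] + list("BCDEFGHIJ"))
    b2 = ballot("s2", "p2", ["X"] + list("KLMNOPQRS"))
    records = {r.mirna: r for r in aggregate_scope([b1, b2], {"p1", "p2"})}
    assert records[mk("X")].total_score == 20.0
    # out-of-scope products are ignored
    only_p1 = {r.mirna: r for r in aggregate_scope([b1, b2], {"p1"})}
    assert only_p1[mk("X")].total_score == 10.0


def test_empty_scope_fatal():
    with pytest.raises(ValueError):
        aggregate_scope([], set())


def test_boundary_tie_scores_half_each():
    entries = [RankEntry(i + 1, mk(n)) for i, n in enumerate("ABCDEFGHI")]
    entries += [RankEntry(10, mk("X"), "t"), RankEntry(10, mk("Y"), "t")]
    ranking = StudyRanking("s1", "p", entries, top_n=10)
    records = {r.mirna: r.total_score for r in aggregate_scope([ranking], {"p"})}
    assert records[mk("X")] == pytest.approx(0.5)
    assert records[mk("Y")] == pytest.approx(0.5)
    # ballot mass is conserved: 54 from ranks 1..9 plus 2 x 0.5
    assert sum(records.values()) == pytest.approx(55.0)


@settings(derandomize=True, max_examples=50)
@given(st.integers(1, 12), st.randoms(use_true_random=False))
def test_borda_mass_conservation(top_n, rnd):
    """A full ballot always contributes top_n(top_n+1)/2 points."""
    names = [f"N{i}" for i in range(top_n)]
    rnd.shuffle(names)
    records = aggregate_scope([ballot("s", "p", names, top_n=top_n)], {"p"})
    assert sum(r.total_score for r in records) == pytest.approx(top_n * (top_n + 1) / 2)


def test_aggregation_order_invariance():
    ballots = [
        ballot("s1", "p", list("ABCDEFGHIJ")),
        ballot("s2", "p", list("BADCFEHGJI")),
        ballot("s3", "p", list("JIHGFEDCBA")),
    ]
    base = aggregate_scope(ballots, {"p"})
    for perm in ([2, 0, 1], [1, 2, 0]):
        assert aggregate_scope([ballots[i] for i in perm], {"p"}) == base


def test_adding_top_vote_never_demotes():
    ballots = [ballot("s1", "p", list("ABCDEFGHIJ"))]
    before = {r.mirna: r.total_score for r in aggregate_scope(ballots, {"p"})}
    more = ballots + [ballot("s2", "p", ["E"] + list("ABCDFGHIJ"))]
    after = {r.mirna: r.total_score for r in aggregate_scope(more, {"p"})}
    assert after[mk("E")] >= before[mk("E")]
    rank_before = [r.mirna for r in consensus(aggregate_scope(ballots, {"p"})).records]
    rank_after = [r.mirna for r in consensus(aggregate_scope(more, {"p"})).records]
    assert rank_after.index(mk("E")) <= rank_before.index(mk("E"))


def test_equal_weights_equivalence():
    ballots = [ballot("s1", "p", list("ABCDEFGHIJ")), ballot("s2", "p", list("CABDEFGHIJ"))]
    unit = consensus(aggregate_scope(ballots, {"p"}))
    scaled = consensus(
        aggregate_scope(ballots, {"p"}, weights={"s1": 3.0, "s2": 3.0})
    )
    assert [r.mirna for r in unit.records] == [r.mirna for r in scaled.records]


def test_consensus_tie_break_chain_and_trace():
    a = BordaRecord(mk("A"), 12.0, 2, 3)
    b = BordaRecord(mk("B"), 12.0, 1, 1)
    c = BordaRecord(mk("C"), 15.0, 1, 2)
    d = BordaRecord(mk("D"), 12.0, 2, 3)  # ties A on all keys but name
    cons = consensus([b, d, a, c])
    assert [r.mirna for r in cons.records] == [mk("C"), mk("A"), mk("D"), mk("B")]
    assert cons.tie_break_trace == ["score", "name", "recurrence"]


def test_top_k_slice_and_boundary_tie():
    records = [BordaRecord(mk(chr(65 + i)), 50.0 - i, 3, 1) for i in range(12)]
    cons = consensus(records)
    assert len(top_k(cons, 10).names) == 10
    assert top_k(cons, 100).names == [r.mirna for r in cons.records]
    with pytest.raises(ValueError):
        top_k(cons, 0)
    # records 3 and 4 identical on every key except name -> both reported
    tied = [
        BordaRecord(mk("A"), 9.0, 2, 1),
        BordaRecord(mk("B"), 8.0, 2, 1),
        BordaRecord(mk("C"), 7.0, 2, 2),
        BordaRecord(mk("D"), 7.0, 2, 2),
    ]
    sel = top_k(consensus(tied), 3)
    assert sel.boundary_tie and [m.display for m in sel.names] == [
        "miR-A-5p", "miR-B-5p", "miR-C-5p", "miR-D-5p",
    ]
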