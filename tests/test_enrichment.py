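"""Target coverage, hypergeometric ORA and BH adjustment."""

import itertools

import pytest

from mirank.enrichment import (
    TargetMap,
    bh_adjust,
    common_targets,
    coverage_counts,
    hypergeom_p,
    read_gmt,
    read_target_map,
    run_ora,
    select_top_targeted,
)
from mirank.nomenclature import canonicalize


def mk(name):
    return canonicalize(name)


def tmap(**kw):
    return TargetMap(targets={mk(k): set(v) for k, v in kw.items()})


def enumeration_tail(x, K, n, M):
    """P(X >= x) by exhaustively enumerating all C(M, n) draws."""
    hits = total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(M), n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return hits / total


class TestCommonTargets:
    def test_modes(self):
        m = tmap(**{"miR-1-3p": {"g1", "g2"}, "miR-206": {"g2", "g3"}, "miR-122-5p": {"g4"}})
        query = {mk("miR-1-3p"), mk("miR-206")}
        assert common_targets(query, m, "all") == {"g2"}
        assert common_targets(query, m, "any") == {"g1", "g2", "g3"}
        # the third miRNA's {g4} removes nothing from the union
        assert common_targets(query, m, "exclusive") == {"g1", "g2", "g3"}

    def test_identical_and_disjoint_sets(self):
        m = tmap(**{"miR-1-3p": {"a", "b"}, "miR-206": {"a", "b"}, "miR-122-5p": {"c"}})
        assert common_targets({mk("miR-1-3p"), mk("miR-206")}, m, "all") == {"a", "b"}
        assert common_targets({mk("miR-1-3p"), mk("miR-122-5p")}, m, "all") == set()

    def test_subset_relations(self):
        m = tmap(**{"miR-1-3p": {"a", "b"}, "miR-206": {"b", "c"}, "miR-122-5p": {"a", "d"}})
        q = {mk("miR-1-3p"), mk("miR-206")}
        assert common_targets(q, m, "all") <= common_targets(q, m, "any")
        assert common_targets(q, m, "exclusive") <= common_targets(q, m, "any")

    def test_errors(self):
        m = tmap(**{"miR-1-3p": {"a"}})
        with pytest.raises(ValueError):
            common_targets(set(), m)
        with pytest.raises(KeyError, match="miR-206"):
            common_targets({mk("miR-206")}, m)


def test_coverage_counts_and_selection():
    m = tmap(**{"miR-1-3p": {"g", "h"}, "miR-206": {"g"}, "miR-122-5p": {"h", "k"}})
    counts = coverage_counts(m)
    assert counts == {"g": 2, "h": 2, "k": 1}
    assert select_top_targeted(counts, min_mirnas=2) == ["g", "h"]
    assert select_top_targeted(counts, min_mirnas=3) == []
    assert select_top_targeted({}, min_mirnas=1) == []
    # cap truncates after count-desc, name-asc ordering
    big = {f"g{i:03d}": 5 for i in range(150)}
    assert len(select_top_targeted(big, min_mirnas=1, cap=100)) == 100
    # fractional selector: top 20% of the gene space
    assert select_top_targeted(counts, min_mirnas=1, fraction=0.34) == ["g"]


def test_read_target_map_dedup(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("mirna\tgene\nmiR-1-3p\tg1\nbta-miR-1-3p\tg1\nmiR-1-3p\tg2\n")
    m = read_target_map(p)
    assert m.targets == {mk("miR-1-3p"): {"g1", "g2"}}


class TestHypergeom:
    def test_worked_case(self):
        assert hypergeom_p(4, 4, 5, 10) == pytest.approx(6 / 252, abs=1e-12)
        assert hypergeom_p(4, 4, 5, 10) == pytest.approx(
            enumeration_tail(4, 4, 5, 10), abs=1e-12
        )

    def test_boundaries(self):
        assert hypergeom_p(0, 3, 4, 10) == 1.0
        assert hypergeom_p(5, 10, 5, 10) == pytest.approx(1.0)  # K = M

    def test_matches_enumeration_small_universe(self):
        for M in (5, 8):
            for K in range(M + 1):
                for n in range(M + 1):
                    for x in range(min(K, n) + 1):
                        assert hypergeom_p(x, K, n, M) == pytest.approx(
                            enumeration_tail(x, K, n, M), abs=1e-12
                        )

    def test_monotone_in_overlap(self):
        ps = [hypergeom_p(x, 6, 5, 20) for x in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_fatal(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 11, 5, 10)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.037]) == [pytest.approx(0.037)]

    def test_worked_triple(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_monotone_capped_and_order_preserving(self):
        ps = [0.5, 0.001, 0.04, 0.9, 0.02]
        qs = bh_adjust(ps)
        assert all(q <= 1 for q in qs)
        assert all(q >= p for p, q in zip(ps, qs))
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        assert all(
            qs[a] <= qs[b] for a, b in zip(order, order[1:])
        )  # monotone after cumulative-min

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestORA:
    def test_exact_set_attains_minimal_p(self):
        universe = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(5)}
        sets = {
            "exact": set(query),
            "off_by_one": {f"g{i}" for i in range(1, 6)},
            "disjoint_same_size": {f"g{i}" for i in range(10, 15)},
        }
        results = run_ora(query, sets, universe)
        assert results[0].set_name == "exact"
        by_name = {r.set_name: r for r in results}
        assert by_name["exact"].p <= by_name["off_by_one"].p

    def test_universe_set_p_one(self):
        universe = {f"g{i}" for i in range(12)}
        results = run_ora({"g0", "g1"}, {"all": set(universe)}, universe)
        assert results[0].p == pytest.approx(1.0)

    def test_empty_query_fatal(self):
        with pytest.raises(ValueError):
            run_ora(set(), {"s": {"a"}}, {"a"})

    def test_out_of_universe_query_dropped_with_warning(self, caplog):
        import logging

        universe = {"a", "b", "c", "d"}
        with caplog.at_level(logging.WARNING, logger="mirank.enrichment"):
            results = run_ora({"a", "zzz"}, {"s": {"a", "b"}}, universe)
        assert results[0].n == 1
        assert any("outside the universe" in r.message for r in caplog.records)

    def test_q_from_bh_across_all_sets(self):
        universe = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(6)}
        sets = {f"s{j}": {f"g{i}" for i in range(j, j + 6)} for j in range(0, 24, 3)}
        results = run_ora(query, sets, universe, min_overlap=0)
        assert len(results) == len(sets)
        ps = [r.p for r in results]
        qs = [r.q for r in results]
        assert qs == pytest.approx(bh_adjust(ps))
        # the reported subset keeps the q computed across ALL tested sets
        kept = run_ora(query, sets, universe, min_overlap=1)
        full_q = {r.set_name: r.q for r in results}
        assert all(r.q == pytest.approx(full_q[r.set_name]) for r in kept)


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("alpha\tdesc\tg1\tg2\tg3\nbeta\tdesc\tg2\n")
    sets = read_gmt(p)
    assert sets == {"alpha": {"g1", "g2", "g3"}, "beta": {"g2"}}
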