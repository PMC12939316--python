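"""Borda-type cross-study rank aggregation ("frequency-weighted ordinal recurrence").

Expression values from heterogeneous small-RNA platforms are not directly
comparable, but ordinal top-N positions are.  Each study's top-N list is
therefore treated as a ballot: position ``p`` earns ``top_n - p + 1`` points
(10 down to 1 for a top-10 list), points are summed per miRNA over all studies
of a scope (one product, or all products of a food group) with equal study
weights by default, and the summed score — together with how many studies
listed the miRNA at all (its recurrence) — orders the consensus.

Tied entries ("ranked similarly") each receive the arithmetic mean of the
scores of the positions their tie block spans; positions beyond the top-N
window contribute 0 to that mean, so total Borda mass per ballot is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .ingest import StudyRanking
from .nomenclature import CanonicalMiRNA

#: Score comparisons tolerate tie-produced halves but not float drift.
SCORE_TOL = 1e-9


def borda_score(position: int, top_n: int = 10) -> float:
    """Score of a single rank position: ``top_n - position + 1``, floored at 0."""
    if position < 1:
        raise ValueError(f"position must be >= 1: {position}")
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1: {top_n}")
    return float(max(top_n - position + 1, 0))


def tie_scores(positions_spanned: Sequence[int], top_n: int = 10) -> float:
    """Per-member score of a tie block spanning contiguous positions.

    Each tied member receives the mean of the plain scores over the spanned
    positions, so a two-way tie across the top-N boundary (positions 10 and
    11 of a top-10 list) yields 0.5 each and ballot mass is conserved.
    """
    positions = sorted(positions_spanned)
    if not positions:
        raise ValueError("empty tie span")
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ValueError(f"tie span not contiguous: {positions}")
    return sum(borda_score(p, top_n) for p in positions) / len(positions)


@dataclass
class BordaRecord:
    """Aggregated evidence for one miRNA within a scope."""

    mirna: CanonicalMiRNA
    total_score: float
    recurrence: int
    best_position: int

    def sort_key(self):
        return (-self.total_score, -self.recurrence, self.best_position, self.mirna.display)


@dataclass
class ConsensusRanking:
    """Orderered consensus for one scope with a per-pair tie-break trace."""

    scope: str
    records: list[BordaRecord]
    tie_break_trace: list[str] = field(default_factory=list)


def _entry_scores(ranking: StudyRanking) -> dict[CanonicalMiRNA, float]:
    """Per-miRNA score of one ballot, applying the tie policy.

    A tie block is a maximal run of entries sharing a non-null tie group; its
    spanned positions are the block's distinct listed positions extended to the
    block size (covering the convention of repeating one position for ties).
    """
    scores: dict[CanonicalMiRNA, float] = {}
    entries = ranking.entries
    i = 0
    while i < len(entries):
        e = entries[i]
        j = i + 1
        if e.tie_group is not None:
            while j < len(entries) and entries[j].tie_group == e.tie_group:
                j += 1
        block = entries[i:j]
        if len(block) == 1:
            scores[e.name] = borda_score(e.position, ranking.top_n)
        else:
            start = block[0].position
            span = range(start, start + len(block))
            s = tie_scores(list(span), ranking.top_n)
            for b in block:
                scores[b.name] = s
        i = j
    return scores


def aggregate_scope(
    rankings: Iterable[StudyRanking],
    scope_members: set[str],
    weights: Optional[Mapping[str, float]] = None,
) -> list[BordaRecord]:
    """Sum weighted ballot scores over all rankings whose product is in scope.

    ``recurrence`` counts contributing ballots listing the miRNA (at any
    position); ``best_position`` is the minimum listed position.  Group scope
    is the same computation with the group's products as members.
    """
    in_scope = [r for r in rankings if r.product_id in scope_members]
    if not scope_members:
        raise ValueError("empty scope")
    totals: dict[CanonicalMiRNA, BordaRecord] = {}
    for ranking in in_scope:
        w = 1.0 if weights is None else float(weights.get(ranking.study_id, 1.0))
        scores = _entry_scores(ranking)
        for entry in ranking.entries:
            s = scores[entry.name] * w
            rec = totals.get(entry.name)
            if rec is None:
                totals[entry.name] = BordaRecord(entry.name, s, 1, entry.position)
            else:
                rec.total_score += s
                rec.recurrence += 1
                rec.best_position = min(rec.best_position, entry.position)
    return sorted(totals.values(), key=lambda r: r.mirna.display)


_KEY_NAMES = ("score", "recurrence", "best_position", "name")


def consensus(records: Sequence[BordaRecord], scope: str = "") -> ConsensusRanking:
    """Order records by score desc, recurrence desc, best position asc, name asc.

    The trace records, for each adjacent pair, which key decided the order
    (``score``/``recurrence``/``best_position``/``name``).
    """
    ordered = sorted(records, key=BordaRecord.sort_key)
    trace: list[str] = []
    for a, b in zip(ordered, ordered[1:]):
        if abs(a.total_score - b.total_score) > SCORE_TOL:
            trace.append("score")
        elif a.recurrence != b.recurrence:
            trace.append("recurrence")
        elif a.best_position != b.best_position:
            trace.append("best_position")
        else:
            trace.append("name")
    return ConsensusRanking(scope=scope, records=list(ordered), tie_break_trace=trace)


@dataclass
class TopSelection:
    """Top-k slice of a consensus; flags a tie straddling the k boundary."""

    names: list[CanonicalMiRNA]
    boundary_tie: bool = False


def top_k(ranking: ConsensusRanking, k: int) -> TopSelection:
    """First ``k`` consensus miRNAs; a boundary tie (records k and k+1 equal on
    every key but name) includes the tied extras and sets the flag."""
    if k < 1:
        raise ValueError(f"k must be >= 1: {k}")
    records = ranking.records
    if k >= len(records):
        return TopSelection([r.mirna for r in records])
    cut = records[k - 1]
    end = k
    while end < len(records) and _same_keys(records[end], cut):
        end += 1
    return TopSelection([r.mirna for r in records[:end]], boundary_tie=end > k)


def _same_keys(a: BordaRecord, b: BordaRecord) -> bool:
    return (
        abs(a.total_score - b.total_score) <= SCORE_TOL
        and a.recurrence == b.recurrence
        and a.best_position == b.best_position
    )


def consensus_frame(ranking: ConsensusRanking):
    """Consensus as a DataFrame in the output TSV layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mirna": [r.mirna.display for r in ranking.records],
            "total_score": [r.total_score for r in ranking.records],
            "recurrence": [r.recurrence for r in ranking.records],
            "best_position": [r.best_position for r in ranking.records],
            "consensus_rank": list(range(1, len(ranking.records) + 1)),
        }
    )
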