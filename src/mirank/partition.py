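"""Set-partition analytics: shared vs selective miRNAs, group exclusivity,
and persistence of group-exclusive miRNAs into processed products.

A miRNA is *exclusive* to a food group when every documented occurrence
(raw or processed state pooled) falls in that group; otherwise it is shared
across groups.  Exclusives that retain at least one processed-state
occurrence are said to *persist* after processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Set

from .ingest import PresenceMatrix
from .nomenclature import CanonicalMiRNA


@dataclass
class ExclusivityPartition:
    """Partition of the miRNA universe into per-group exclusives and the rest."""

    exclusive: dict[str, set[CanonicalMiRNA]]
    shared_multi_group: set[CanonicalMiRNA]
    persisted_after_processing: set[CanonicalMiRNA] = field(default_factory=set)

    @property
    def all_exclusives(self) -> set[CanonicalMiRNA]:
        out: set[CanonicalMiRNA] = set()
        for s in self.exclusive.values():
            out |= s
        return out


@dataclass
class SharedSelective:
    """Within one food type: miRNAs in >= 2 products vs exactly one."""

    shared: set[CanonicalMiRNA]
    selective: dict[str, set[CanonicalMiRNA]]


def shared_selective(
    product_sets: Mapping[str, Set[CanonicalMiRNA]]
) -> SharedSelective:
    """Split the miRNAs of one food type's per-product top-k sets.

    ``shared`` = present in at least two products' sets; ``selective`` maps
    each product to the miRNAs appearing in that product only.
    """
    if not product_sets:
        raise ValueError("no products in food type")
    counts: dict[CanonicalMiRNA, int] = {}
    for names in product_sets.values():
        for n in names:
            counts[n] = counts.get(n, 0) + 1
    shared = {n for n, c in counts.items() if c >= 2}
    selective = {
        pid: {n for n in names if counts[n] == 1}
        for pid, names in product_sets.items()
    }
    return SharedSelective(shared=shared, selective=selective)


def group_exclusive(matrix: PresenceMatrix) -> ExclusivityPartition:
    """Partition matrix rows into per-group exclusives and multi-group shared.

    Exclusivity pools raw and processed states: a miRNA seen only in raw milk
    and skimmed milk powder is still dairy-exclusive.
    """
    exclusive: dict[str, set[CanonicalMiRNA]] = {g: set() for g in matrix.groups()}
    shared: set[CanonicalMiRNA] = set()
    for mirna in matrix.rows:
        groups = {g for (g, _) in matrix.cells_of(mirna)}
        if len(groups) == 1:
            exclusive[next(iter(groups))].add(mirna)
        else:
            shared.add(mirna)
    return ExclusivityPartition(exclusive=exclusive, shared_multi_group=shared)


def processing_persistence(
    partition: ExclusivityPartition, matrix: PresenceMatrix
) -> set[CanonicalMiRNA]:
    """Group-exclusive miRNAs with at least one processed-state occurrence."""
    persisted = {
        m
        for m in partition.all_exclusives
        if any(state == "processed" for (_, state) in matrix.cells_of(m))
    }
    partition.persisted_after_processing = persisted
    return persisted


def universe_counts(matrix: PresenceMatrix) -> tuple[int, int, int]:
    """(n with a raw cell, n with a processed cell, n distinct rows)."""
    n_raw = sum(
        1
        for m in matrix.rows
        if any(state == "raw" for (_, state) in matrix.cells_of(m))
    )
    n_processed = sum(
        1
        for m in matrix.rows
        if any(state == "processed" for (_, state) in matrix.cells_of(m))
    )
    return n_raw, n_processed, len(matrix)


def partition_json(partition: ExclusivityPartition) -> dict:
    """JSON-serializable view: {group: [names...], shared: [...], persisted: [...]}."""
    out = {
        group: sorted(m.display for m in members)
        for group, members in sorted(partition.exclusive.items())
    }
    out["shared"] = sorted(m.display for m in partition.shared_multi_group)
    out["persisted"] = sorted(m.display for m in partition.persisted_after_processing)
    return out
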