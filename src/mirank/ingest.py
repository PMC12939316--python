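"""Input readers: study ranking tables, product metadata, packaged presence fixtures.

The packaged fixtures transcribe the curated cross-study summary tables of
highly conserved predominant miRNAs in raw and processed animal-source foods;
each row is one canonical miRNA with its semicolon-separated source labels,
and a packaged label map assigns every label to one of the five food groups
(lean_meat, meat_fat, meat_offal, dairy, seafood) and a raw/processed state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .nomenclature import CanonicalMiRNA, canonicalize

logger = logging.getLogger(__name__)

FOOD_GROUPS = ("lean_meat", "meat_fat", "meat_offal", "dairy", "seafood")
STATES = ("raw", "processed")

RANKING_COLUMNS = ("study", "product", "rank", "mirna", "tie")


class IngestError(ValueError):
    """Fatal validation failure while reading an input table."""


@dataclass(frozen=True)
class RankEntry:
    position: int
    name: CanonicalMiRNA
    tie_group: Optional[str] = None


@dataclass
class StudyRanking:
    """One study's ordered top-N miRNA list for one food product."""

    study_id: str
    product_id: str
    entries: list[RankEntry]
    top_n: int = 10

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        if positions != sorted(positions):
            raise IngestError(
                f"{self.study_id}/{self.product_id}: positions not non-decreasing"
            )
        seen: dict[CanonicalMiRNA, int] = {}
        for e in self.entries:
            if e.name in seen:
                raise IngestError(
                    f"{self.study_id}/{self.product_id}: duplicate miRNA {e.name.display}"
                )
            seen[e.name] = e.position
        for a, b in zip(self.entries, self.entries[1:]):
            if a.position == b.position and (
                a.tie_group is None or a.tie_group != b.tie_group
            ):
                raise IngestError(
                    f"{self.study_id}/{self.product_id}: equal positions without a "
                    f"shared tie group at position {a.position}"
                )

    @property
    def names(self) -> set[CanonicalMiRNA]:
        return {e.name for e in self.entries}


@dataclass(frozen=True)
class FoodProduct:
    """Product metadata; group vocabulary is open here (synthetic runs may use
    their own groups) and closed-vocabulary checked by :func:`read_products`."""

    product_id: str
    group: str
    state: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise IngestError(
                f"unknown state {self.state!r} for {self.product_id!r}; "
                f"allowed: {', '.join(STATES)}"
            )


class PresenceMatrix:
    """Boolean membership of canonical miRNAs in (food group, state) cells.

    Rows are keyed by arm-exact canonical identity; every cell carries the
    source labels that put it there (provenance).
    """

    def __init__(self) -> None:
        # row -> (group, state) -> set of source labels
        self._cells: dict[CanonicalMiRNA, dict[tuple[str, str], set[str]]] = {}

    def add(
        self, mirna: CanonicalMiRNA, group: str, state: str, source: str = ""
    ) -> None:
        # group vocabulary is open: synthetic runs may define their own groups
        cell = self._cells.setdefault(mirna, {}).setdefault((group, state), set())
        if source:
            cell.add(source)
        else:
            cell.add("(unspecified)")

    @property
    def rows(self) -> list[CanonicalMiRNA]:
        return sorted(self._cells)

    def groups(self) -> list[str]:
        return sorted({g for cells in self._cells.values() for (g, _) in cells})

    def cells_of(self, mirna: CanonicalMiRNA) -> set[tuple[str, str]]:
        return set(self._cells.get(mirna, {}))

    def provenance(self, mirna: CanonicalMiRNA, group: str, state: str) -> set[str]:
        return set(self._cells.get(mirna, {}).get((group, state), set()))

    def has(self, mirna: CanonicalMiRNA, group: str, state: str) -> bool:
        return (group, state) in self._cells.get(mirna, {})

    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, mirna: CanonicalMiRNA) -> bool:
        return mirna in self._cells

    def to_frame(self) -> pd.DataFrame:
        """Boolean DataFrame, rows = display names, columns = 'group/state'."""
        cols = sorted({c for cells in self._cells.values() for c in cells})
        data = {
            f"{g}/{s}": [self.has(m, g, s) for m in self.rows] for (g, s) in cols
        }
        return pd.DataFrame(data, index=[m.display for m in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="mirna")


def read_rankings(path, dialect: str = "tsv", top_n: int = 10) -> list[StudyRanking]:
    """Read a study-rankings table into validated :class:`StudyRanking` objects.

    Expected header: ``study, product, rank, mirna, tie`` (tie may be empty).
    Validation failures are aggregated and raised together with line numbers.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise IngestError(f"dialect must be 'csv' or 'tsv': {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s): {', '.join(missing)}")

    errors: list[str] = []
    rows = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            rank = int(row["rank"])
            if rank < 1:
                raise ValueError("rank must be >= 1")
            name = canonicalize(row["mirna"])
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        tie = row["tie"].strip() or None
        rows.append((row["study"], row["product"], rank, name, tie, line))

    rankings: list[StudyRanking] = []
    groups: dict[tuple[str, str], list] = {}
    for r in rows:
        groups.setdefault((r[0], r[1]), []).append(r)
    for (study, product), grp in groups.items():
        seen: dict[CanonicalMiRNA, int] = {}
        for _, _, _, name, _, line in grp:
            if name in seen:
                errors.append(
                    f"lines {seen[name]} and {line}: duplicate miRNA "
                    f"{name.display} in {study}/{product}"
                )
            else:
                seen[name] = line
        grp.sort(key=lambda r: r[2])
        positions = sorted({r[2] for r in grp})
        gaps = [b for a, b in zip(positions, positions[1:]) if b > a + 1]
        if gaps:
            logger.warning(
                "%s/%s: rank gap before position(s) %s; positions kept as given",
                study, product, ", ".join(map(str, gaps)),
            )
        entries = [RankEntry(rank, name, tie) for _, _, rank, name, tie, _ in grp]
        if not errors:
            rankings.append(StudyRanking(study, product, entries, top_n=top_n))
    if errors:
        raise IngestError(f"{path}: " + "; ".join(errors))
    return rankings


def write_rankings(rankings: Sequence[StudyRanking], path, dialect: str = "tsv") -> None:
    """Serialize rankings back to the input dialect (round-trips with read_rankings)."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    records = [
        {
            "study": r.study_id,
            "product": r.product_id,
            "rank": e.position,
            "mirna": e.name.display,
            "tie": e.tie_group or "",
        }
        for r in rankings
        for e in r.entries
    ]
    pd.DataFrame(records, columns=list(RANKING_COLUMNS)).to_csv(path, sep=sep, index=False)


def read_products(path) -> dict[str, FoodProduct]:
    """Read the product metadata config (YAML or JSON).

    Layout: ``products: {id: {group: ..., state: ..., label: ...}}``.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or "products" not in data:
        raise IngestError(f"{path}: expected a top-level 'products' mapping")
    out: dict[str, FoodProduct] = {}
    for pid, entry in data["products"].items():
        group = entry.get("group", "")
        if group not in FOOD_GROUPS:
            raise IngestError(
                f"unknown group {group!r} for {pid!r}; "
                f"allowed: {', '.join(FOOD_GROUPS)}"
            )
        out[pid] = FoodProduct(
            product_id=pid,
            group=group,
            state=entry.get("state", ""),
            label=entry.get("label", ""),
        )
    return out


def check_product_coverage(
    rankings: Iterable[StudyRanking], products: Mapping[str, FoodProduct]
) -> None:
    """Every ranked product must have metadata (referential integrity)."""
    missing = sorted({r.product_id for r in rankings} - set(products))
    if missing:
        raise IngestError(f"products missing from config: {', '.join(missing)}")


def _read_source_map() -> dict[str, tuple[str, str]]:
    with resources.files("mirank.data").joinpath("source_groups.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {r.source: (r.group, r.state) for r in df.itertuples()}


def _load_fixture_table(
    name: str, matrix: PresenceMatrix, source_map: Mapping[str, tuple[str, str]]
) -> int:
    with resources.files("mirank.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for r in df.itertuples():
        mirna = canonicalize(r.mirna)
        for label in (s.strip() for s in r.sources.split(";")):
            if label not in source_map:
                raise IngestError(
                    f"{name}: source label {label!r} absent from source-group map"
                )
            group, state = source_map[label]
            matrix.add(mirna, group, state, source=label)
    return len(df)


def load_table_fixtures() -> PresenceMatrix:
    """Load the packaged raw/processed presence fixtures into one matrix.

    Row counts are checked on load: 46 distinct raw-state miRNAs, 26
    processed-state, 48 in the union.
    """
    source_map = _read_source_map()
    matrix = PresenceMatrix()
    n_raw = _load_fixture_table("table2_raw.tsv", matrix, source_map)
    n_proc = _load_fixture_table("table3_processed.tsv", matrix, source_map)
    if (n_raw, n_proc, len(matrix)) != (46, 26, 48):
        raise IngestError(
            f"fixture checksum mismatch: expected 46/26/48 rows, "
            f"got {n_raw}/{n_proc}/{len(matrix)}"
        )
    return matrix
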