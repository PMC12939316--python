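"""Mature-miRNA name canonicalization.

Published top-abundance tables mix species dialects freely: ``bta-miR-320a``,
``Oni-miR-1``, ``spu-miR-92b-3p_2``, ``miR-100-x``.  Cross-study set algebra is
only meaningful on a species-independent identity, so every raw name is reduced
to a :class:`CanonicalMiRNA` — a ``miR-``/``let-`` base plus an optional mature
arm (``5p``/``3p``).

Armless names are left armless: guessing a dominant arm would silently change
downstream set counts.  Lettered paralogs (miR-92a vs miR-92b) stay distinct;
an optional :func:`family_key` collapses them for callers who ask.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: Species prefixes seen in the source tables (bovine, porcine, ovine, caprine,
#: tilapia, sea urchin/cucumber dialects, bat, pearl oyster, human ...).
KNOWN_PREFIXES = frozenset(
    {"bta", "ssc", "oar", "chi", "ocu", "cap", "oni", "spu", "efu", "pmi", "hsa"}
)

#: Placeholder arm letters used by some invertebrate annotations (miR-100-x).
_PLACEHOLDERS = frozenset({"x", "y", "z"})

_ARMS = frozenset({"5p", "3p"})

_PREFIX_RE = re.compile(r"^([A-Za-z]{3,4})-(?=(?:mir|let)\b)", re.IGNORECASE)


class NomenclatureError(ValueError):
    """Raised for names that cannot be interpreted as a mature miRNA."""


@dataclass(frozen=True)
class CanonicalMiRNA:
    """Species-independent mature miRNA identity.

    Parameters
    ----------
    base:
        Name stem beginning with ``miR-`` or ``let-`` (e.g. ``miR-148a``).
    arm:
        Mature arm, ``"5p"`` or ``"3p"``, or ``None`` when unannotated.
    """

    base: str
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.base.startswith("miR-") or self.base.startswith("let-")):
            raise NomenclatureError(f"base must start with 'miR-' or 'let-': {self.base!r}")
        if self.arm is not None and self.arm not in _ARMS:
            raise NomenclatureError(f"arm must be '5p', '3p' or None: {self.arm!r}")

    @property
    def display(self) -> str:
        """Canonical display form, ``base-arm`` or bare base."""
        return self.base if self.arm is None else f"{self.base}-{self.arm}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display

    def __lt__(self, other: "CanonicalMiRNA") -> bool:
        # lexicographic on display form; keeps armless/arm-bearing mixes sortable
        return self.display < other.display


def canonicalize(raw_name: str) -> CanonicalMiRNA:
    """Parse a raw miRNA token into a :class:`CanonicalMiRNA`.

    Strips species prefixes (``bta-``, ``spu-`` ...), normalizes stem casing
    (``MiR`` -> ``miR``, ``Let`` -> ``let``), splits a trailing ``-5p``/``-3p``
    arm, drops underscore variant suffixes (``_1``, ``_2``) and invertebrate
    placeholder letters (``-x``/``-y``/``-z``).

    Raises
    ------
    NomenclatureError
        If the name is empty or lacks a ``miR``/``let`` stem.
    """
    name = raw_name.strip()
    if not name:
        raise NomenclatureError("empty miRNA name")

    # variant suffixes like miR-92b-3p_2 annotate precursor copies, not identity
    name = name.split("_", 1)[0]

    m = _PREFIX_RE.match(name)
    if m:
        prefix = m.group(1).lower()
        if prefix not in KNOWN_PREFIXES:
            logger.warning("stripping unrecognized species prefix %r from %r", prefix, raw_name)
        name = name[m.end():]

    lowered = name.lower()
    if lowered.startswith("mir"):
        stem = "miR"
    elif lowered.startswith("let"):
        stem = "let"
    else:
        raise NomenclatureError(f"no miR/let stem in {raw_name!r}")

    rest = name[3:]
    if rest.startswith("-"):
        rest = rest[1:]
    if not rest:
        raise NomenclatureError(f"no identifier after stem in {raw_name!r}")

    tokens = rest.split("-")
    arm: Optional[str] = None
    last = tokens[-1].lower()
    if len(tokens) > 1 and last in _ARMS:
        arm = last
        tokens = tokens[:-1]
    elif len(tokens) > 1 and last in _PLACEHOLDERS:
        tokens = tokens[:-1]

    if not tokens or not tokens[0]:
        raise NomenclatureError(f"no identifier after stem in {raw_name!r}")

    # paralog letters are lowercase by convention (miR-148A -> miR-148a)
    body = "-".join(t.lower() for t in tokens)
    return CanonicalMiRNA(base=f"{stem}-{body}", arm=arm)


def same_mirna(a: CanonicalMiRNA, b: CanonicalMiRNA, arm_policy: str = "exact") -> bool:
    """Identity test under an arm policy.

    ``exact`` requires equal base and arm; ``lenient`` additionally matches
    when either arm is unannotated (an armless table entry matches its
    arm-annotated homolog).
    """
    if arm_policy not in {"exact", "lenient"}:
        raise ValueError(f"arm_policy must be 'exact' or 'lenient': {arm_policy!r}")
    if a.base != b.base:
        return False
    if arm_policy == "exact":
        return a.arm == b.arm
    return a.arm == b.arm or a.arm is None or b.arm is None


def family_key(mirna: CanonicalMiRNA) -> str:
    """Collapse lettered paralogs (miR-92a/miR-92b -> miR-92). Optional helper."""
    return re.sub(r"([0-9])[a-z]+$", r"\1", mirna.base)


@dataclass(frozen=True)
class ConservedList:
    """Allow-list of highly conserved miRNAs; membership is arm-exact."""

    members: frozenset[CanonicalMiRNA]

    def __contains__(self, item: CanonicalMiRNA) -> bool:
        return item in self.members

    def __len__(self) -> int:
        return len(self.members)


def read_conserved_list(path) -> ConservedList:
    """Read an allow-list: UTF-8 text, one display-form name per line, ``#`` comments."""
    members = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.add(canonicalize(line))
    return ConservedList(frozenset(members))


def filter_conserved(
    names: Iterable[CanonicalMiRNA], allow: ConservedList
) -> set[CanonicalMiRNA]:
    """Arm-exact intersection of ``names`` with the conserved allow-list."""
    if not allow.members:
        raise ValueError("conserved allow-list is empty")
    return {n for n in names if n in allow}
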