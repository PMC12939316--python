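"""Target-coverage selection and hypergeometric over-representation analysis.

Generic re-implementations of the downstream analytics usually delegated to
dedicated enrichment suites: shared-target intersections of a miRNA query,
most-targeted gene ranking (genes hit by at least a threshold number of the
query miRNAs, capped), the one-sided hypergeometric tail test and
Benjamini–Hochberg FDR control over a GMT gene-set collection.

The background universe defaults to the target map's own gene space (the
predicted-target universe), mirroring target-prediction-based enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .nomenclature import CanonicalMiRNA

logger = logging.getLogger(__name__)


@dataclass
class TargetMap:
    """miRNA -> target gene sets plus the background gene universe."""

    targets: dict[CanonicalMiRNA, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for m, genes in self.targets.items():
            if not genes:
                raise ValueError(f"empty target set for {m.display}")
            union |= genes
        if not self.universe:
            self.universe = union
        elif not union <= self.universe:
            raise ValueError("targets outside the declared universe")


def read_target_map(path) -> TargetMap:
    """Two-column TSV ``mirna<TAB>gene``; repeated rows dedup on load."""
    from .nomenclature import canonicalize

    targets: dict[CanonicalMiRNA, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()  # mirna / gene
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mirna, gene = line.split("\t")
            targets.setdefault(canonicalize(mirna), set()).add(gene)
    return TargetMap(targets=targets)


def common_targets(
    mirnas: Set[CanonicalMiRNA], target_map: TargetMap, mode: str = "all"
) -> set[str]:
    """Targets of a miRNA query set.

    ``all`` — genes targeted by every query miRNA (intersection);
    ``any`` — genes targeted by at least one (union);
    ``exclusive`` — the union minus every target of the non-query miRNAs.
    """
    if not mirnas:
        raise ValueError("empty miRNA query set")
    missing = sorted(m.display for m in mirnas if m not in target_map.targets)
    if missing:
        raise KeyError(f"miRNAs absent from target map: {', '.join(missing)}")
    sets = [target_map.targets[m] for m in mirnas]
    if mode == "all":
        out = set.intersection(*sets)
    elif mode == "any":
        out = set.union(*sets)
    elif mode == "exclusive":
        out = set.union(*sets)
        for m, genes in target_map.targets.items():
            if m not in mirnas:
                out -= genes
    else:
        raise ValueError(f"mode must be 'all', 'any' or 'exclusive': {mode!r}")
    return out


def coverage_counts(target_map: TargetMap) -> dict[str, int]:
    """Per gene: number of distinct miRNAs in the map targeting it."""
    counts: dict[str, int] = {}
    for genes in target_map.targets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def select_top_targeted(
    counts: Mapping[str, int],
    min_mirnas: int = 40,
    cap: Optional[int] = 100,
    fraction: Optional[float] = None,
) -> list[str]:
    """Most-targeted genes: count >= ``min_mirnas``, count-desc then name-asc,
    truncated to ``cap``; ``fraction`` (e.g. 0.2 for the top 20%) replaces the
    absolute cap when given."""
    if min_mirnas < 1:
        raise ValueError(f"min_mirnas must be >= 1: {min_mirnas}")
    eligible = sorted(
        (g for g, c in counts.items() if c >= min_mirnas),
        key=lambda g: (-counts[g], g),
    )
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1]: {fraction}")
        cap = max(1, int(round(fraction * len(counts)))) if counts else 0
    return eligible if cap is None else eligible[:cap]


def hypergeom_p(x: int, K: int, n: int, M: int) -> float:
    """Upper-tail P(X >= x) drawing ``n`` from ``M`` with ``K`` successes."""
    if not (0 <= x <= min(K, n) and K <= M and n <= M):
        raise ValueError(f"inconsistent counts: x={x}, K={K}, n={n}, M={M}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, M, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    if len(pvalues) == 0:
        return []
    if any(not (0 < p <= 1) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(v) for v in q]


@dataclass
class EnrichmentResult:
    """One gene set's ORA outcome."""

    set_name: str
    x: int  # overlap
    K: int  # set size (within universe)
    n: int  # query size
    M: int  # universe size
    p: float
    q: float = 1.0
    overlap_genes: tuple[str, ...] = ()


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: per line, set name, description, then tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def run_ora(
    query: Set[str],
    gene_sets: Mapping[str, Set[str]],
    universe: Set[str],
    min_overlap: int = 1,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of ``query`` against each gene set.

    Query genes outside the universe are dropped with a logged count; q-values
    come from BH across every tested set (not only those reported), and the
    report keeps sets with overlap >= ``min_overlap``, sorted by q then p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    dropped = len(query - set(universe))
    if dropped:
        logger.warning("dropping %d query gene(s) outside the universe", dropped)
    query_in = set(query) & set(universe)
    if not query_in:
        raise ValueError("no query genes inside the universe")
    M, n = len(universe), len(query_in)
    results = []
    for name, members in gene_sets.items():
        members_in = set(members) & set(universe)
        if not members_in:
            continue
        overlap = sorted(query_in & members_in)
        results.append(
            EnrichmentResult(
                set_name=name,
                x=len(overlap),
                K=len(members_in),
                n=n,
                M=M,
                p=hypergeom_p(len(overlap), len(members_in), n, M),
                overlap_genes=tuple(overlap),
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
    kept = [r for r in results if r.x >= min_overlap]
    kept.sort(key=lambda r: (r.q, r.p, r.set_name))
    return kept


def ora_frame(results: Iterable[EnrichmentResult]):
    """Results as a DataFrame in the output TSV layout."""
    import pandas as pd

    rows = [
        {"set_name": r.set_name, "x": r.x, "K": r.K, "n": r.n, "M": r.M, "p": r.p, "q": r.q}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["set_name", "x", "K", "n", "M", "p", "q"])
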