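"""Synthetic study generator with known ground truth.

Emulates the kind of evidence the pipeline consumes in the wild: per-product
top-N miRNA lists reported by independent studies, each observing a common
underlying abundance profile through multiplicative log-normal noise and its
own naming dialect (species prefixes, occasionally dropped arms).  Abundance
follows a Zipf profile (rank-r member proportional to r^-s), consistent with
the heavy top-10 dominance seen in real small-RNA profiles, where the ten most
abundant miRNAs can account for roughly half to nearly all mapped reads.

Ground truth is constructive: each food group reserves a known set of
group-exclusive miRNAs placed at the top true ranks, the remainder of every
product's top-N window is a core of miRNAs shared by all groups, and deeper
pool members are likewise global.  Exclusivity of the planted sets is then
identifiable from top-N membership alone.

Companion generators plant recoverable structure for the downstream analytics:
a gene covered by a configurable number of miRNA target sets, a gene set that
strictly contains a designated query (hence attains its minimal ORA p-value),
and an interaction star hub of known degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ingest import FOOD_GROUPS, FoodProduct, PresenceMatrix, RankEntry, StudyRanking
from .nomenclature import CanonicalMiRNA

#: Per-group exclusive-set sizes emulated for the five-group configuration.
DEFAULT_EXCLUSIVE_COUNTS = (3, 3, 3, 6, 4)

_JITTER_PREFIXES = ("bta", "ssc", "oar", "chi", "oni", "spu", "efu", "pmi")


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator; defaults are the conditions
    used throughout the test-bed."""

    n_groups: int = 5
    products_per_group: int = 2
    pool_size: int = 30
    zipf_exponent: float = 1.2
    noise_sigma: float = 0.3
    studies_per_product: int = 8
    top_n: int = 10
    prefix_jitter_prob: float = 0.5
    armless_jitter_prob: float = 0.1
    seed: int = 0
    exclusive_counts: Optional[Sequence[int]] = None
    # downstream-analytics plants
    n_genes: int = 200
    targets_per_mirna: int = 25
    planted_gene: str = "PLANTED_TARGET"
    planted_gene_coverage: int = 40
    n_gene_sets: int = 20
    gene_set_size: int = 15
    n_background_edges: int = 60
    planted_hub: str = "HUB"
    planted_hub_degree: int = 7

    def __post_init__(self) -> None:
        if self.pool_size < self.top_n:
            raise ValueError("pool_size must be >= top_n")
        for p in (self.prefix_jitter_prob, self.armless_jitter_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.exclusive_counts is None:
            if self.n_groups == 5:
                self.exclusive_counts = DEFAULT_EXCLUSIVE_COUNTS
            else:
                self.exclusive_counts = tuple([3] * self.n_groups)
        self.exclusive_counts = tuple(self.exclusive_counts)
        if len(self.exclusive_counts) != self.n_groups:
            raise ValueError("exclusive_counts length must equal n_groups")
        if max(self.exclusive_counts) >= self.top_n:
            raise ValueError("exclusive counts must leave room for shared core in top_n")
        if max(self.exclusive_counts) > self.pool_size:
            raise ValueError("exclusive counts exceed pool_size")

    @property
    def group_names(self) -> list[str]:
        if self.n_groups == 5:
            return list(FOOD_GROUPS)
        return [f"group{i + 1}" for i in range(self.n_groups)]


@dataclass
class GroundTruth:
    """True per-product abundances and the planted exclusivity structure."""

    abundances: dict[str, dict[CanonicalMiRNA, float]]  # product -> mirna -> level
    exclusive: dict[str, set[CanonicalMiRNA]]  # group -> planted exclusives
    products: dict[str, FoodProduct]

    def true_order(self, product_id: str) -> list[CanonicalMiRNA]:
        levels = self.abundances[product_id]
        return sorted(levels, key=lambda m: (-levels[m], m.display))

    def true_top(self, product_id: str, k: int) -> list[CanonicalMiRNA]:
        return self.true_order(product_id)[:k]

    def presence_matrix(self, top_n: int) -> PresenceMatrix:
        """Presence of each true top-N member in its product's (group, state)."""
        matrix = PresenceMatrix()
        for pid, product in self.products.items():
            for m in self.true_top(pid, top_n):
                matrix.add(m, product.group, product.state, source=pid)
        return matrix


def _shared_names(n: int) -> list[CanonicalMiRNA]:
    return [CanonicalMiRNA(f"miR-{100 + i}", "5p") for i in range(n)]


def _exclusive_names(group_idx: int, n: int) -> list[CanonicalMiRNA]:
    # 9xx series keeps planted exclusives disjoint from the shared 1xx series
    return [CanonicalMiRNA(f"miR-9{group_idx + 1}{j + 1}", "3p") for j in range(n)]


def gen_abundances(config: SyntheticConfig) -> GroundTruth:
    """Build the deterministic ground-truth abundance profiles.

    Within a product, the true ranked pool is the group's exclusives (ranks
    1..e) followed by globally shared miRNAs; rank r has abundance r^-s.
    """
    shared = _shared_names(config.pool_size)
    abundances: dict[str, dict[CanonicalMiRNA, float]] = {}
    exclusive: dict[str, set[CanonicalMiRNA]] = {}
    products: dict[str, FoodProduct] = {}
    for gi, group in enumerate(config.group_names):
        excl = _exclusive_names(gi, config.exclusive_counts[gi])
        exclusive[group] = set(excl)
        for pj in range(config.products_per_group):
            pid = f"{group}_p{pj + 1}"
            pool = excl + shared[: config.pool_size - len(excl)]
            abundances[pid] = {
                m: (r + 1) ** -config.zipf_exponent for r, m in enumerate(pool)
            }
            products[pid] = FoodProduct(pid, group, "raw", label=f"synthetic {pid}")
    return GroundTruth(abundances=abundances, exclusive=exclusive, products=products)


def gen_studies(
    truth: GroundTruth, config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[StudyRanking]:
    """Draw noisy per-study top-N ballots from the true abundance profiles.

    Observed abundance = true x exp(N(0, sigma^2)); with sigma = 0 every
    study reproduces the true order exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rankings: list[StudyRanking] = []
    for pid in sorted(truth.abundances):
        levels = truth.abundances[pid]
        names = sorted(levels, key=lambda m: m.display)
        true_vals = np.array([levels[m] for m in names])
        for s in range(config.studies_per_product):
            noise = rng.normal(0.0, config.noise_sigma, size=len(names))
            observed = np.log(true_vals) + noise
            order = sorted(
                range(len(names)), key=lambda i: (-observed[i], names[i].display)
            )
            entries = [
                RankEntry(pos + 1, names[i]) for pos, i in enumerate(order[: config.top_n])
            ]
            rankings.append(
                StudyRanking(f"{pid}_s{s + 1}", pid, entries, top_n=config.top_n)
            )
    return rankings


def jittered_name(
    mirna: CanonicalMiRNA, config: SyntheticConfig, rng: np.random.Generator
) -> str:
    """Raw-name dialect jitter: random species prefix, occasionally dropped arm."""
    name = mirna.display
    if mirna.arm is not None and rng.random() < config.armless_jitter_prob:
        name = mirna.base
    if rng.random() < config.prefix_jitter_prob:
        name = f"{rng.choice(_JITTER_PREFIXES)}-{name}"
    return name


def write_synthetic_rankings(
    rankings: Sequence[StudyRanking],
    path,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Serialize ballots in the ingest dialect with raw-name jitter applied."""
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    records = [
        {
            "study": r.study_id,
            "product": r.product_id,
            "rank": e.position,
            "mirna": jittered_name(e.name, config, rng),
            "tie": "",
        }
        for r in rankings
        for e in r.entries
    ]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def gen_target_map(
    truth: GroundTruth, config: SyntheticConfig, rng: Optional[np.random.Generator] = None
):
    """Random miRNA->gene map with one gene planted in a known number of sets."""
    from .enrichment import TargetMap

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    mirnas = sorted(
        {m for levels in truth.abundances.values() for m in levels},
        key=lambda m: m.display,
    )
    coverage = min(config.planted_gene_coverage, len(mirnas))
    planted_carriers = set(rng.choice(len(mirnas), size=coverage, replace=False))
    targets: dict[CanonicalMiRNA, set[str]] = {}
    for i, m in enumerate(mirnas):
        picked = rng.choice(
            config.n_genes, size=min(config.targets_per_mirna, config.n_genes), replace=False
        )
        tset = {genes[j] for j in picked}
        if i in planted_carriers:
            tset.add(config.planted_gene)
        else:
            tset.discard(config.planted_gene)
        targets[m] = tset
    universe = set(genes) | {config.planted_gene}
    return TargetMap(targets=targets, universe=universe)


def gen_gene_sets(
    config: SyntheticConfig,
    universe: Sequence[str],
    planted_query: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, set[str]]:
    """Random gene sets plus, when a query is given, one strict superset of it."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    universe = sorted(universe)
    sets: dict[str, set[str]] = {}
    for i in range(config.n_gene_sets):
        size = min(config.gene_set_size, len(universe))
        picked = rng.choice(len(universe), size=size, replace=False)
        sets[f"random_set_{i + 1:02d}"] = {universe[j] for j in picked}
    if planted_query is not None:
        extra_pool = [g for g in universe if g not in set(planted_query)]
        n_extra = min(2, len(extra_pool))
        extras = {extra_pool[j] for j in rng.choice(len(extra_pool), size=n_extra, replace=False)}
        sets["planted_set"] = set(planted_query) | extras
    return sets


def gen_edges(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
):
    """Random background edges plus a planted star hub of known degree.

    Hub spokes carry score 900 (surviving the default high-confidence
    threshold); background edges connect a disjoint node pool with random
    scores in 400..999.
    """
    import networkx as nx

    from .network import add_edge

    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    net = nx.Graph()
    for j in range(config.planted_hub_degree):
        add_edge(net, config.planted_hub, f"SPOKE{j + 1:02d}", 900)
    pool = [f"BG{i:03d}" for i in range(max(10, config.planted_hub_degree + 3))]
    for _ in range(config.n_background_edges):
        a, b = rng.choice(len(pool), size=2, replace=False)
        # duplicate draws collapse onto one edge keeping the max score
        add_edge(net, pool[a], pool[b], int(rng.integers(400, 1000)))
    return net
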