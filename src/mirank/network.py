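"""Protein interaction network analytics over STRING-dialect edge lists.

Undirected simple graph with integer confidence scores on the STRING 0–1000
scale; analytics are confidence thresholding (high confidence = 700, i.e. a
0.7 combined score), node degrees, a minimum-degree presentation filter, and
hub (top-degree) extraction.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def new_network() -> nx.Graph:
    return nx.Graph()


def add_edge(net: nx.Graph, a: str, b: str, score: int) -> None:
    """Add an undirected edge; duplicates keep the maximum score, self-loops rejected."""
    if a == b:
        raise NetworkError(f"self-loop on {a!r}")
    if not 0 <= score <= 1000:
        raise NetworkError(f"score out of range 0-1000: {score}")
    if net.has_edge(a, b):
        score = max(score, net.edges[a, b]["score"])
    net.add_edge(a, b, score=int(score))


def read_edges(path) -> nx.Graph:
    """Read a STRING-export TSV (``protein1, protein2, combined_score``).

    Fractional scores (<= 1) are rescaled to the 0–1000 integer scale;
    duplicate unordered pairs keep the maximum score; self-loops are dropped
    with a logged count.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    except ValueError as exc:
        raise NetworkError(f"{path}: {exc}") from exc
    missing = [c for c in ("protein1", "protein2", "combined_score") if c not in df.columns]
    if missing:
        raise NetworkError(f"{path}: missing column(s): {', '.join(missing)}")

    net = nx.Graph()
    self_loops = 0
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            raw = float(row.combined_score)
        except (TypeError, ValueError):
            raise NetworkError(
                f"{path}: non-numeric score {row.combined_score!r} at line {i}"
            ) from None
        score = int(round(raw * 1000)) if raw <= 1 else int(round(raw))
        if row.protein1 == row.protein2:
            self_loops += 1
            continue
        add_edge(net, row.protein1, row.protein2, score)
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    return net


def write_edges(net: nx.Graph, path) -> None:
    """Serialize in the input dialect (round-trips with read_edges)."""
    rows = sorted(
        (min(a, b), max(a, b), d["score"]) for a, b, d in net.edges(data=True)
    )
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def threshold(net: nx.Graph, min_score: int = 700) -> nx.Graph:
    """Keep edges with score >= ``min_score``; all nodes are retained."""
    if not 0 <= min_score <= 1000:
        raise NetworkError(f"min_score out of range 0-1000: {min_score}")
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    out.add_edges_from(
        (a, b, d) for a, b, d in net.edges(data=True) if d["score"] >= min_score
    )
    return out


def degrees(net: nx.Graph) -> dict[str, int]:
    """Distinct-neighbor count per node (sums to twice the edge count)."""
    return {node: deg for node, deg in net.degree()}


def min_degree_filter(node_degrees: dict[str, int], k: int = 2) -> dict[str, int]:
    """Nodes with degree >= ``k``, ordered degree-desc then name-asc."""
    if k < 0:
        raise NetworkError(f"k must be >= 0: {k}")
    kept = sorted(
        ((n, d) for n, d in node_degrees.items() if d >= k),
        key=lambda nd: (-nd[1], nd[0]),
    )
    return dict(kept)


def hubs(node_degrees: dict[str, int], top: int = 5) -> list[str]:
    """The ``top`` highest-degree connected nodes, ties broken name-asc."""
    if top < 1:
        raise NetworkError(f"top must be >= 1: {top}")
    connected = sorted(
        ((n, d) for n, d in node_degrees.items() if d > 0),
        key=lambda nd: (-nd[1], nd[0]),
    )
    return [n for n, _ in connected[:top]]
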