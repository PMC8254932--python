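"""TAD interaction graph, maximal cliques and per-TAD clique statistics.

TADs are nodes; significant long-range interactions are edges. A TAD
clique is a set of >= 3 TADs that interact pairwise. Each TAD is
summarized by its degree, its maximal clique size ``k`` (the size of
the largest maximal clique containing it; 1 for isolated TADs) and the
ratio ``k / (degree + 1)``, which measures how much of a TAD's
interaction neighborhood its largest clique accounts for.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .core import TadPairTest

CATEGORIES = ["singleton", "binary", "clique_3", "clique_4", "clique_5",
              "clique_6", "clique_7", "clique_8plus"]


def category_for_k(k: int) -> str:
    if k <= 1:
        return "singleton"
    if k == 2:
        return "binary"
    if k >= 8:
        return "clique_8plus"
    return f"clique_{k}"


def build_tad_graph(pairs: list[TadPairTest], nodes: list[str] | None = None) -> nx.Graph:
    """Simple undirected graph with one edge per significant pair.

    ``nodes``, when given, fixes the node universe so TADs with no
    significant partner are retained as isolated nodes.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for t in pairs:
        if t.tad_a == t.tad_b:
            raise ValueError(f"self-pair {t.tad_a} cannot be a graph edge")
        g.add_edge(t.tad_a, t.tad_b)
    return g


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques (Bron–Kerbosch with pivoting), in
    deterministic lexicographic order of sorted member ids."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques)


def assign_clique_stats(graph: nx.Graph,
                        cliques: list[tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Per-TAD degree, maximal clique size, ratio and category.

    Returns a DataFrame indexed by TAD id with columns ``degree``,
    ``max_clique_size``, ``ratio`` and ``category``. Isolated TADs get
    k = 1 and (trivially) ratio 1.
    """
    if cliques is None:
        cliques = maximal_cliques(graph)
    k = {n: 1 for n in graph.nodes}
    for c in cliques:
        for n in c:
            k[n] = max(k[n], len(c))
    ids = sorted(graph.nodes)
    deg = [graph.degree(n) for n in ids]
    ks = [k[n] for n in ids]
    ratio = [kk / (d + 1) for kk, d in zip(ks, deg)]
    return pd.DataFrame({
        "degree": deg,
        "max_clique_size": ks,
        "ratio": ratio,
        "category": [category_for_k(kk) for kk in ks],
    }, index=pd.Index(ids, name="tad_id"))


def cliques_to_dataframe(cliques: list[tuple[str, ...]]) -> pd.DataFrame:
    return pd.DataFrame({
        "clique_id": [f"C{i + 1:04d}" for i in range(len(cliques))],
        "size": [len(c) for c in cliques],
        "members": [",".join(c) for c in cliques],
    })


def edge_recovery(found_edges: set[frozenset[str]],
                  true_edges: set[frozenset[str]]) -> tuple[float, float]:
    """(precision, recall) of a found edge set against planted edges."""
    if not found_edges:
        return 0.0, 0.0
    tp = len(found_edges & true_edges)
    return tp / len(found_edges), tp / len(true_edges) if true_edges else float("nan")
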