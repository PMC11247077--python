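"""Term-graph construction and largest-connected-component pruning.

Each retained bigram (w1, w2) contributes its two words as nodes and one
undirected, unweighted edge {w1, w2}; duplicate bigrams collapse onto a
single edge and same-word bigrams are dropped as self-loops.  The trained
model of a class is the largest connected component (LCC) of its term
graph — a pruning heuristic that keeps the high-degree core and discards
fragmented satellite components.  Machine-generated corpora characteristically
yield graphs with fewer nodes but more edges than publication corpora, i.e.
a lower node:edge ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .features import BigramTable
from .preprocess import Bigram


@dataclass(frozen=True)
class TermGraph:
    """Undirected word co-occurrence graph of one class."""

    graph: nx.Graph
    class_label: str
    provenance: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, w1: str, w2: str) -> bool:
        return self.graph.has_edge(w1, w2)

    def has_node(self, w: str) -> bool:
        return w in self.graph


@dataclass(frozen=True)
class LCCModel:
    """The pruned largest connected component: the trained model of a class."""

    graph: TermGraph
    n_nodes: int
    n_edges: int
    node_edge_ratio: float | None

    @property
    def class_label(self) -> str:
        return self.graph.class_label

    def contains_edge(self, bigram: Bigram) -> bool:
        return self.graph.has_edge(*bigram)

    def contains_nodes(self, bigram: Bigram) -> bool:
        return self.graph.has_node(bigram[0]) and self.graph.has_node(bigram[1])


def build_term_graph(
    table: BigramTable | Iterable[Bigram],
    class_label: str,
    provenance: str = "",
) -> TermGraph:
    """Build the undirected term graph from a bigram table (or raw bigrams).

    Edge multiplicity is recorded as optional ``count`` metadata but is not
    used by classification.  Raises on an empty table.
    """
    bigrams = table.bigrams() if isinstance(table, BigramTable) else list(table)
    if not bigrams:
        raise ValueError("cannot build a term graph from an empty bigram table")
    g: nx.Graph = nx.Graph()
    for w1, w2 in bigrams:
        if w1 == w2:
            continue  # self-loop carries no connectivity information
        if g.has_edge(w1, w2):
            g[w1][w2]["count"] += 1
        else:
            g.add_edge(w1, w2, count=1)
    return TermGraph(graph=g, class_label=class_label, provenance=provenance)


def largest_connected_component(g: TermGraph) -> LCCModel:
    """Prune a term graph to its largest connected component.

    Ties on component size break deterministically toward the component
    whose lexicographically smallest node sorts first.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot take the LCC of an empty graph")
    components = list(nx.connected_components(g.graph))
    best = max(components, key=lambda c: (len(c), _neg_lex(min(c))))
    sub = g.graph.subgraph(best).copy()
    pruned = TermGraph(graph=sub, class_label=g.class_label, provenance=g.provenance)
    stats = graph_stats(pruned)
    return LCCModel(
        graph=pruned,
        n_nodes=stats["n_nodes"],
        n_edges=stats["n_edges"],
        node_edge_ratio=stats["node_edge_ratio"],
    )


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smallest string."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def graph_stats(g: TermGraph) -> dict:
    """Node count, edge count and node:edge ratio (None when edgeless)."""
    n_nodes = g.n_nodes
    n_edges = g.n_edges
    ratio = n_nodes / n_edges if n_edges >= 1 else None
    return {"n_nodes": n_nodes, "n_edges": n_edges, "node_edge_ratio": ratio}


def save_model(model: LCCModel, path: str | Path) -> None:
    """Persist an LCC model as a tab-separated edge list plus a JSON sidecar."""
    path = Path(path)
    edges = sorted((min(u, v), max(u, v)) for u, v in model.graph.graph.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    sidecar = {
        "class_label": model.class_label,
        "provenance": model.graph.provenance,
        "n_nodes": model.n_nodes,
        "n_edges": model.n_edges,
        "node_edge_ratio": model.node_edge_ratio,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> LCCModel:
    """Load an LCC model saved by :func:`save_model`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    g: nx.Graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v = line.split("\t")
            g.add_edge(u, v)
    tg = TermGraph(graph=g, class_label=sidecar["class_label"],
                   provenance=sidecar.get("provenance", ""))
    stats = graph_stats(tg)
    return LCCModel(graph=tg, n_nodes=stats["n_nodes"], n_edges=stats["n_edges"],
                    node_edge_ratio=stats["node_edge_ratio"])
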