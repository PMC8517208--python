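"""Interactor graph construction and edge-betweenness community detection.

The interactome is the subgraph of a STRING-style edge list induced on a
selected interactor set, with enrichment ratios as node attributes (display
size in the published figure scales with the ratio).  Communities are found
by the divisive edge-betweenness procedure: iteratively remove an edge of
maximal betweenness, recompute, and keep the partition along the removal
sequence that maximizes Newman-Girvan modularity Q.

Betweenness is exact Brandes shortest-path edge betweenness (networkx),
unweighted, with each unordered node pair counted once and equal split over
multiple shortest paths.  Ties on maximal betweenness are broken by removing
the lexicographically smallest edge (sorted endpoint ids), which makes the
whole sweep deterministic without any seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "Partition",
    "build_graph",
    "load_edge_list",
    "edge_betweenness",
    "modularity",
    "cluster_edge_betweenness",
]


@dataclass
class Partition:
    """A disjoint community assignment with its modularity score."""

    communities: dict  # node -> community id (0-based ints)
    modularity: float

    def groups(self) -> list[frozenset]:
        by_id: dict[int, set] = {}
        for node, cid in self.communities.items():
            by_id.setdefault(cid, set()).add(node)
        return [frozenset(s) for _, s in sorted(by_id.items())]


def load_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a ``protein_a<TAB>protein_b<TAB>score`` edge list (score optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need at least two columns")
    rename = {cols[0]: "protein_a", cols[1]: "protein_b"}
    if len(cols) >= 3:
        rename[cols[2]] = "score"
    return df.rename(columns=rename)


def build_graph(interactors, edges: pd.DataFrame, *,
                min_score: float | None = None,
                strict: bool = False) -> nx.Graph:
    """Induced interactor subgraph; isolated interactors stay as singletons.

    ``interactors`` is either an iterable of protein ids or a selection audit
    DataFrame (rows with ``selected`` are used; ``mean_ratio`` becomes the
    ``ratio`` node attribute).  Edges touching unknown ids are dropped with a
    warning (or raise in strict mode); (A,B)/(B,A) duplicates and self-loops
    collapse to single undirected edges / nothing.
    """
    ratios: dict = {}
    if isinstance(interactors, pd.DataFrame):
        df = interactors[interactors["selected"]] if "selected" in interactors \
            else interactors
        nodes = list(df.index)
        if "mean_ratio" in df:
            ratios = df["mean_ratio"].to_dict()
    else:
        nodes = list(interactors)
    node_set = set(nodes)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for node, ratio in ratios.items():
        g.nodes[node]["ratio"] = float(ratio)

    dropped = 0
    for row in edges.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        score = float(getattr(row, "score", 1.0))
        if a == b:
            continue
        if a not in node_set or b not in node_set:
            if strict:
                raise ValueError(f"edge references unknown id: ({a}, {b})")
            dropped += 1
            continue
        if min_score is not None and score < min_score:
            continue
        g.add_edge(a, b, score=score)
    if dropped:
        warnings.warn(f"dropped {dropped} edge(s) referencing unknown ids",
                      stacklevel=2)
    return g


def edge_betweenness(graph: nx.Graph, *, weighted: bool = False) -> dict:
    """Exact shortest-path edge betweenness, unordered pairs counted once."""
    weight = "score" if weighted else None
    eb = nx.edge_betweenness_centrality(graph, normalized=False, weight=weight)
    return {tuple(sorted(e)): v for e, v in eb.items()}


def modularity(graph: nx.Graph, partition: Partition | dict) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2].

    ``m`` is the edge count, ``e_c`` the intra-community edge count and
    ``d_c`` the total degree of community ``c``.  An edgeless graph has
    Q = 0 by convention; an empty graph raises.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("modularity of an empty graph is undefined")
    comm = partition.communities if isinstance(partition, Partition) else partition
    missing = set(graph.nodes) - set(comm)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    e_c: dict = {}
    d_c: dict = {}
    for u, v in graph.edges:
        if comm[u] == comm[v]:
            e_c[comm[u]] = e_c.get(comm[u], 0) + 1
    for node, deg in graph.degree:
        d_c[comm[node]] = d_c.get(comm[node], 0) + deg
    return sum(e_c.get(c, 0) / m - (d / (2.0 * m)) ** 2 for c, d in d_c.items())


def _components_partition(graph: nx.Graph) -> dict:
    comm = {}
    comps = sorted(nx.connected_components(graph), key=lambda s: sorted(s)[0])
    for cid, comp in enumerate(comps):
        for node in comp:
            comm[node] = cid
    return comm


def cluster_edge_betweenness(graph: nx.Graph, *, weighted: bool = False
                             ) -> tuple[Partition, list]:
    """Girvan-Newman sweep with max-modularity selection.

    Removes one maximal-betweenness edge at a time (lexicographically smallest
    edge on ties), recording the component partition whenever the component
    structure changes, and returns the partition with maximal Q on the
    original graph plus the dendrogram of removals
    ``[(edge, betweenness, n_components_after), ...]``.

    Disconnected inputs are handled as-is (components only ever split), and
    community ids are globally unique across components.  An edgeless graph
    returns singleton communities with Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    work = nx.Graph(graph)
    removals: list = []

    best_comm = _components_partition(work)
    best_q = modularity(graph, best_comm)

    while work.number_of_edges() > 0:
        eb = edge_betweenness(work, weighted=weighted)
        max_b = max(eb.values())
        edge = min(e for e, b in eb.items() if b == max_b)
        work.remove_edge(*edge)
        n_comp = nx.number_connected_components(work)
        removals.append((edge, max_b, n_comp))
        comm = _components_partition(work)
        q = modularity(graph, comm)
        if q > best_q + 1e-12:
            best_q, best_comm = q, comm

    return Partition(best_comm, best_q), removals


def partition_table(graph: nx.Graph, partition: Partition) -> pd.DataFrame:
    """Node table (community id, ratio) for export alongside the edge table."""
    rows = [
        (node, partition.communities[node], graph.nodes[node].get("ratio"))
        for node in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "community", "ratio"])
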