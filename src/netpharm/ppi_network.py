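"""Scored interaction graph construction, topology metrics, and exports.

The graph is undirected and unweighted for every metric; combined
scores are used only for threshold cuts (the "medium confidence"
convention) and are carried along for export.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from netpharm.target_sets import GeneSet

__all__ = [
    "NetworkSummary",
    "TopologyRow",
    "build_graph",
    "topology",
    "summarize",
    "rank_hubs",
    "export_graph",
    "read_string_tsv",
    "read_edge_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopologyRow:
    """Per-node topological-importance metrics.

    betweenness is unnormalized shortest-path betweenness (equal
    splitting among equal-length geodesics); betweenness_norm rescales
    by 2/((n-1)(n-2)); closeness is the component-scaled
    Wasserman-Faust variant (r/(n-1)) * (r/sum d) with r = number of
    reachable nodes; coreness is the k-core index.
    """

    gene: str
    degree: int
    betweenness: float
    betweenness_norm: float
    closeness: float
    coreness: int


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_shortest_path: float
    avg_clustering: float
    n_disconnected_pairs: int


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style interactions TSV.

    Requires a header row with a ``combined_score`` column; the first
    two columns are taken as the node labels (STRING exports name them
    ``#node1``/``node2``).
    """
    df = pd.read_csv(path, sep="\t")
    if "combined_score" not in df.columns:
        raise ValueError(f"{path}: no 'combined_score' column")
    cols = list(df.columns)
    df = df.rename(columns={cols[0]: "node1", cols[1]: "node2"})
    return df[["node1", "node2", "combined_score"]]


read_string_tsv = read_edge_table


def build_graph(
    edge_table: pd.DataFrame | Iterable[tuple[str, str, float]],
    score_threshold: float = 0.4,
    drop_isolated: bool = False,
    node_universe: GeneSet | Sequence[str] | None = None,
) -> nx.Graph:
    """Build the undirected scored graph from an edge table.

    Edges scoring at or above `score_threshold` survive; duplicate
    pairs collapse keeping the maximum score; self-loops are dropped.
    Universe nodes with no surviving edge are retained as isolated
    nodes unless `drop_isolated`.  Edge labels not in the universe are
    warned about but kept.
    """
    if isinstance(edge_table, pd.DataFrame):
        rows = edge_table.itertuples(index=False)
        triples = [(str(r[0]), str(r[1]), float(r[2])) for r in rows]
    else:
        triples = [(str(a), str(b), float(s)) for a, b, s in edge_table]

    universe = list(node_universe) if node_universe is not None else []
    universe_set = set(universe)

    g = nx.Graph()
    g.add_nodes_from(universe)
    n_self, n_dup = 0, 0
    for a, b, score in triples:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"combined score {score} outside [0, 1] for edge ({a}, {b})")
        if a == b:
            n_self += 1
            continue
        if score < score_threshold:
            continue
        if universe_set:
            for label in (a, b):
                if label not in universe_set:
                    logger.warning("edge node %r absent from universe; retained", label)
        if g.has_edge(a, b):
            n_dup += 1
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=score)
    if n_self or n_dup:
        logger.info("dropped %d self-loop(s), collapsed %d duplicate edge(s)", n_self, n_dup)
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def topology(graph: nx.Graph) -> list[TopologyRow]:
    """Degree, betweenness, closeness and coreness per node."""
    n = graph.number_of_nodes()
    btw = nx.betweenness_centrality(graph, normalized=False)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    clo = nx.closeness_centrality(graph, wf_improved=True)
    core = nx.core_number(graph)
    return [
        TopologyRow(
            gene=v,
            degree=graph.degree(v),
            betweenness=btw[v],
            betweenness_norm=btw[v] * scale,
            closeness=clo[v],
            coreness=core[v],
        )
        for v in graph.nodes
    ]


def summarize(graph: nx.Graph) -> NetworkSummary:
    """Network-level statistics.

    Average shortest path is the mean geodesic over connected unordered
    pairs only; the number of excluded (disconnected) pairs is reported
    and logged.  Local clustering counts 0 for degree < 2 nodes.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("cannot summarize an empty graph")
    e = graph.number_of_edges()
    total_len = 0
    n_connected_pairs = 0
    for source, dists in nx.all_pairs_shortest_path_length(graph):
        for target, d in dists.items():
            if target != source:
                total_len += d
                n_connected_pairs += 1
    n_connected_pairs //= 2  # each unordered pair counted twice
    total_len //= 2
    all_pairs = n * (n - 1) // 2
    n_disconnected = all_pairs - n_connected_pairs
    if n_disconnected:
        logger.info("%d disconnected pair(s) excluded from average shortest path", n_disconnected)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=2.0 * e / n,
        avg_shortest_path=(total_len / n_connected_pairs) if n_connected_pairs else float("nan"),
        avg_clustering=nx.average_clustering(graph) if n else 0.0,
        n_disconnected_pairs=n_disconnected,
    )


def rank_hubs(rows: Sequence[TopologyRow]) -> list[TopologyRow]:
    """Degree desc, then betweenness desc, then symbol asc — deterministic."""
    return sorted(rows, key=lambda r: (-r.degree, -r.betweenness, r.gene))


def export_graph(graph: nx.Graph, path: str | Path, format: Literal["SIF", "GraphML", "TSV"]) -> None:
    """Write the graph for downstream (Cytoscape-style) consumption.

    SIF uses interaction type ``pp``; TSV mirrors the STRING
    interactions dialect (node1, node2, combined_score) with isolated
    nodes listed as single-column rows so a round trip preserves them.
    """
    path = Path(path)
    if format == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            done = set()
            for a, b, _ in graph.edges(data="combined_score"):
                fh.write(f"{a}\tpp\t{b}\n")
                done.update((a, b))
            for v in graph.nodes:
                if v not in done:
                    fh.write(f"{v}\n")
    elif format == "GraphML":
        nx.write_graphml(graph, path)
    elif format == "TSV":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["node1", "node2", "combined_score"])
            connected = set()
            for a, b, score in graph.edges(data="combined_score"):
                writer.writerow([a, b, repr(float(score))])
                connected.update((a, b))
            for v in graph.nodes:
                if v not in connected:
                    writer.writerow([v, "", ""])
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graph_tsv(path: str | Path) -> nx.Graph:
    """Inverse of ``export_graph(..., format='TSV')``."""
    g = nx.Graph()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            if len(row) >= 3 and row[1]:
                g.add_edge(row[0], row[1], combined_score=float(row[2]))
            elif row and row[0]:
                g.add_node(row[0])
    return g


def write_topology_tsv(path: str | Path, rows: Sequence[TopologyRow]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "degree", "betweenness", "betweenness_norm", "closeness", "coreness"])
        for r in rows:
            writer.writerow(
                [r.gene, r.degree, repr(r.betweenness), repr(r.betweenness_norm), repr(r.closeness), r.coreness]
            )
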