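"""Protein-protein interaction subnetworks and hub ranking.

Meta-genes seed a zero-order (seeds only, isolated nodes removed) or
first-order (seeds plus direct neighbors) subnetwork of a reference
interaction graph.  Hub candidates are ranked by degree with betweenness
centrality as tie-break; a restart random walk from the seed set provides
a propagation-based score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZERO_ORDER = "zero"
FIRST_ORDER = "first"


@dataclass
class InteractionNetwork:
    """Undirected gene graph with optional per-node seed annotations."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_edge_list(path: str | Path, min_score: float | None = None) -> InteractionNetwork:
    """Two-column TSV edge list; a third numeric column is an optional
    confidence score filterable with ``min_score``.  Duplicate edges and
    self-loops are dropped with a log entry."""
    graph = nx.Graph()
    n_self, n_dup, n_filtered = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need at least two columns")
            u, v = fields[0], fields[1]
            if min_score is not None and len(fields) >= 3:
                if float(fields[2]) < min_score:
                    n_filtered += 1
                    continue
            if u == v:
                n_self += 1
                continue
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v)
    if n_self or n_dup or n_filtered:
        logger.info("read_edge_list: dropped %d self-loops, %d duplicates, %d below min_score", n_self, n_dup, n_filtered)
    return InteractionNetwork(graph)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def build_subnetwork(seeds, reference: InteractionNetwork, order: str = ZERO_ORDER) -> InteractionNetwork:
    """Seed-induced subnetwork of the reference graph.

    zero order: subgraph induced on the seeds with degree-0 nodes removed;
    first order: subgraph induced on seeds plus all their direct neighbors.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    present = seeds & set(reference.graph.nodes)
    if not present:
        missing = sorted(seeds)
        raise ValueError(f"no seed maps into the reference network (first missing: {missing[:5]})")
    n_unmapped = len(seeds) - len(present)
    if n_unmapped:
        logger.info("build_subnetwork: %d seeds absent from the reference network", n_unmapped)
    if order == ZERO_ORDER:
        sub = reference.graph.subgraph(present).copy()
        sub.remove_nodes_from([n for n, d in list(sub.degree) if d == 0])
    elif order == FIRST_ORDER:
        neighbors = set()
        for s in present:
            neighbors.update(reference.graph.neighbors(s))
        sub = reference.graph.subgraph(present | neighbors).copy()
    else:
        raise ValueError(f"order must be {ZERO_ORDER!r} or {FIRST_ORDER!r}")
    nx.set_node_attributes(sub, {n: (n in present) for n in sub.nodes}, "seed")
    return InteractionNetwork(sub)


def random_walk_scores(
    net: InteractionNetwork, seeds, restart: float = 0.5, tol: float = 1e-10, max_iter: int = 10_000
) -> pd.Series:
    """Stationary visiting probabilities of a restart random walk from the seeds.

    Power iteration on the column-normalized adjacency; at each step the
    walker restarts to the uniform seed vector with probability ``restart``.
    Mass on dangling (degree-0) nodes is redistributed to the restart
    vector, so the scores always sum to 1.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    nodes = sorted(net.graph.nodes)
    if not nodes:
        raise ValueError("network is empty")
    index = {n: i for i, n in enumerate(nodes)}
    seed_nodes = [s for s in set(seeds) if s in index]
    if not seed_nodes:
        raise ValueError("no seeds present in the network")
    n = len(nodes)
    adj = nx.to_numpy_array(net.graph, nodelist=nodes)
    deg = adj.sum(axis=0)
    dangling = deg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(deg > 0, adj / np.where(deg > 0, deg, 1.0), 0.0)
    p0 = np.zeros(n)
    p0[[index[s] for s in seed_nodes]] = 1.0 / len(seed_nodes)
    p = p0.copy()
    for _ in range(max_iter):
        walk = W @ p + p[dangling].sum() * p0
        p_next = (1.0 - restart) * walk + restart * p0
        if np.abs(p_next - p).max() < tol:
            p = p_next
            break
        p = p_next
    return pd.Series(p, index=nodes, name="rwr_score")


def node_stats(net: InteractionNetwork, seeds, restart: float = 0.5) -> pd.DataFrame:
    """Per-node degree, exact unnormalized betweenness, and restart-walk score.

    Betweenness counts, for each node, the fraction of shortest paths
    between every unordered pair of other nodes that pass through it
    (star center with 4 leaves scores C(4,2) = 6).
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    nodes = sorted(net.graph.nodes)
    degree = pd.Series(dict(net.graph.degree), name="degree").loc[nodes]
    betweenness = pd.Series(
        nx.betweenness_centrality(net.graph, normalized=False), name="betweenness"
    ).loc[nodes]
    rwr = random_walk_scores(net, seeds, restart=restart).loc[nodes]
    seeds = set(seeds)
    stats = pd.DataFrame({"seed": [n in seeds for n in nodes]}, index=nodes)
    stats["degree"] = degree
    stats["betweenness"] = betweenness
    stats["rwr_score"] = rwr
    return stats


def rank_hubs(stats: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Hub ranking: degree descending, ties by betweenness descending, then node id."""
    order = np.lexsort(
        (stats.index.to_numpy(), -stats["betweenness"].to_numpy(), -stats["degree"].to_numpy())
    )
    ranked = stats.iloc[order]
    return ranked.head(top_k) if top_k else ranked


def write_node_stats(stats: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        stats.to_csv(fh, sep="\t", index_label="node", float_format="%.6g")
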