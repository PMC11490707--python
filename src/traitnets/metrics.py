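"""Network metrics for trait networks.

Four metrics summarize a trait network's structure, read here as proxies
for community resilience: modularity Q (with module detection), edge
density, Freeman degree centralization, and per-node degree (high-degree
trait values are candidate keystone traits). All metrics operate on the
binary thresholded network; edge weights are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MetricReport",
    "edge_density",
    "detect_modules",
    "degree_centralization",
    "node_degrees",
    "compute_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("edge_density", "modularity_Q", "n_modules", "degree_centralization")


def _canonical(G: nx.Graph) -> nx.Graph:
    """Copy of G with nodes and edges inserted in sorted order.

    Community detection tie-breaks depend on iteration order; fixing the
    node order makes detection deterministic regardless of how the input
    graph was assembled.
    """
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes(), key=str))
    H.add_edges_from(sorted((tuple(sorted((u, v), key=str)) for u, v in G.edges()),
                            key=lambda e: (str(e[0]), str(e[1]))))
    return H


def edge_density(G: nx.Graph) -> float:
    """Realized edges over all possible edges: m / C(n, 2)."""
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError(f"edge density undefined for n={n} nodes (need n >= 2)")
    return G.number_of_edges() / (n * (n - 1) / 2)


def detect_modules(G: nx.Graph, algorithm: str = "greedy", seed: int | None = None):
    """Partition the network into modules and return (partition, Q).

    The default is greedy (Clauset-Newman-Moore) modularity maximization
    over a canonically ordered copy of the graph, so repeated runs give
    identical partitions without a seed. ``algorithm='fastgreedy'`` is
    the same agglomerative algorithm in igraph's C implementation (also
    deterministic; used where thousands of replicate networks must be
    scored). ``algorithm='louvain'`` selects Louvain instead and then
    requires an explicit seed. Q is the standard Newman-Girvan modularity
    of the returned partition. Edgeless graphs (including the empty
    graph) get one singleton module per node and Q = 0 by convention.

    Returns
    -------
    partition : list[set]
        Modules, sorted by (-size, smallest member) for stable output.
    Q : float
    """
    H = _canonical(G)
    if H.number_of_edges() == 0:
        partition = [{n} for n in H.nodes()]
        return partition, 0.0
    if algorithm == "greedy":
        comms = nx.community.greedy_modularity_communities(H)
    elif algorithm == "fastgreedy":
        import igraph as ig
        nodes = list(H.nodes())
        index = {node: i for i, node in enumerate(nodes)}
        g = ig.Graph(n=len(nodes),
                     edges=[(index[u], index[v]) for u, v in H.edges()])
        membership = g.community_fastgreedy().as_clustering().membership
        comms = {}
        for node, c in zip(nodes, membership):
            comms.setdefault(c, set()).add(node)
        comms = list(comms.values())
    elif algorithm == "louvain":
        if seed is None:
            raise ValueError("louvain is stochastic: an explicit seed is required")
        comms = nx.community.louvain_communities(H, seed=seed)
    else:
        raise ValueError(f"unknown module detection algorithm {algorithm!r}")
    partition = sorted((set(c) for c in comms), key=lambda c: (-len(c), min(map(str, c))))
    Q = nx.community.modularity(H, partition)
    return partition, float(Q)


def degree_centralization(G: nx.Graph) -> float:
    """Freeman degree centralization: sum_i (d_max - d_i) / ((n-1)(n-2)).

    1 for a star (one hub carries every edge), 0 for any regular graph
    (cycle, clique, empty). Undefined below 3 nodes.
    """
    n = G.number_of_nodes()
    if n < 3:
        raise ValueError(f"degree centralization undefined for n={n} nodes (need n >= 3)")
    deg = np.fromiter((d for _, d in G.degree()), dtype=float, count=n)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def node_degrees(G: nx.Graph):
    """Degrees, standardized degrees and the keystone ranking.

    Standardized degree is degree/(n-1), the share of possible partners a
    trait value is connected to. Keystone ranking sorts nodes by degree
    descending, ties broken lexicographically.
    """
    n = G.number_of_nodes()
    degrees = {node: int(d) for node, d in G.degree()}
    standardized = {node: (d / (n - 1) if n > 1 else 0.0) for node, d in degrees.items()}
    keystone = sorted(degrees, key=lambda node: (-degrees[node], str(node)))
    return degrees, standardized, keystone


@dataclass
class MetricReport:
    """All four trait-network metrics plus the module partition."""

    n_nodes: int
    n_edges: int
    edge_density: float
    modularity_Q: float
    modules: list = field(default_factory=list)   # list of sorted node lists
    n_modules: int = 0
    degree_centralization: float = float("nan")
    node_degrees: dict = field(default_factory=dict)
    standardized_degrees: dict = field(default_factory=dict)
    keystone_traits: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def scalar_series(self) -> pd.Series:
        return pd.Series({
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "edge_density": self.edge_density,
            "modularity_Q": self.modularity_Q,
            "n_modules": self.n_modules,
            "degree_centralization": self.degree_centralization,
        })

    def to_csv(self, path) -> None:
        self.scalar_series().rename("value").to_csv(path, index_label="metric")

    def modules_to_csv(self, path) -> None:
        rows = [
            {"node": node, "module_id": k}
            for k, module in enumerate(self.modules)
            for node in module
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def compute_metrics(G: nx.Graph, algorithm: str = "greedy", seed: int | None = None) -> MetricReport:
    """Full MetricReport for one network."""
    n = G.number_of_nodes()
    partition, Q = detect_modules(G, algorithm=algorithm, seed=seed)
    degrees, standardized, keystone = node_degrees(G)
    return MetricReport(
        n_nodes=n,
        n_edges=G.number_of_edges(),
        edge_density=edge_density(G) if n >= 2 else float("nan"),
        modularity_Q=Q,
        modules=[sorted(map(str, m)) for m in partition],
        n_modules=len(partition),
        degree_centralization=degree_centralization(G) if n >= 3 else float("nan"),
        node_degrees=degrees,
        standardized_degrees=standardized,
        keystone_traits=keystone,
    )
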