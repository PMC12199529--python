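"""Sparsified co-occurrence networks, clustering and global properties.

Nodes are genera; an edge connects two genera whose correlation passed the
sparsification test.  Edge weight is the absolute correlation (the sign is
kept as an attribute) and the edge dissimilarity ``1 - weight`` serves as the
shortest-path length.  Isolated genera stay in the graph: each one counts as
its own component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .sparcc import CorrelationEstimate, EdgeTest

__all__ = [
    "MicrobialNetwork",
    "ClusterAssignment",
    "GlobalProperties",
    "build_network",
    "fast_greedy_clusters",
    "global_properties",
]


@dataclass
class MicrobialNetwork:
    graph: nx.Graph
    group_label: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterAssignment:
    cluster_of: dict
    modularity_q: float


@dataclass
class GlobalProperties:
    """The ten whole-network / LCC summary statistics.

    ``edge_number`` is the (definitional) product of edge density and the
    number of components.  Properties that are undefined on a given network
    (e.g. positive-edge percentage of an edgeless graph) are ``None``.
    """

    n_nodes: int
    n_edges: int
    n_components: int
    clustering_coefficient: float
    modularity: float | None
    positive_edge_pct: float | None
    edge_density: float
    natural_connectivity: float
    edge_number: float
    rel_lcc_size: float
    lcc_avg_dissimilarity: float | None
    lcc_avg_path_length: float | None
    lcc_avg_path_length_raw: float | None
    lcc_clustering_coefficient: float
    lcc_modularity: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_network(est: CorrelationEstimate, test: EdgeTest, group_label: str = "") -> MicrobialNetwork:
    """Graph of all genera with edges for every kept pair."""
    if test.keep is None:
        raise ValueError("edge test has no keep mask; run lfdr_adjust first")
    ids = est.genus_ids or [str(i) for i in range(est.rho.shape[0])]
    if len(ids) != est.rho.shape[0]:
        raise ValueError("estimate and genus ids misaligned")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for (i, j), rho, kept in zip(test.pairs, test.rho, test.keep):
        if kept:
            w = abs(float(rho))
            g.add_edge(ids[i], ids[j], rho=float(rho), weight=w, dissimilarity=1.0 - w)
    return MicrobialNetwork(graph=g, group_label=group_label)


def fast_greedy_clusters(net: MicrobialNetwork) -> ClusterAssignment:
    """Agglomerative greedy modularity clustering (Clauset-Newman-Moore).

    Runs on |rho| edge weights; isolated nodes become singleton clusters.
    Cluster ids are assigned in lexicographic order of each cluster's smallest
    node, which fixes the labelling deterministically.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        clusters = {node: k for k, node in enumerate(sorted(g.nodes))}
        return ClusterAssignment(cluster_of=clusters, modularity_q=float("nan"))
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    cluster_of = {node: k for k, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(g, [set(c) for c in communities], weight="weight")
    return ClusterAssignment(cluster_of=cluster_of, modularity_q=float(q))


def _modularity_of(g: nx.Graph, cluster_of: dict) -> float | None:
    if g.number_of_edges() == 0:
        return None
    groups: dict = {}
    for node, c in cluster_of.items():
        if node in g:
            groups.setdefault(c, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values()), weight="weight"))


def natural_connectivity(g: nx.Graph, weighted: bool = False) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    The unweighted skeleton is the default (the robustness-literature
    convention); ``weighted`` uses |rho| edge weights instead.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight="weight" if weighted else None)
    lam = np.linalg.eigvalsh(a)
    # log-sum-exp for numerical safety on larger spectra
    m = lam.max()
    return float(m + np.log(np.mean(np.exp(lam - m))))


def average_path_length(g: nx.Graph, weight: str = "dissimilarity") -> float | None:
    """Mean weighted shortest-path length over all connected node pairs."""
    total, pairs = 0.0, 0
    for source, dists in nx.all_pairs_dijkstra_path_length(g, weight=weight):
        for target, d in dists.items():
            if target != source:
                total += d
                pairs += 1
    if pairs == 0:
        return None
    return total / pairs


def global_properties(
    net: MicrobialNetwork,
    clusters: ClusterAssignment | None = None,
    clustering: str = "global",
) -> GlobalProperties:
    """Compute the ten global properties plus the LCC-restricted variants.

    The LCC average path length uses dissimilarity edge lengths and is
    reported both raw and in units of the LCC's average dissimilarity (raw
    mean divided by the mean edge dissimilarity).  ``clustering`` selects the
    clustering-coefficient flavour: ``"global"`` transitivity (default) or
    ``"average"`` mean local clustering, both on the unweighted skeleton.
    """
    if clustering not in ("global", "average"):
        raise ValueError(f"unknown clustering flavour {clustering!r}")
    cc = nx.transitivity if clustering == "global" else nx.average_clustering
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    if clusters is None:
        clusters = fast_greedy_clusters(net)

    n_components = nx.number_connected_components(g)
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    pos_pct = (
        100.0 * sum(1 for *_, d in g.edges(data=True) if d["rho"] > 0) / m if m else None
    )
    modularity = _modularity_of(g, clusters.cluster_of)

    lcc_nodes = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    lcc = g.subgraph(lcc_nodes)
    lcc_m = lcc.number_of_edges()
    lcc_diss = (
        float(np.mean([d["dissimilarity"] for *_, d in lcc.edges(data=True)])) if lcc_m else None
    )
    apl_raw = average_path_length(lcc) if lcc_m else None
    apl_units = (
        apl_raw / lcc_diss if apl_raw is not None and lcc_diss not in (None, 0.0) else None
    )

    return GlobalProperties(
        n_nodes=n,
        n_edges=m,
        n_components=n_components,
        clustering_coefficient=float(cc(g)),
        modularity=modularity,
        positive_edge_pct=pos_pct,
        edge_density=density,
        natural_connectivity=natural_connectivity(g),
        edge_number=density * n_components,
        rel_lcc_size=len(lcc_nodes) / n,
        lcc_avg_dissimilarity=lcc_diss,
        lcc_avg_path_length=apl_units,
        lcc_avg_path_length_raw=apl_raw,
        lcc_clustering_coefficient=float(cc(lcc)),
        lcc_modularity=_modularity_of(lcc, clusters.cluster_of),
    )
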