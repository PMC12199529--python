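"""Independent brute-force oracles used only by the tests."""

import itertools

import networkx as nx
import numpy as np

N_ORBITS = 15


def orbit_counts_exhaustive(g: nx.Graph) -> np.ndarray:
    """Orbit counts by checking every node subset of size 2-4 for connectivity
    and classifying the induced subgraph by its degree multiset."""
    nodes = sorted(g.nodes)
    counts = {v: [0] * N_ORBITS for v in nodes}
    for v in nodes:
        counts[v][0] = g.degree(v)
    for k in (3, 4):
        for sub in itertools.combinations(nodes, k):
            h = g.subgraph(sub)
            if not nx.is_connected(h):
                continue
            deg = {v: h.degree(v) for v in sub}
            e = h.number_of_edges()
            if k == 3:
                orb = {v: 3 if e == 3 else (2 if deg[v] == 2 else 1) for v in sub}
            elif e == 3:
                if max(deg.values()) == 3:
                    orb = {v: 7 if deg[v] == 3 else 6 for v in sub}
                else:
                    orb = {v: 4 if deg[v] == 1 else 5 for v in sub}
            elif e == 4:
                if max(deg.values()) == 2:
                    orb = {v: 8 for v in sub}
                else:
                    orb = {v: {1: 9, 2: 10, 3: 11}[deg[v]] for v in sub}
            elif e == 5:
                orb = {v: 12 if deg[v] == 2 else 13 for v in sub}
            else:
                orb = {v: 14 for v in sub}
            for v in sub:
                counts[v][orb[v]] += 1
    return np.array([counts[v] for v in nodes])


def betweenness_floyd_warshall(g: nx.Graph, weight: str) -> dict:
    """Betweenness by Floyd-Warshall distances plus explicit path counting."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, d in g.edges(data=True):
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = d[weight]
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])

    tol = 1e-12
    sigma = np.zeros((n, n))          # number of shortest paths
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        for t in np.argsort(dist[s]):
            if t == s or not np.isfinite(dist[s, t]):
                continue
            sigma[s, t] = sum(
                sigma[s, idx[a]]
                for a in g.neighbors(nodes[t])
                if abs(dist[s, idx[a]] + g[a][nodes[t]][weight] - dist[s, t]) < tol
            )

    bc = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t) or not np.isfinite(dist[s, v]) or not np.isfinite(dist[v, t]):
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) < tol:
                    bc[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def modularity_direct(g: nx.Graph, partition, weight: str = "weight") -> float:
    """Weighted Newman modularity evaluated straight from its definition."""
    m2 = sum(d.get(weight, 1.0) for *_, d in g.edges(data=True)) * 2.0
    strength = {v: 0.0 for v in g.nodes}
    for u, v, d in g.edges(data=True):
        strength[u] += d.get(weight, 1.0)
        strength[v] += d.get(weight, 1.0)
    q = 0.0
    for comm in partition:
        inside = sum(
            d.get(weight, 1.0)
            for u, v, d in g.edges(data=True)
            if u in comm and v in comm
        )
        tot = sum(strength[v] for v in comm)
        q += 2.0 * inside / m2 - (tot / m2) ** 2
    return q


def bh_keep_by_sort(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg by sorting."""
    m = len(pvals)
    order = np.argsort(pvals)
    keep = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= alpha * rank / m:
            max_k = rank
    keep[order[:max_k]] = True
    return keep


def expected_jaccard_hypergeometric(universe: int, a: int, b: int) -> float:
    """Closed-form null mean of the Jaccard index for random same-size sets."""
    from scipy.stats import hypergeom

    ks = np.arange(0, min(a, b) + 1)
    pmf = hypergeom(universe, a, b).pmf(ks)
    with np.errstate(invalid="ignore"):
        j = np.where(a + b - ks > 0, ks / (a + b - ks), 0.0)
    return float(np.sum(pmf * j))
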