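"""Graphlet orbit counting (2-4 nodes), graphlet correlation matrices and
terminal-node role analysis.

A graphlet is a small connected induced subgraph; an orbit is an equivalence
class of node positions under the graphlet's automorphisms.  Up to four nodes
there are 9 graphlets with 15 orbits; orbits 3, 12, 13 and 14 are redundant
(their counts follow from the others through subgraph-counting identities),
leaving the 11 non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11}.  Orbit 0 is
the node degree; orbits 1, 4, 6 and 9 are the end-node ("terminal") orbits.

Counting enumerates every connected induced subgraph on 3-4 nodes exactly
once with the ESU scheme (bitmask adjacency) and classifies it by its inner
degree sequence, which determines the orbit of every member node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import MicrobialNetwork

__all__ = [
    "N_ORBITS",
    "NONREDUNDANT_ORBITS",
    "REDUNDANT_ORBITS",
    "TERMINAL_ORBITS",
    "OrbitCountMatrix",
    "GCM",
    "GCMDifference",
    "TerminalNodeReport",
    "count_orbits",
    "gcm",
    "gcm_difference",
    "select_orbits",
    "map_genera",
    "orbit_taxonomy",
]

N_ORBITS = 15
#: orbits whose counts are determined by the others (see orbit_taxonomy)
REDUNDANT_ORBITS = (3, 12, 13, 14)
NONREDUNDANT_ORBITS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)
#: end-node orbits: positions with a single attachment into the subgraph
TERMINAL_ORBITS = (1, 4, 6, 9)


@dataclass
class OrbitCountMatrix:
    counts: pd.DataFrame           # node x 15 integer counts

    @property
    def reduced(self) -> pd.DataFrame:
        """Node x 11 view restricted to the non-redundant orbits."""
        return self.counts.iloc[:, list(NONREDUNDANT_ORBITS)]


@dataclass
class GCM:
    spearman: pd.DataFrame         # 11 x 11, unit diagonal where defined
    n_rows: int                    # nodes + pseudo-count row


@dataclass
class GCMDifference:
    table: pd.DataFrame            # upper-triangle entries with z / p / significance
    alpha: float


@dataclass
class TerminalNodeReport:
    orbits: tuple[int, ...]
    occurrence: pd.Series          # mean orbit count over the selected orbits
    focal: pd.Series               # True when in the top-k of every orbit
    top_k: int
    warning: str | None = None


def _classify3(deg: tuple[int, int, int]) -> tuple[int, ...]:
    if sum(deg) == 4:              # path: two edges
        return tuple(2 if d == 2 else 1 for d in deg)
    return (3, 3, 3)               # triangle


def _classify4(deg: tuple[int, int, int, int]) -> tuple[int, ...]:
    e = sum(deg) // 2
    if e == 3:
        if max(deg) == 3:          # star
            return tuple(7 if d == 3 else 6 for d in deg)
        return tuple(4 if d == 1 else 5 for d in deg)    # path
    if e == 4:
        if max(deg) == 2:          # 4-cycle
            return (8, 8, 8, 8)
        return tuple({1: 9, 2: 10, 3: 11}[d] for d in deg)  # tailed triangle
    if e == 5:                     # diamond
        return tuple(12 if d == 2 else 13 for d in deg)
    return (14, 14, 14, 14)        # K4


def count_orbits(net: MicrobialNetwork | nx.Graph) -> OrbitCountMatrix:
    """Exact per-node orbit counts for all 2-4-node graphlets.

    Every connected induced subgraph on 3 or 4 nodes is visited exactly once
    (ESU enumeration over bitmask adjacency); 2-node counts are the degrees.
    """
    g = net.graph if isinstance(net, MicrobialNetwork) else net
    nodes = sorted(g.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges:
        iu, iv = index[u], index[v]
        adj[iu] |= 1 << iv
        adj[iv] |= 1 << iu

    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    for i in range(n):
        counts[i, 0] = adj[i].bit_count()

    def classify(members: list[int], sub_mask: int) -> None:
        k = len(members)
        deg = tuple((adj[m] & sub_mask).bit_count() for m in members)
        orbits = _classify3(deg) if k == 3 else _classify4(deg)
        for m, o in zip(members, orbits):
            counts[m, o] += 1

    # ESU: each connected induced subgraph rooted at its smallest node,
    # extension candidates restricted to indices above the root.
    for root in range(n):
        above = ~((1 << (root + 1)) - 1)
        ext0 = adj[root] & above
        stack = [([root], ext0, 1 << root, adj[root])]
        while stack:
            members, ext, sub_mask, nbr_mask = stack.pop()
            if len(members) >= 3:
                classify(members, sub_mask)
            if len(members) == 4:
                continue
            e = ext
            while e:
                w_bit = e & -e
                e ^= w_bit
                w = w_bit.bit_length() - 1
                # candidates for deeper levels: exclusive new neighbours of w
                new_ext = e | (adj[w] & above & ~nbr_mask & ~sub_mask)
                stack.append(
                    (members + [w], new_ext, sub_mask | w_bit, nbr_mask | adj[w])
                )

    return OrbitCountMatrix(
        counts=pd.DataFrame(counts, index=nodes, columns=[f"o{i}" for i in range(N_ORBITS)])
    )


def gcm(matrix: OrbitCountMatrix) -> GCM:
    """Graphlet correlation matrix: Spearman correlation between the 11
    non-redundant orbit-count columns, after appending a pseudo-count row of
    ones (so orbits unobserved in the network still yield defined ranks).

    Entries involving a column that is constant even with the pseudo row are
    reported as missing rather than fabricated.
    """
    reduced = matrix.reduced
    if reduced.shape[0] + 1 < 3:
        raise ValueError("need at least 2 nodes (3 rows with the pseudo row)")
    data = np.vstack([reduced.to_numpy(), np.ones(reduced.shape[1])])
    k = data.shape[1]
    rho = np.full((k, k), np.nan)
    constant = data.std(axis=0) == 0
    ok = ~constant
    if ok.sum() == 2:
        r = stats.spearmanr(data[:, ok]).statistic
        rho[np.ix_(ok, ok)] = np.array([[1.0, r], [r, 1.0]])
    elif ok.sum() > 2:
        rho[np.ix_(ok, ok)] = stats.spearmanr(data[:, ok]).statistic
    rho[np.diag_indices(k)] = np.where(ok, 1.0, np.nan)
    labels = list(reduced.columns)
    return GCM(spearman=pd.DataFrame(rho, index=labels, columns=labels), n_rows=data.shape[0])


def gcm_difference(g1: GCM, g2: GCM, alpha: float = 0.05, adjust: str | None = None,
                   spearman_variance_factor: float = 1.0) -> GCMDifference:
    """Fisher z-test on every upper-triangle GCM entry.

    The statistic is ``(atanh r1 - atanh r2) / sqrt(v/(n1-3) + v/(n2-3))``
    with ``v = spearman_variance_factor`` (1.0 by default; 1.06 is the usual
    Spearman correction) and ``n`` the number of rows used for each GCM
    (nodes plus the pseudo row).  Entries with ``|r| = 1`` get infinite z and
    ``p = 0`` with a flag; missing correlations propagate as missing.
    ``adjust="bh"`` applies Benjamini-Hochberg across the tested entries.
    """
    if min(g1.n_rows, g2.n_rows) <= 3:
        raise ValueError("both GCMs need more than 3 rows for the z-test")
    labels = list(g1.spearman.columns)
    if labels != list(g2.spearman.columns):
        raise ValueError("GCMs must share orbit labels")
    rows = []
    for a, b in combinations(range(len(labels)), 2):
        r1 = g1.spearman.iat[a, b]
        r2 = g2.spearman.iat[a, b]
        rec = {"orbit_a": labels[a], "orbit_b": labels[b], "r1": r1, "r2": r2,
               "abs_diff": abs(r1 - r2), "degenerate": False}
        if np.isnan(r1) or np.isnan(r2):
            rec.update(z=np.nan, p=np.nan)
        elif abs(r1) >= 1.0 or abs(r2) >= 1.0:
            if r1 == r2:
                rec.update(z=0.0, p=1.0, degenerate=True)
            else:
                rec.update(z=np.inf if r1 > r2 else -np.inf, p=0.0, degenerate=True)
        else:
            se = np.sqrt(
                spearman_variance_factor / (g1.n_rows - 3)
                + spearman_variance_factor / (g2.n_rows - 3)
            )
            z = (np.arctanh(r1) - np.arctanh(r2)) / se
            rec.update(z=z, p=2.0 * stats.norm.sf(abs(z)))
        rows.append(rec)
    df = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        tested = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if tested.any():
            adj[tested.to_numpy()] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
        df["p_adj"] = adj
        df["significant"] = df["p_adj"] <= alpha
    elif adjust is None:
        df["significant"] = df["p"] <= alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return GCMDifference(table=df, alpha=alpha)


def select_orbits(diff: GCMDifference, min_hits: int = 1) -> list[int]:
    """Orbits of interest, ranked by how many significant entries they touch
    (ties broken by orbit id)."""
    hits: dict[int, int] = {}
    for _, row in diff.table[diff.table["significant"].fillna(False)].iterrows():
        for label in (row["orbit_a"], row["orbit_b"]):
            o = int(str(label).lstrip("o"))
            hits[o] = hits.get(o, 0) + 1
    chosen = [(cnt, o) for o, cnt in hits.items() if cnt >= min_hits]
    return [o for cnt, o in sorted(chosen, key=lambda t: (-t[0], t[1]))]


def map_genera(matrix: OrbitCountMatrix, orbits, top_k: int = 25) -> TerminalNodeReport:
    """Rank genera within each selected orbit and flag the focal set.

    ``focal`` genera appear in the top ``top_k`` of every selected orbit
    (ties broken lexicographically by genus id); ``occurrence`` is the mean
    count over the selected orbits.
    """
    orbits = tuple(int(o) for o in orbits)
    if not orbits:
        raise ValueError("no orbits selected")
    warning = None
    n = matrix.counts.shape[0]
    if top_k > n:
        warning = f"top_k clamped from {top_k} to the {n} available genera"
        top_k = n
    cols = [f"o{o}" for o in orbits]
    sub = matrix.counts[cols]
    focal_sets = []
    for col in cols:
        # stable sort: genus id ascending first, then count descending
        order = sub[col].sort_index().sort_values(ascending=False, kind="mergesort")
        focal_sets.append(set(order.index[:top_k]))
    focal_members = set.intersection(*focal_sets)
    occurrence = sub.mean(axis=1)
    focal = pd.Series({g: g in focal_members for g in matrix.counts.index})
    return TerminalNodeReport(
        orbits=orbits,
        occurrence=occurrence,
        focal=focal,
        top_k=top_k,
        warning=warning,
    )


def orbit_taxonomy() -> dict:
    """Enumerate the graphlet/orbit taxonomy for 2-4 nodes from first
    principles.

    Generates all connected graphs on 2, 3 and 4 nodes up to isomorphism,
    computes the automorphism orbits of each, and reports the totals together
    with the non-redundant orbit count after removing the dependent orbits
    (triangle orbit 3 follows from orbits 0 and 2 via
    ``o3 = C(o0, 2) - o2``; orbits 12-14 follow from neighbourhood-triple
    identities such as ``C(o0, 3) = o7 + o11 + o13 + o14``).
    """
    graphlets = []
    for k in (2, 3, 4):
        seen: list[nx.Graph] = []
        for edges in _edge_subsets(k):
            g = nx.Graph()
            g.add_nodes_from(range(k))
            g.add_edges_from(edges)
            if not nx.is_connected(g):
                continue
            if any(nx.is_isomorphic(g, h) for h in seen):
                continue
            seen.append(g)
        graphlets.extend(seen)

    orbit_total = 0
    per_graphlet = []
    for g in graphlets:
        gm = nx.algorithms.isomorphism.GraphMatcher(g, g)
        nodes = list(g.nodes)
        partner: dict = {v: {v} for v in nodes}
        for mapping in gm.isomorphisms_iter():
            for v, w in mapping.items():
                partner[v].add(w)
        orbits = {frozenset(s) for s in partner.values()}
        per_graphlet.append(len(orbits))
        orbit_total += len(orbits)
    return {
        "n_graphlets": len(graphlets),
        "orbits_per_graphlet": per_graphlet,
        "n_orbits": orbit_total,
        "n_nonredundant_orbits": orbit_total - len(REDUNDANT_ORBITS),
        "nonredundant_orbits": list(NONREDUNDANT_ORBITS),
    }


def _edge_subsets(k: int):
    pairs = list(combinations(range(k), 2))
    for bits in range(1 << len(pairs)):
        yield [pairs[i] for i in range(len(pairs)) if bits >> i & 1]
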