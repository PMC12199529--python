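"""Node centralities, hub detection, the Jaccard set test and core microbiota.

A hub is a genus whose min/max-scaled degree, betweenness and closeness all
lie strictly above the chosen empirical quantile.  Two core-microbiota
definitions are implemented: the conventional prevalence/abundance rule and a
network-based one that lowers the hub quantile until the core reaches a
target size, enabling like-for-like comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import MicrobialNetwork
from .preprocess import CompositionTable, CountTable

__all__ = [
    "HubSet",
    "JaccardResult",
    "CoreSet",
    "CoreComparison",
    "centralities",
    "hubs",
    "jaccard_test",
    "core_def1",
    "core_def2",
    "compare_cores",
]

MM_COLUMNS = ("degree_mm", "betweenness_mm", "closeness_mm")


@dataclass
class HubSet:
    quantile: float
    genera: frozenset[str]


@dataclass
class JaccardResult:
    jaccard: float
    expected: float
    p_greater: float
    p_less: float
    n_permutations: int
    degenerate: bool = False


@dataclass
class CoreSet:
    definition: str                # "prevalence_abundance" | "hub_quantile"
    genera: frozenset[str]
    params: dict = field(default_factory=dict)
    warning: str | None = None


@dataclass
class CoreComparison:
    core_size: int
    average_prevalence_pct: float
    cumulative_abundance: float
    mean_summed_centrality: float


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def centralities(net: MicrobialNetwork, weighted_paths: bool = True) -> pd.DataFrame:
    """Degree, betweenness and closeness, normalised and min/max scaled.

    Degree is the unweighted edge count.  Betweenness counts shortest paths
    through a node and closeness is the inverse average distance within a
    node's component (Wasserman-Faust component scaling; isolated nodes get
    zero), both using dissimilarity edge lengths when ``weighted_paths``.
    Normalised columns divide by ``n - 1``; the ``*_mm`` columns are min/max
    scaled per measure, with constant columns mapped to all zeros.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("centralities need at least 2 nodes")
    weight = "dissimilarity" if weighted_paths else None
    nodes = sorted(g.nodes)
    degree = pd.Series({v: g.degree(v) for v in nodes}, dtype=float)
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=False, weight=weight))
    closeness = pd.Series(nx.closeness_centrality(g, distance=weight, wf_improved=True))

    df = pd.DataFrame(
        {
            "degree_raw": degree,
            "betweenness_raw": betweenness.reindex(nodes),
            "closeness_raw": closeness.reindex(nodes),
        }
    )
    df["betweenness_norm"] = df["betweenness_raw"] / (n - 1)
    df["closeness_norm"] = df["closeness_raw"] / (n - 1)
    df["degree_mm"] = _minmax(df["degree_raw"])
    df["betweenness_mm"] = _minmax(df["betweenness_norm"])
    df["closeness_mm"] = _minmax(df["closeness_norm"])
    df["summed_mm"] = df[list(MM_COLUMNS)].sum(axis=1)
    return df


def hubs(table: pd.DataFrame, quantile: float = 0.90) -> HubSet:
    """Genera strictly above the per-measure empirical quantile on all three
    scaled centralities (linear-interpolation quantile)."""
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    mask = np.ones(len(table), dtype=bool)
    for col in MM_COLUMNS:
        cut = np.quantile(table[col].to_numpy(), quantile)
        mask &= table[col].to_numpy() > cut
    return HubSet(quantile=quantile, genera=frozenset(table.index[mask]))


def jaccard_test(
    set_a,
    set_b,
    universe,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> JaccardResult:
    """Permutation test of set similarity following the Real & Vargas scheme.

    The null draws same-size random subsets from the shared universe;
    ``p_greater``/``p_less`` are one-sided Monte-Carlo p-values with the +1
    small-sample correction and ``expected`` is the null mean Jaccard index.
    """
    universe = list(universe)
    a = frozenset(set_a)
    b = frozenset(set_b)
    if not (a | b):
        return JaccardResult(0.0, 0.0, 1.0, 1.0, n_permutations, degenerate=True)
    if not (a <= set(universe) and b <= set(universe)):
        raise ValueError("sets must be drawn from the universe")
    observed = len(a & b) / len(a | b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_u = len(universe)
    # vectorised null: membership masks of random same-size subsets
    order_a = np.argsort(rng.random((n_permutations, n_u)), axis=1)
    order_b = np.argsort(rng.random((n_permutations, n_u)), axis=1)
    in_a = np.zeros((n_permutations, n_u), dtype=bool)
    in_b = np.zeros((n_permutations, n_u), dtype=bool)
    np.put_along_axis(in_a, order_a[:, : len(a)], True, axis=1)
    np.put_along_axis(in_b, order_b[:, : len(b)], True, axis=1)
    inter = (in_a & in_b).sum(axis=1)
    union = (in_a | in_b).sum(axis=1)
    null = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    p_greater = (1 + np.sum(null >= observed)) / (n_permutations + 1)
    p_less = (1 + np.sum(null <= observed)) / (n_permutations + 1)
    return JaccardResult(
        jaccard=observed,
        expected=float(null.mean()),
        p_greater=float(p_greater),
        p_less=float(p_less),
        n_permutations=n_permutations,
    )


def _relative_abundance(table) -> pd.DataFrame:
    if isinstance(table, CompositionTable):
        return table.fractions
    if isinstance(table, CountTable):
        return table.counts / table.counts.sum(axis=0)
    raise TypeError("expected a CountTable or CompositionTable")


def core_def1(table, detection: float = 0.001, prevalence: float = 0.5) -> CoreSet:
    """Conventional core: relative abundance above ``detection`` in at least a
    ``prevalence`` fraction of samples."""
    rel = _relative_abundance(table)
    frac_detected = (rel > detection).mean(axis=1)
    members = frozenset(rel.index[frac_detected >= prevalence])
    return CoreSet(
        definition="prevalence_abundance",
        genera=members,
        params={"detection": detection, "prevalence": prevalence},
    )


def core_def2(
    table: pd.DataFrame,
    target_count: int,
    q_start: float = 0.95,
    q_step: float = 0.005,
) -> CoreSet:
    """Hub-based core: scan hub quantiles downward and return the hub set
    whose size is closest to ``target_count`` (larger quantile wins ties)."""
    if target_count < 1:
        raise ValueError("target_count must be at least 1")
    grid = np.arange(q_start, -q_step / 2, -q_step)
    best: tuple[int, float, HubSet] | None = None
    for q in grid:
        hs = hubs(table, quantile=max(q, 0.0))
        diff = abs(len(hs.genera) - target_count)
        if best is None or diff < best[0]:
            best = (diff, q, hs)
        if diff == 0:
            break
    assert best is not None
    diff, q, hs = best
    warning = (
        f"closest achievable core size is {len(hs.genera)} (target {target_count})"
        if diff > 0
        else None
    )
    return CoreSet(
        definition="hub_quantile",
        genera=hs.genera,
        params={"quantile": float(q), "target_count": target_count},
        warning=warning,
    )


def compare_cores(core: CoreSet, counts: CountTable, table: pd.DataFrame) -> CoreComparison:
    """Prevalence, cumulative abundance and mean summed centrality of a core.

    Average prevalence is the mean over samples of the percentage of core
    genera present (count > 0); cumulative abundance is the per-sample summed
    count of core genera averaged over samples (count scale); the centrality
    summary averages ``summed_mm`` over core members present in the table.
    """
    members = sorted(core.genera)
    if not members:
        raise ValueError("empty core set")
    missing = [m for m in members if m not in counts.counts.index]
    if missing:
        raise ValueError(f"core members missing from the count table: {missing[:5]}")
    sub = counts.counts.loc[members]
    prevalence_pct = float((sub > 0).mean(axis=0).mean() * 100.0)
    cumulative = float(sub.sum(axis=0).mean())
    in_table = [m for m in members if m in table.index]
    mean_centrality = float(table.loc[in_table, "summed_mm"].mean()) if in_table else float("nan")
    return CoreComparison(
        core_size=len(members),
        average_prevalence_pct=prevalence_pct,
        cumulative_abundance=cumulative,
        mean_summed_centrality=mean_centrality,
    )
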