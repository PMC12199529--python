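"""Permutation tests for group differences in network properties.

The null hypothesis is that a network property computed from group 1 equals
that from group 2.  Its sampling distribution is obtained by randomly
reassigning group labels to samples (preserving group sizes) and re-running
the full per-group pipeline -- zero replacement, SparCC, edge sparsification,
property computation -- for every permutation.  Taxon/sample filters are
applied once to the full dataset before permuting, keeping the genus universe
fixed so per-genus comparisons stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import centralities
from .network import build_network, global_properties
from .preprocess import CountTable, bayes_multiplicative_replace
from .sparcc import edge_significance, lfdr_adjust, sparcc

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "permute_labels",
    "group_pipeline",
    "property_difference_test",
    "centrality_difference_test",
]

#: properties computable without building a graph (cheap numpy path)
_FAST_PROPERTIES = {"edge_density", "positive_edge_pct", "n_edges"}


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    properties: tuple[str, ...] = ("edge_density",)
    sparsify_method: str = "lfdr"      # "lfdr" or "bh"
    sparsify_alpha: float = 0.05
    max_failure_fraction: float = 0.05
    #: re-apply taxon filters inside every permutation (default keeps the
    #: genus universe fixed by filtering once, up front)
    refilter_per_permutation: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")


@dataclass
class PermutationResult:
    property: str
    observed: tuple[float, float]
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    significant: bool
    n_failed: int = 0


def permute_labels(group_of: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Uniformly random relabeling preserving the original group sizes."""
    labels = group_of.to_numpy()
    if len(pd.unique(labels)) != 2:
        raise ValueError("need exactly two groups")
    return pd.Series(rng.permutation(labels), index=group_of.index, name=group_of.name)


def _keep_matrix(counts: np.ndarray, method: str, alpha: float):
    """Zero-replace -> SparCC -> t-test -> keep mask, all in numpy.

    Returns (rho, keep) as condensed upper-triangle vectors plus D.
    """
    frac = bayes_multiplicative_replace(counts)
    est = sparcc(frac)
    test = edge_significance(est)
    test = lfdr_adjust(test, alpha=alpha, method=method)
    return est, test


def _fast_properties(test, D: int, wanted: set[str]) -> dict[str, float]:
    kept = test.keep
    m = int(kept.sum())
    out = {}
    if "n_edges" in wanted:
        out["n_edges"] = float(m)
    if "edge_density" in wanted:
        out["edge_density"] = 2.0 * m / (D * (D - 1))
    if "positive_edge_pct" in wanted:
        out["positive_edge_pct"] = (
            100.0 * float((test.rho[kept] > 0).sum()) / m if m else np.nan
        )
    return out


def group_pipeline(
    counts: np.ndarray,
    properties: tuple[str, ...],
    method: str = "bh",
    alpha: float = 0.05,
) -> dict[str, float]:
    """Per-group pipeline returning the requested global properties.

    Properties outside the cheap set trigger a full graph build; the cheap
    ones (edge density, positive-edge percentage, edge count) are computed
    directly from the keep mask.
    """
    D = counts.shape[0]
    est, test = _keep_matrix(counts, method, alpha)
    wanted = set(properties)
    out = _fast_properties(test, D, wanted & _FAST_PROPERTIES)
    slow = wanted - _FAST_PROPERTIES
    if slow:
        net = build_network(est, test)
        props = global_properties(net).as_dict()
        for name in slow:
            if name not in props:
                raise KeyError(f"unknown network property {name!r}")
            val = props[name]
            out[name] = np.nan if val is None else float(val)
    return out


def _two_group_arrays(counts: pd.DataFrame, group_of: pd.Series):
    labels = list(pd.unique(group_of))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    mask = (group_of == labels[0]).to_numpy()
    return counts.to_numpy(), mask, labels


def property_difference_test(
    table: CountTable,
    config: PermutationConfig = PermutationConfig(),
) -> dict[str, PermutationResult]:
    """Permutation test of group differences in global network properties.

    Two-sided Monte-Carlo p-values with the +1 correction:
    ``p = (1 + #{|d_b| >= |d_obs|}) / (B + 1)``.  Permutations whose pipeline
    fails are excluded and counted; more than ``max_failure_fraction`` of
    failures aborts the test.
    """
    if table.group_of is None:
        raise ValueError("count table has no group labels")
    arr, mask_a, labels = _two_group_arrays(table.counts, table.group_of)
    rng = np.random.default_rng(config.seed)
    props = tuple(config.properties)

    def one(sub: np.ndarray) -> dict[str, float]:
        if config.refilter_per_permutation:
            from .preprocess import FilterConfig, filter_counts

            filtered, _ = filter_counts(
                CountTable(pd.DataFrame(sub)), FilterConfig(min_sample_depth=0)
            )
            sub = filtered.counts.to_numpy()
        return group_pipeline(sub, props, config.sparsify_method, config.sparsify_alpha)

    def both(mask):
        return one(arr[:, mask]), one(arr[:, ~mask])

    obs_a, obs_b = both(mask_a)
    observed = {p: obs_a[p] - obs_b[p] for p in props}

    null = {p: [] for p in props}
    n_failed = 0
    for b in range(config.n_permutations):
        perm = rng.permutation(mask_a)
        try:
            pa, pb = both(perm)
        except Exception:
            n_failed += 1
            if n_failed > config.max_failure_fraction * config.n_permutations:
                raise RuntimeError(
                    f"{n_failed} of {b + 1} permutations failed; aborting"
                )
            continue
        for p in props:
            null[p].append(pa[p] - pb[p])

    results = {}
    for p in props:
        diffs = np.asarray(null[p])
        valid = diffs[~np.isnan(diffs)]
        d_obs = observed[p]
        pval = (1 + np.sum(np.abs(valid) >= abs(d_obs))) / (valid.size + 1)
        results[p] = PermutationResult(
            property=p,
            observed=(obs_a[p], obs_b[p]),
            observed_diff=d_obs,
            null_diffs=diffs,
            p_value=float(pval),
            significant=pval <= config.alpha,
            n_failed=n_failed,
        )
    return results


def _group_centrality(counts: np.ndarray, genus_ids, method: str, alpha: float,
                      measure: str) -> pd.Series:
    est, test = _keep_matrix(np.asarray(counts), method, alpha)
    est.genus_ids = list(genus_ids)
    test.genus_ids = list(genus_ids)
    net = build_network(est, test)
    cent = centralities(net)
    # genera isolated in (or absent from) a permuted network contribute zero
    return cent[measure].reindex(genus_ids).fillna(0.0)


def centrality_difference_test(
    table: CountTable,
    config: PermutationConfig = PermutationConfig(),
    measure: str = "summed_mm",
) -> pd.DataFrame:
    """Per-genus permutation test on scaled centrality differences.

    Same machinery as the global test, applied to a per-genus centrality
    column (default: the summed min/max-scaled centrality).
    """
    if table.group_of is None:
        raise ValueError("count table has no group labels")
    arr, mask_a, labels = _two_group_arrays(table.counts, table.group_of)
    ids = list(table.counts.index)
    rng = np.random.default_rng(config.seed)

    def diff(mask) -> np.ndarray:
        ca = _group_centrality(arr[:, mask], ids, config.sparsify_method,
                               config.sparsify_alpha, measure)
        cb = _group_centrality(arr[:, ~mask], ids, config.sparsify_method,
                               config.sparsify_alpha, measure)
        return (ca - cb).to_numpy()

    d_obs = diff(mask_a)
    exceed = np.zeros(len(ids))
    n_valid = 0
    n_failed = 0
    for b in range(config.n_permutations):
        perm = rng.permutation(mask_a)
        try:
            d_b = diff(perm)
        except Exception:
            n_failed += 1
            if n_failed > config.max_failure_fraction * config.n_permutations:
                raise RuntimeError(f"{n_failed} of {b + 1} permutations failed; aborting")
            continue
        exceed += np.abs(d_b) >= np.abs(d_obs)
        n_valid += 1
    pvals = (1 + exceed) / (n_valid + 1)
    return pd.DataFrame(
        {
            "observed_diff": d_obs,
            "p_value": pvals,
            "significant": pvals <= config.alpha,
            "n_failed": n_failed,
        },
        index=ids,
    )
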