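"""File I/O, run configuration and the end-to-end orchestrator.

Formats are deliberately plain: TSV for tables (genera as rows, samples as
columns), GraphML for networks, JSON for property reports and the manifest.
Every artifact records the seed and a hash of the configuration so a run can
be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .centrality import (
    CoreComparison,
    centralities,
    compare_cores,
    core_def1,
    core_def2,
    hubs,
    jaccard_test,
)
from .graphlets import TERMINAL_ORBITS, count_orbits, gcm, gcm_difference, map_genera, select_orbits
from .network import build_network, fast_greedy_clusters, global_properties
from .permutation import PermutationConfig, property_difference_test
from .preprocess import (
    CountTable,
    FilterConfig,
    alpha_diversity,
    clr,
    compare_diversity,
    filter_counts,
    zero_replace,
)
from .sparcc import edge_significance, lfdr_adjust, sparcc

__all__ = ["RunConfig", "read_counts", "read_metadata", "write_counts", "run_comparison"]

log = logging.getLogger("taxonet")


@dataclass(frozen=True)
class RunConfig:
    """Everything one comparison run needs, in one place."""

    counts_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "taxonet_out"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    sparsify_method: str = "lfdr"
    sparsify_alpha: float = 0.05
    hub_quantile: float = 0.90
    core_detection: float = 0.001
    core_prevalence: float = 0.5
    graphlet_top_k: int = 25
    graphlet_alpha: float = 0.05
    n_permutations: int = 1000
    compare_properties: tuple[str, ...] = (
        "edge_density",
        "positive_edge_pct",
        "clustering_coefficient",
        "natural_connectivity",
    )
    run_property_test: bool = True

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")       # where results land does not change them
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        if "compare_properties" in raw:
            raw["compare_properties"] = tuple(raw["compare_properties"])
        return cls(filter=filt, **raw)


def read_counts(path: str | Path) -> CountTable:
    """Read a genus x sample TSV with integer validation.

    First column holds genus IDs, header row holds sample IDs.  Non-integer
    cells and duplicate IDs are rejected with coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate genus or sample IDs")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer cell {cell!r} at genus {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    return CountTable(pd.DataFrame(values, index=df.index, columns=df.columns))


def read_metadata(path: str | Path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError(f"{path}: metadata needs 'sample_id' and 'group' columns")
    return pd.Series(meta["group"].values, index=meta["sample_id"].values, name="group")


def write_counts(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="genus")


def _write_network(net, clusters, path: Path) -> None:
    g = net.graph.copy()
    for node in g.nodes:
        g.nodes[node]["genus"] = str(node)
        g.nodes[node]["cluster"] = int(clusters.cluster_of.get(node, -1))
    nx.write_graphml(g, path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_comparison(table: CountTable, config: RunConfig) -> dict:
    """Execute the full two-group pipeline and write all artifacts.

    Per group: filter, zero-replace, CLR, diversity, SparCC, sparsify, build
    network, cluster, global properties, centralities, hubs, both core
    definitions, orbit counts and GCM.  Across groups: GCM difference with
    orbit selection, terminal-node mapping, hub Jaccard test, and (optionally)
    the permutation test on global properties.  Returns the report bundle.
    """
    if table.group_of is None:
        raise ValueError("metadata with a group column is required")
    labels = list(pd.unique(table.group_of))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=outdir / "run.log", level=logging.INFO, force=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    manifest: dict[str, str] = {}
    bundle: dict = {"stamp": stamp, "groups": {}}

    def save_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(_jsonable({**stamp, **payload}), indent=2))
        manifest[name] = path.name

    def save_tsv(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        manifest[name] = path.name

    per_group: dict[str, dict] = {}
    for label in labels:
        log.info("group %s: preprocessing", label)
        sub = table.subset_group(label)
        filtered, report = filter_counts(sub, config.filter)
        comp = zero_replace(filtered)
        clr_mat = clr(comp)
        diversity = alpha_diversity(filtered)
        est = sparcc(comp)
        test = lfdr_adjust(edge_significance(est), alpha=config.sparsify_alpha,
                           method=config.sparsify_method)
        net = build_network(est, test, group_label=label)
        clusters = fast_greedy_clusters(net)
        props = global_properties(net, clusters)
        cent = centralities(net)
        hub_set = hubs(cent, config.hub_quantile)
        core1 = core_def1(filtered, config.core_detection, config.core_prevalence)
        core2 = core_def2(cent, target_count=max(len(core1.genera), 1))
        orbits = count_orbits(net)
        group_gcm = gcm(orbits)

        save_tsv(f"filtered_counts_{label}.tsv", filtered.counts, index_label="genus")
        save_tsv(f"clr_{label}.tsv", clr_mat, index_label="genus")
        save_tsv(f"diversity_{label}.tsv", diversity, index_label="sample")
        save_tsv(f"edges_{label}.tsv", test.frame(), index=False)
        save_tsv(f"correlations_{label}.tsv", est.rho_frame(), index_label="genus")
        save_tsv(f"centrality_{label}.tsv", cent, index_label="genus")
        save_tsv(f"orbits_{label}.tsv", orbits.counts, index_label="genus")
        save_tsv(f"gcm_{label}.tsv", group_gcm.spearman, index_label="orbit")
        _write_network(net, clusters, outdir / f"network_{label}.graphml")
        manifest[f"network_{label}.graphml"] = f"network_{label}.graphml"
        save_json(f"filter_report_{label}.json", dataclasses.asdict(report))
        save_json(f"global_properties_{label}.json", props.as_dict())
        save_json(
            f"cores_{label}.json",
            {
                "definition1": {"genera": sorted(core1.genera), "params": core1.params},
                "definition2": {
                    "genera": sorted(core2.genera),
                    "params": core2.params,
                    "warning": core2.warning,
                },
                "comparison": {
                    "definition1": (
                        dataclasses.asdict(compare_cores(core1, filtered, cent))
                        if core1.genera else None
                    ),
                    "definition2": (
                        dataclasses.asdict(compare_cores(core2, filtered, cent))
                        if core2.genera else None
                    ),
                },
            },
        )
        per_group[label] = {
            "filtered": filtered,
            "cent": cent,
            "hubs": hub_set,
            "orbits": orbits,
            "gcm": group_gcm,
            "props": props,
            "diversity": diversity,
        }
        bundle["groups"][label] = {
            "n_genera": filtered.counts.shape[0],
            "n_samples": filtered.counts.shape[1],
            "properties": props.as_dict(),
            "hubs": sorted(hub_set.genera),
        }

    a, b = labels
    diversity_all = pd.concat([per_group[a]["diversity"], per_group[b]["diversity"]])
    div_p = compare_diversity(diversity_all, table.group_of)

    universe = sorted(
        set(per_group[a]["cent"].index) | set(per_group[b]["cent"].index)
    )
    jac = jaccard_test(
        per_group[a]["hubs"].genera,
        per_group[b]["hubs"].genera,
        universe,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )

    diff = gcm_difference(per_group[a]["gcm"], per_group[b]["gcm"], alpha=config.graphlet_alpha)
    orbits_of_interest = select_orbits(diff) or list(TERMINAL_ORBITS)
    reports = {
        label: map_genera(per_group[label]["orbits"], orbits_of_interest, config.graphlet_top_k)
        for label in labels
    }
    focal = {label: set(r.focal.index[r.focal]) for label, r in reports.items()}
    terminal = {
        "orbits_of_interest": orbits_of_interest,
        "focal": {k: sorted(v) for k, v in focal.items()},
        f"exclusive_{a}": sorted(focal[a] - focal[b]),
        f"exclusive_{b}": sorted(focal[b] - focal[a]),
    }
    save_tsv(
        "terminal_nodes.tsv",
        pd.DataFrame(
            {
                f"occurrence_{label}": reports[label].occurrence.reindex(universe)
                for label in labels
            }
            | {f"focal_{label}": reports[label].focal.reindex(universe) for label in labels}
        ),
        index_label="genus",
    )
    save_tsv("gcm_difference.tsv", diff.table, index=False)

    comparison: dict = {
        "diversity_p": div_p.to_dict(),
        "hub_jaccard": dataclasses.asdict(jac),
        "terminal_nodes": terminal,
    }

    if config.run_property_test:
        # filters are applied once to the full dataset before permuting, so
        # the genus universe stays fixed across permutations
        joint, _ = filter_counts(table, config.filter)
        perm = property_difference_test(
            joint,
            PermutationConfig(
                n_permutations=config.n_permutations,
                seed=config.seed,
                properties=config.compare_properties,
                sparsify_method=config.sparsify_method,
                sparsify_alpha=config.sparsify_alpha,
            ),
        )
        comparison["property_tests"] = {
            name: {
                "observed": res.observed,
                "observed_diff": res.observed_diff,
                "p_value": res.p_value,
                "significant": res.significant,
            }
            for name, res in perm.items()
        }
    save_json("comparison.json", comparison)
    bundle["comparison"] = comparison

    save_json("manifest.json", {"artifacts": sorted(manifest)})
    return bundle
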