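import numpy as np
import pandas as pd
import pytest

from taxonet import CountTable
from taxonet.network import MicrobialNetwork
from taxonet.synth import BasisNetworkSpec, DepthLaw, generate_basis_correlation, sample_counts

import networkx as nx


def make_network(edges, nodes=None, group="g") -> MicrobialNetwork:
    """Small weighted network from (u, v, rho) triples."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, rho in edges:
        w = abs(rho)
        g.add_edge(u, v, rho=rho, weight=w, dissimilarity=1.0 - w)
    return MicrobialNetwork(graph=g, group_label=group)


@pytest.fixture(scope="session")
def planted_pair_dataset():
    """D=20 genera, one strongly correlated pair (0, 1), n=500 samples."""
    spec = BasisNetworkSpec(
        n_genera=20, n_modules=10, p_within=0.0, p_between=0.0,
        corr_magnitude_range=(0.8, 0.8), seed=5,
    )
    truth = generate_basis_correlation(spec)
    rho = truth.basis_correlation.copy()
    rho[0, 1] = rho[1, 0] = 0.8
    truth.basis_correlation = rho
    truth.true_edges = frozenset({(0, 1)})
    ds = sample_counts(
        truth, 500, mean_log_abundance=np.zeros(20),
        depth_law=DepthLaw(kind="constant", mean=20000), seed=6,
    )
    return ds, truth


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        [[4, 0, 10], [1, 5, 10], [1, 5, 10], [2, 0, 10]],
        index=list("abcd"),
        columns=["s1", "s2", "s3"],
    )
    return CountTable(counts)
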