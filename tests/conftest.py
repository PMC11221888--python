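import networkx as nx
import numpy as np
import pandas as pd
import pytest

from niee import BackgroundNetwork, prune_isolated_nodes, prune_leaf_edges


@pytest.fixture
def triangle_net() -> BackgroundNetwork:
    return BackgroundNetwork.from_edges(
        [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)]
    )


def random_instance(seed: int, n_genes: int | None = None, n_ref: int | None = None):
    """Seeded random analysis instance: pruned network + cohort + sample.

    Sizes stay small (≤ 50 genes, ≤ 150 edges, 8–12 reference samples);
    expression has mild network-independent structure (iid normal plus a
    shared latent factor) so correlations are non-trivial.
    """
    rng = np.random.default_rng(seed)
    n = int(n_genes or rng.integers(12, 51))
    n_s = int(n_ref or rng.integers(8, 13))
    p = min(1.0, 110.0 / (n * (n - 1) / 2))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g, {i: f"g{i:03d}" for i in range(n)})
        for u, v in g.edges:
            g.edges[u, v]["confidence"] = 0.9
        net = prune_leaf_edges(prune_isolated_nodes(BackgroundNetwork(g)))
        if 1 <= net.n_edges <= 150:
            break
    genes = net.sorted_nodes()
    latent = rng.standard_normal(n_s)
    loadings = rng.uniform(-1, 1, size=len(genes))
    values = rng.standard_normal((len(genes), n_s)) + np.outer(loadings, latent)
    reference = pd.DataFrame(
        values, index=genes, columns=[f"s{j}" for j in range(n_s)]
    )
    perturbed = pd.Series(
        rng.standard_normal(len(genes)) * rng.uniform(1, 3),
        index=genes,
        name="case",
    )
    return net, reference, perturbed


@pytest.fixture
def small_instance():
    return random_instance(seed=7, n_genes=12, n_ref=8)
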