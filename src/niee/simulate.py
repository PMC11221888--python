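"""Seeded synthetic networks and expression cohorts with a planted
pre-transition module.

The generator emulates the dynamic-network-biomarker signature: a small
module of genes whose expression variance and mutual correlation surge at
a designated tipping time while the rest of the network stays at
baseline.  Expression is drawn from a multivariate normal whose
correlation matrix follows the network (a baseline correlation on
adjacent gene pairs, ~0 elsewhere), which controls exactly the two
quantities the scoring method consumes — correlations and standard
deviations — without emulating platform-specific noise.

All randomness flows through one integer seed; every artifact is
bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    BackgroundNetwork,
    prune_isolated_nodes,
    prune_leaf_edges,
)

__all__ = [
    "SyntheticScenario",
    "make_network",
    "make_reference_cohort",
    "make_perturbed_series",
    "write_fixture_files",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale study: a 50-gene network with a
    5-gene module planted as a clique, a 17-sample reference cohort
    (the size of a typical published reference cohort for this class of
    method), ten perturbed time points with the tipping at the sixth,
    and a three-fold variance boost with strong (0.8) intra-module
    correlation after the tipping.
    """

    n_genes: int = 50
    network_model: str = "erdos_renyi"  # or "scale_free"
    edge_density: float = 0.12  # erdos_renyi edge probability
    attachment: int = 3  # scale_free: edges per new node
    n_reference: int = 17
    n_time_points: int = 10
    tipping_index: int = 5  # 0-based position of the tipping time point
    module_size: int = 5
    baseline_rho: float = 0.3  # correlation on adjacent gene pairs
    rho_boost: float = 0.8  # intra-module correlation at/after tipping
    sd_boost: float = 3.0  # module SD multiplier at/after tipping
    noise_sd: float = 1.0  # baseline per-gene SD
    seed: int = 0
    time_points: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.network_model not in ("erdos_renyi", "scale_free"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if self.network_model == "erdos_renyi" and not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        if self.n_reference < 3:
            raise ValueError(
                "n_reference must be >= 3 (minimum reference-cohort size)"
            )
        if not 2 <= self.module_size <= self.n_genes:
            raise ValueError("module_size must be in [2, n_genes]")
        if self.sd_boost < 1.0:
            raise ValueError("sd_boost must be >= 1 (a variance surge)")
        if not 0.0 <= self.rho_boost < 1.0:
            raise ValueError("rho_boost must be in [0, 1)")
        if not 0.0 <= self.baseline_rho < 1.0:
            raise ValueError("baseline_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.time_points:
            width = len(str(self.n_time_points))
            self.time_points = [
                f"t{i + 1:0{width}d}" for i in range(self.n_time_points)
            ]
        if len(self.time_points) != self.n_time_points:
            raise ValueError("time_points length must equal n_time_points")
        if not 0 <= self.tipping_index < self.n_time_points:
            raise ValueError("tipping_index must index a time point")

    @property
    def tipping_time(self) -> str:
        return self.time_points[self.tipping_index]

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def module_genes(scenario: SyntheticScenario) -> list[str]:
    """The planted module: the first ``module_size`` gene labels."""
    return _gene_labels(scenario.n_genes)[: scenario.module_size]


def make_network(scenario: SyntheticScenario) -> BackgroundNetwork:
    """Seeded random background network containing the planted module.

    The module genes are wired into a clique so their induced edges are
    guaranteed to survive pruning; the rest of the graph follows the
    chosen random-graph model.  Pruning matches the loader defaults
    (isolated nodes, then iterative leaf-edge removal).
    """
    rng = np.random.default_rng(scenario.seed)
    nx_seed = int(rng.integers(2**31 - 1))
    if scenario.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(scenario.n_genes, scenario.edge_density, seed=nx_seed)
    else:
        g = nx.barabasi_albert_graph(scenario.n_genes, scenario.attachment, seed=nx_seed)
    labels = _gene_labels(scenario.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(labels)))
    module = module_genes(scenario)
    for i, u in enumerate(module):
        for v in module[i + 1 :]:
            g.add_edge(u, v)
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = float(rng.uniform(0.85, 1.0))
    net = prune_isolated_nodes(BackgroundNetwork(g))
    net = prune_leaf_edges(net, iterative=True)
    if net.n_edges == 0:
        raise ValueError("scenario parameters admit no valid pruned network")
    missing = set(module) - net.nodes
    if missing:  # clique of size >= 3 always survives leaf pruning
        raise ValueError(f"module genes lost in pruning: {sorted(missing)}")
    return net


def _network_correlation(
    net: BackgroundNetwork, genes: list[str], rho: float
) -> np.ndarray:
    """Correlation matrix with ``rho`` on adjacent pairs, 0 elsewhere."""
    idx = {g: i for i, g in enumerate(genes)}
    c = np.eye(len(genes))
    for u, v in net.sorted_edges():
        if u in idx and v in idx:
            c[idx[u], idx[v]] = c[idx[v], idx[u]] = rho
    return c


def _nearest_pd_correlation(c: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to make ``c`` positive definite, re-unitise diag."""
    eigval, eigvec = np.linalg.eigh(c)
    if eigval.min() > 1e-8:
        return c
    warnings.warn(
        "target correlation matrix not positive definite; repairing by "
        "eigenvalue clipping"
    )
    eigval = np.clip(eigval, 1e-6, None)
    fixed = eigvec @ np.diag(eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _cholesky(c: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(_nearest_pd_correlation(c))


def make_reference_cohort(
    scenario: SyntheticScenario, net: BackgroundNetwork
) -> pd.DataFrame:
    """Reference samples from the network-structured baseline distribution.

    Genes × samples DataFrame over the pruned network's nodes; each
    sample is a multivariate-normal draw with per-gene SD ``noise_sd``
    and correlation ``baseline_rho`` on adjacent pairs.
    """
    genes = net.sorted_nodes()
    chol = _cholesky(_network_correlation(net, genes, scenario.baseline_rho))
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    z = rng.standard_normal((len(genes), scenario.n_reference))
    values = scenario.noise_sd * (chol @ z)
    samples = [f"ref{j + 1:02d}" for j in range(scenario.n_reference)]
    return pd.DataFrame(values, index=genes, columns=samples)


def make_perturbed_series(
    scenario: SyntheticScenario, net: BackgroundNetwork
) -> tuple[list[tuple[str, pd.Series]], dict]:
    """One perturbed sample per time point, plus the planted ground truth.

    Samples before the tipping index follow the reference distribution;
    at and after it the module genes' SD is multiplied by ``sd_boost``
    and their mutual correlation is raised to ``rho_boost``.  Returns the
    ``(label, gene-indexed vector)`` series and a ground-truth dict with
    the module genes, the module's internal edges in the pruned network,
    and the tipping index/label.
    """
    genes = net.sorted_nodes()
    idx = {g: i for i, g in enumerate(genes)}
    module = [g for g in module_genes(scenario) if g in idx]

    base_corr = _network_correlation(net, genes, scenario.baseline_rho)
    boost_corr = base_corr.copy()
    for i, u in enumerate(module):
        for v in module[i + 1 :]:
            boost_corr[idx[u], idx[v]] = boost_corr[idx[v], idx[u]] = scenario.rho_boost
    chol_base = _cholesky(base_corr)
    chol_boost = _cholesky(boost_corr)

    sds = np.full(len(genes), scenario.noise_sd)
    boosted_sds = sds.copy()
    boosted_sds[[idx[g] for g in module]] *= scenario.sd_boost

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    series: list[tuple[str, pd.Series]] = []
    for t, label in enumerate(scenario.time_points):
        z = rng.standard_normal(len(genes))
        if t < scenario.tipping_index:
            x = sds * (chol_base @ z)
        else:
            x = boosted_sds * (chol_boost @ z)
        series.append((label, pd.Series(x, index=genes, name=label)))

    module_edges = sorted(
        tuple(sorted((u, v)))
        for u, v in net.sorted_edges()
        if u in module and v in module
    )
    truth = {
        "module_genes": module,
        "module_edges": [list(e) for e in module_edges],
        "tipping_index": scenario.tipping_index,
        "tipping_time": scenario.tipping_time,
    }
    return series, truth


def write_fixture_files(scenario: SyntheticScenario, outdir: str | Path) -> dict:
    """Generate and write a complete fixture set; returns written paths.

    Outputs use exactly the formats the loaders consume: an edge-list
    TSV (unit-scale confidence), a reference genes × samples TSV, a
    perturbed genes × time-points TSV, a sample-metadata TSV, and the
    ground truth as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = make_network(scenario)
    reference = make_reference_cohort(scenario, net)
    series, truth = make_perturbed_series(scenario, net)

    paths = {
        "network": outdir / "network.tsv",
        "reference": outdir / "reference.tsv",
        "perturbed": outdir / "perturbed.tsv",
        "metadata": outdir / "samples.tsv",
        "truth": outdir / "ground_truth.json",
    }
    net.write_edges(paths["network"])
    reference.to_csv(paths["reference"], sep="\t", float_format="%.10g")
    perturbed = pd.DataFrame({label: vec for label, vec in series})
    perturbed.to_csv(paths["perturbed"], sep="\t", float_format="%.10g")
    with open(paths["metadata"], "w") as fh:
        fh.write("sample\tgroup\ttime\n")
        for col in reference.columns:
            fh.write(f"{col}\treference\t\n")
        for i, (label, _) in enumerate(series):
            fh.write(f"{label}\tperturbed\t{i}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
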