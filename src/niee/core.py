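"""Edge-entropy scoring of a perturbed sample against a reference cohort.

For every edge of the background network the method compares two
statistics computed once on the ``s`` reference samples and once on the
``s + 1`` samples obtained by appending the perturbed sample:

* a degree-weighted edge entropy ``H_E = α/(α+β)·H_g1 + β/(α+β)·H_g2``,
  where ``H_g`` is the normalised Shannon entropy of the gene's
  neighbour-correlation distribution — the absolute Pearson correlations
  between the gene and each of its ``M`` first-order neighbours,
  normalised to sum to one — divided by ``log M`` so that ``H_g ∈ [0, 1]``;
* a degree-weighted edge standard deviation ``SD_E`` built the same way
  from the two genes' sample standard deviations.

The differential score of an edge is
``ΔH_E = |SD_E(s+1) − SD_E(s)| · |H_E(s+1) − H_E(s)|``, and the global
score of a sample is the mean of ``ΔH_E`` over all edges.  Node weights
``α, β`` are the genes' degrees in the analysis network.

Degenerate cases are handled explicitly: the correlation of a
zero-variance gene is defined as 0 (a constant gene carries no
co-fluctuation signal), and if every neighbour correlation of a node is 0
its weight distribution falls back to uniform — the maximum-uncertainty
state, continuous with near-zero-correlation inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import BackgroundNetwork

__all__ = [
    "EdgeContext",
    "EdgeScoreRecord",
    "NieeResult",
    "pcc",
    "neighbor_weights",
    "node_entropy",
    "node_sd",
    "edge_context",
    "edge_entropy",
    "edge_sd",
    "differential_edge_score",
    "score_sample",
    "local_score",
]

_RECORD_COLUMNS = ["gene1", "gene2", "H_ref", "SD_ref", "H_pert", "SD_pert", "delta"]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class EdgeContext:
    """One edge's genes, degrees (= node weights) and neighbour lists."""

    gene1: str
    gene2: str
    alpha: int
    beta: int
    neighbors1: tuple[str, ...]
    neighbors2: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.gene2 not in self.neighbors1 or self.gene1 not in self.neighbors2:
            raise ValueError(
                f"({self.gene1}, {self.gene2}) is not a first-order adjacency "
                "of its own endpoints"
            )
        if len(self.neighbors1) < 2 or len(self.neighbors2) < 2:
            raise ValueError(
                "both endpoints need at least two first-order neighbours "
                "(prune leaf edges first)"
            )

    @property
    def M1(self) -> int:
        return len(self.neighbors1)

    @property
    def M2(self) -> int:
        return len(self.neighbors2)


@dataclass(frozen=True)
class EdgeScoreRecord:
    """Reference/perturbed entropy and SD of one edge, and their product score."""

    gene1: str
    gene2: str
    H_ref: float
    SD_ref: float
    H_pert: float
    SD_pert: float
    delta: float


@dataclass
class NieeResult:
    """All edge scores of one perturbed sample plus the global summary.

    ``records`` is a DataFrame with one row per analysis-network edge
    (lexicographic edge order) and columns ``gene1, gene2, H_ref, SD_ref,
    H_pert, SD_pert, delta``; ``global_score`` is the mean ``delta``.
    """

    sample: str
    records: pd.DataFrame
    global_score: float = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in _RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        if len(self.records) == 0:
            raise ValueError("a result needs at least one scored edge")
        self.global_score = float(self.records["delta"].to_numpy(dtype=float).mean())

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.records["gene1"], self.records["gene2"]))

    def delta_by_edge(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.edges, self.records["delta"].to_numpy()))

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.12g")

    def sidecar(self) -> dict:
        return {
            "sample": self.sample,
            "global_score": self.global_score,
            "n_edges": int(len(self.records)),
        }


# ---------------------------------------------------------------------------
# scalar building blocks


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation with the zero-variance-is-zero convention.

    Requires at least three points; a correlation over two points is
    always ±1 and carries no information.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise ValueError(f"need at least 3 samples, got {xa.size}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.sqrt((xc * xc).sum()) * np.sqrt((yc * yc).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def neighbor_weights(
    gene: str, neighbors: Sequence[str], expr: pd.DataFrame
) -> np.ndarray:
    """Normalised absolute neighbour correlations of one gene.

    Returns a probability vector over ``neighbors``: |PCC| between
    ``gene`` and each neighbour, normalised to sum to one.  If every
    correlation is zero the uniform vector is returned.
    """
    if len(neighbors) < 2:
        raise ValueError("need at least two neighbours")
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    missing = [n for n in neighbors if n not in expr.index]
    if missing:
        raise KeyError(f"neighbours absent from expression matrix: {missing}")
    x = expr.loc[gene].to_numpy(dtype=float)
    absc = np.array([abs(pcc(x, expr.loc[n].to_numpy(dtype=float))) for n in neighbors])
    total = absc.sum()
    if total == 0.0:
        return np.full(len(neighbors), 1.0 / len(neighbors))
    return absc / total


def node_entropy(weights: Sequence[float]) -> float:
    """Normalised Shannon entropy of a probability vector of length M ≥ 2.

    ``−(1/log M) Σ p log p`` with the ``0·log 0 := 0`` convention; the
    normalisation cancels the choice of log base, so the result is in
    [0, 1] with 1 for the uniform distribution.
    """
    w = np.asarray(weights, dtype=float)
    m = w.size
    if m < 2:
        raise ValueError(f"need at least 2 weights, got {m}")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a probability vector (sum 1, entries >= 0)")
    if np.all(w == w[0]):
        return 1.0  # uniform maximiser, exact regardless of rounding in p log p
    nz = w[w > 0]
    h = float(-(nz * np.log(nz)).sum() / np.log(m))
    return min(max(h, 0.0), 1.0)


def node_sd(gene: str, expr: pd.DataFrame) -> float:
    """Sample standard deviation (divisor s − 1) of one gene."""
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    x = expr.loc[gene].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    return float(np.std(x, ddof=1))


def edge_context(net: BackgroundNetwork, gene1: str, gene2: str) -> EdgeContext:
    """Assemble the neighbour lists and degree weights of one edge."""
    n1 = tuple(net.neighbors(gene1))
    n2 = tuple(net.neighbors(gene2))
    return EdgeContext(
        gene1=gene1,
        gene2=gene2,
        alpha=net.degree(gene1),
        beta=net.degree(gene2),
        neighbors1=n1,
        neighbors2=n2,
    )


def edge_entropy(ctx: EdgeContext, expr: pd.DataFrame) -> float:
    """Degree-weighted convex combination of the two endpoint entropies."""
    h1 = node_entropy(neighbor_weights(ctx.gene1, ctx.neighbors1, expr))
    h2 = node_entropy(neighbor_weights(ctx.gene2, ctx.neighbors2, expr))
    a, b = ctx.alpha, ctx.beta
    return (a * h1 + b * h2) / (a + b)


def edge_sd(ctx: EdgeContext, expr: pd.DataFrame) -> float:
    """Degree-weighted convex combination of the two endpoint SDs."""
    a, b = ctx.alpha, ctx.beta
    return (a * node_sd(ctx.gene1, expr) + b * node_sd(ctx.gene2, expr)) / (a + b)


def differential_edge_score(
    ctx: EdgeContext, reference: pd.DataFrame, perturbed: pd.Series
) -> EdgeScoreRecord:
    """Score one edge: |ΔSD| · |ΔH| between reference and appended sets."""
    from .expression import build_sample_set, validate_reference

    validate_reference(reference)
    appended = build_sample_set(reference, perturbed)
    h_ref = edge_entropy(ctx, reference)
    sd_ref = edge_sd(ctx, reference)
    h_pert = edge_entropy(ctx, appended)
    sd_pert = edge_sd(ctx, appended)
    return EdgeScoreRecord(
        gene1=ctx.gene1,
        gene2=ctx.gene2,
        H_ref=h_ref,
        SD_ref=sd_ref,
        H_pert=h_pert,
        SD_pert=sd_pert,
        delta=abs(sd_pert - sd_ref) * abs(h_pert - h_ref),
    )


# ---------------------------------------------------------------------------
# vectorised whole-network scoring


def _node_stats(
    values: np.ndarray,
    nbr_flat: np.ndarray,
    nbr_src: np.ndarray,
    nbr_start: np.ndarray,
    degrees: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node normalised entropy and sample SD over ``values`` (g × n).

    ``nbr_flat`` concatenates every node's sorted neighbour indices,
    ``nbr_src`` repeats the owning node per entry, ``nbr_start`` marks
    each node's slice start.  Vectorised equivalent of applying
    ``neighbor_weights`` + ``node_entropy`` + ``node_sd`` to every node.
    """
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    sd = values.std(axis=1, ddof=1)

    dots = np.einsum("ij,ij->i", centred[nbr_src], centred[nbr_flat])
    denom = norms[nbr_src] * norms[nbr_flat]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0.0, dots / denom, 0.0)
    absc = np.minimum(np.abs(corr), 1.0)

    sums = np.add.reduceat(absc, nbr_start)
    sums_per_entry = sums[nbr_src]
    w = np.where(
        sums_per_entry > 0.0,
        absc / np.where(sums_per_entry > 0.0, sums_per_entry, 1.0),
        1.0 / degrees[nbr_src],
    )
    plogp = np.where(w > 0.0, w * np.log(np.where(w > 0.0, w, 1.0)), 0.0)
    entropy = -np.add.reduceat(plogp, nbr_start) / np.log(degrees)
    return np.clip(entropy, 0.0, 1.0), sd


def score_sample(
    net: BackgroundNetwork,
    reference: pd.DataFrame,
    perturbed: pd.Series,
    label: str | None = None,
) -> NieeResult:
    """Score one perturbed sample over every edge of the analysis network.

    ``reference`` must cover every network node (align first with
    :func:`niee.expression.align_to_network`); ``perturbed`` is a
    gene-indexed vector covering the same genes.  Returns one record per
    edge in lexicographic order plus the global mean score.  Fully
    deterministic: fixed edge order, double precision throughout.
    """
    from .expression import validate_reference

    validate_reference(reference)
    genes = net.sorted_nodes()
    missing = [g for g in genes if g not in reference.index]
    if missing:
        raise KeyError(f"network genes absent from reference matrix: {missing}")
    missing_p = [g for g in genes if g not in perturbed.index]
    if missing_p:
        raise KeyError(f"network genes absent from perturbed sample: {missing_p}")

    gidx = {g: i for i, g in enumerate(genes)}
    degrees = np.array([net.degree(g) for g in genes], dtype=float)
    if degrees.min() < 2:
        raise ValueError(
            "every node needs degree >= 2 (run leaf pruning before scoring)"
        )

    nbr_lists = [[gidx[n] for n in net.neighbors(g)] for g in genes]
    nbr_flat = np.concatenate([np.asarray(l, dtype=int) for l in nbr_lists])
    nbr_src = np.repeat(np.arange(len(genes)), [len(l) for l in nbr_lists])
    nbr_start = np.concatenate(([0], np.cumsum([len(l) for l in nbr_lists])[:-1]))

    ref_vals = reference.loc[genes].to_numpy(dtype=float)
    pert_col = perturbed.reindex(genes).to_numpy(dtype=float)
    all_vals = np.column_stack([ref_vals, pert_col])

    h_ref, sd_ref = _node_stats(ref_vals, nbr_flat, nbr_src, nbr_start, degrees)
    h_pert, sd_pert = _node_stats(all_vals, nbr_flat, nbr_src, nbr_start, degrees)

    edges = net.sorted_edges()
    i1 = np.array([gidx[u] for u, _ in edges], dtype=int)
    i2 = np.array([gidx[v] for _, v in edges], dtype=int)
    a = degrees[i1]
    b = degrees[i2]
    wsum = a + b
    e_h_ref = (a * h_ref[i1] + b * h_ref[i2]) / wsum
    e_h_pert = (a * h_pert[i1] + b * h_pert[i2]) / wsum
    e_sd_ref = (a * sd_ref[i1] + b * sd_ref[i2]) / wsum
    e_sd_pert = (a * sd_pert[i1] + b * sd_pert[i2]) / wsum
    delta = np.abs(e_sd_pert - e_sd_ref) * np.abs(e_h_pert - e_h_ref)

    records = pd.DataFrame(
        {
            "gene1": [u for u, _ in edges],
            "gene2": [v for _, v in edges],
            "H_ref": e_h_ref,
            "SD_ref": e_sd_ref,
            "H_pert": e_h_pert,
            "SD_pert": e_sd_pert,
            "delta": delta,
        }
    )
    if label is None:
        label = str(perturbed.name) if perturbed.name is not None else "perturbed"
    return NieeResult(sample=label, records=records)


def local_score(
    result: NieeResult,
    edge_subset: Iterable[tuple[str, str]],
    reduction: str = "mean",
) -> float:
    """Aggregate ``delta`` over a subset of edges (the local network score).

    ``reduction="mean"`` averages over the subset; ``"sum"`` adds the
    scores instead.  The two differ only by the constant subset size and
    rank samples identically for a fixed subset.  Over the full edge set
    the mean reduction equals :attr:`NieeResult.global_score` exactly.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    subset = [tuple(sorted(e)) for e in edge_subset]
    if not subset:
        raise ValueError("edge subset must be non-empty")
    by_edge = result.delta_by_edge()
    unknown = [e for e in subset if e not in by_edge]
    if unknown:
        raise KeyError(f"edges not in the scored network: {unknown}")
    # fixed lexicographic summation order for bit-reproducibility
    deltas = np.array([by_edge[e] for e in sorted(set(subset))], dtype=float)
    return float(deltas.mean() if reduction == "mean" else deltas.sum())
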