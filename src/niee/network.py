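"""Background protein–protein interaction network handling.

The entropy scores are computed over an externally supplied background
network (e.g. STRING protein links).  Edges are kept only above a
confidence threshold, isolated nodes are dropped, and edges incident to
degree-one nodes are pruned away: the normalised node entropy divides by
``log M`` for a node with ``M`` first-order neighbours, so every node that
enters the computation must keep at least two neighbours.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "BackgroundNetwork",
    "load_edge_list",
    "prune_isolated_nodes",
    "prune_leaf_edges",
    "build_background_network",
]

_SPLIT = re.compile(r"[,\t;]|\s+")


class BackgroundNetwork:
    """Undirected gene graph with per-edge confidence scores.

    Thin wrapper around :class:`networkx.Graph` that enforces the
    invariants the scoring code relies on (no self-loops, confidence in
    [0, 1]) and provides deterministic, lexicographically ordered node and
    edge views.

    Parameters
    ----------
    graph
        Undirected graph whose edges carry a ``confidence`` attribute in
        [0, 1].  The graph is used as-is (not copied).
    """

    def __init__(self, graph: nx.Graph) -> None:
        for u, v in graph.edges():
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
        for u, v, c in graph.edges(data="confidence", default=1.0):
            if not (0.0 <= c <= 1.0):
                raise ValueError(
                    f"edge ({u!r}, {v!r}) has confidence {c} outside [0, 1]"
                )
        self._g = graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]] | Iterable[tuple[str, str]]
    ) -> "BackgroundNetwork":
        """Build a network from ``(gene1, gene2[, confidence])`` tuples."""
        g = nx.Graph()
        for edge in edges:
            if len(edge) == 2:
                u, v = edge  # type: ignore[misc]
                c = 1.0
            else:
                u, v, c = edge  # type: ignore[misc]
            g.add_edge(str(u), str(v), confidence=float(c))
        return cls(g)

    # -- views ---------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted 2-tuples (orientation-free representation)."""
        return {tuple(sorted((u, v))) for u, v in self._g.edges}

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        """All edges as sorted tuples, in lexicographic order."""
        return sorted(tuple(sorted((u, v))) for u, v in self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._g.nodes))

    def degree(self, gene: str) -> int:
        if gene not in self._g:
            raise KeyError(f"gene {gene!r} is not in the network")
        return self._g.degree[gene]

    def degrees(self) -> dict[str, int]:
        return {g: self._g.degree[g] for g in self._g.nodes}

    def neighbors(self, gene: str) -> list[str]:
        """First-order neighbours of ``gene`` in lexicographic order."""
        if gene not in self._g:
            raise KeyError(f"gene {gene!r} is not in the network")
        return sorted(self._g.neighbors(gene))

    def confidence(self, gene1: str, gene2: str) -> float:
        if not self._g.has_edge(gene1, gene2):
            raise KeyError(f"edge ({gene1!r}, {gene2!r}) is not in the network")
        return self._g.edges[gene1, gene2].get("confidence", 1.0)

    def copy(self) -> "BackgroundNetwork":
        return BackgroundNetwork(self._g.copy())

    def induced_subgraph(self, genes: Iterable[str]) -> "BackgroundNetwork":
        """Subgraph induced by ``genes`` (unknown genes silently ignored)."""
        keep = set(genes) & set(self._g.nodes)
        return BackgroundNetwork(nx.Graph(self._g.subgraph(keep)))

    # -- I/O -----------------------------------------------------------

    def write_edges(self, path: str | Path) -> None:
        """Write a three-column TSV: gene1, gene2, confidence."""
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tconfidence\n")
            for u, v in self.sorted_edges():
                fh.write(f"{u}\t{v}\t{self.confidence(u, v):.6g}\n")

    def write_degrees(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tdegree\n")
            for g in self.sorted_nodes():
                fh.write(f"{g}\t{self._g.degree[g]}\n")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BackgroundNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def load_edge_list(
    path: str | Path,
    threshold: float = 0.85,
    score_scale: str = "thousand",
) -> BackgroundNetwork:
    """Load a confidence-filtered edge list.

    Accepts the STRING protein-links dialect natively: a whitespace- (or
    comma/tab-) delimited table with at least three columns ``node1 node2
    score``, optionally preceded by a header row.  Duplicate pairs in
    either orientation collapse to the maximum score; self-loops are
    dropped; edges below ``threshold`` (on the [0, 1] scale) are excluded.

    Parameters
    ----------
    path
        Edge-list file.
    threshold
        Minimum confidence, on the unit scale, for an edge to be retained.
    score_scale
        ``"thousand"`` for STRING's native integer scores 0–1000,
        ``"unit"`` for scores already in [0, 1].

    Raises
    ------
    ValueError
        For malformed rows (with the offending line number), out-of-range
        parameters, or an empty post-filter network.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if score_scale not in ("unit", "thousand"):
        raise ValueError(f"score_scale must be 'unit' or 'thousand', got {score_scale!r}")
    divisor = 1000.0 if score_scale == "thousand" else 1.0

    best: dict[tuple[str, str], float] = {}
    seen_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 columns "
                    f"(node1, node2, score), got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError:
                if not seen_data:
                    continue  # header row
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
            seen_data = True
            u, v = fields[0], fields[1]
            conf = score / divisor
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {fields[2]} outside the "
                    f"{score_scale!r} scale range"
                )
            if u == v:
                continue
            key = (u, v) if u < v else (v, u)
            if conf > best.get(key, -1.0):
                best[key] = conf

    kept = [(u, v, c) for (u, v), c in best.items() if c >= threshold]
    if not kept:
        raise ValueError(
            f"empty network: no edges with confidence >= {threshold} in {path}"
        )
    return BackgroundNetwork.from_edges(kept)


def prune_isolated_nodes(net: BackgroundNetwork) -> BackgroundNetwork:
    """Remove all degree-0 nodes; edges are unchanged."""
    g = net.graph.copy()
    g.remove_nodes_from(list(nx.isolates(g)))
    return BackgroundNetwork(g)


def prune_leaf_edges(net: BackgroundNetwork, iterative: bool = True) -> BackgroundNetwork:
    """Remove edges incident to degree-1 nodes.

    With ``iterative=True`` (the default) the pass repeats until no
    degree-1 node remains, so every surviving node has at least two
    first-order neighbours; a single pass may itself create new leaves.
    Nodes left with degree 0 by the removal are dropped too.
    """
    g = net.graph.copy()
    while True:
        leaves = [n for n in g.nodes if g.degree[n] == 1]
        if not leaves:
            break
        g.remove_edges_from([(n, next(iter(g.neighbors(n)))) for n in leaves])
        g.remove_nodes_from(list(nx.isolates(g)))
        if not iterative:
            break
    return BackgroundNetwork(g)


def build_background_network(
    path: str | Path,
    threshold: float = 0.85,
    score_scale: str = "thousand",
    prune_leaves: bool = True,
    iterative: bool = True,
) -> BackgroundNetwork:
    """Load, confidence-filter and fully prune a background network."""
    net = load_edge_list(path, threshold=threshold, score_scale=score_scale)
    net = prune_isolated_nodes(net)
    if prune_leaves:
        net = prune_leaf_edges(net, iterative=iterative)
    return net
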