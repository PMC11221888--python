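"""Key-local-network screening, score trajectories and early-warning flags.

Across a series of perturbed samples, the edges that repeatedly reach the
top fraction of differential scores form the *key local network* — the
candidate dynamic network biomarker.  This module screens those edges,
tracks local/global score trajectories over time points or stages,
exports the plot-ready edge × time "landscape" matrix, and flags
trajectory positions whose score jumps above the running history.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NieeResult, local_score
from .network import BackgroundNetwork

__all__ = [
    "KeyLocalNetwork",
    "ScoreTrajectory",
    "top_fraction_edges",
    "select_key_network",
    "trajectory",
    "grouped_trajectory",
    "detect_signals",
    "landscape_matrix",
    "self_forming_subgraph",
]


@dataclass
class KeyLocalNetwork:
    """Screened edge set with per-edge occurrence counts.

    ``frequency[e]`` is the number of perturbed samples in which edge
    ``e`` reached the top fraction of differential scores; only edges
    with frequency ≥ ``min_frequency`` are retained.
    """

    edges: list[tuple[str, str]]
    frequency: dict[tuple[str, str], int]
    top_fraction: float
    min_frequency: int

    def __post_init__(self) -> None:
        self.edges = sorted(tuple(sorted(e)) for e in self.edges)
        if any(self.frequency[e] < self.min_frequency for e in self.edges):
            raise ValueError("an edge with frequency below min_frequency was kept")

    def __len__(self) -> int:
        return len(self.edges)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tfrequency\n")
            for g1, g2 in self.edges:
                fh.write(f"{g1}\t{g2}\t{self.frequency[(g1, g2)]}\n")


@dataclass
class ScoreTrajectory:
    """Per-label summary scores, optionally with early-warning flags.

    Flags at position ``t`` are computed only from values at positions
    < ``t`` (strictly causal, no look-ahead).
    """

    labels: list[str]
    values: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values must have the same length")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.size != self.values.size:
                raise ValueError("flags and values must have the same length")

    @property
    def first_signal(self) -> int | None:
        """Index of the first flagged position, or None if never flagged."""
        if self.flags is None or not self.flags.any():
            return None
        return int(np.argmax(self.flags))

    def write_tsv(self, path: str | Path) -> None:
        flags = (
            self.flags if self.flags is not None else np.zeros(self.values.size, bool)
        )
        with open(path, "w") as fh:
            fh.write("label\tscore\tflag\n")
            for lab, v, f in zip(self.labels, self.values, flags):
                fh.write(f"{lab}\t{v:.12g}\t{int(f)}\n")


def top_fraction_edges(
    result: NieeResult, fraction: float = 0.01
) -> set[tuple[str, str]]:
    """Edges with the ``⌈fraction · WG⌉`` largest differential scores.

    Ties at the cutoff value are all included, which makes the selection
    deterministic and independent of record storage order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    deltas = result.records["delta"].to_numpy(dtype=float)
    k = math.ceil(fraction * deltas.size)
    cutoff = np.sort(deltas)[::-1][k - 1]
    keep = deltas >= cutoff
    return {
        (g1, g2)
        for g1, g2, m in zip(result.records["gene1"], result.records["gene2"], keep)
        if m
    }


def select_key_network(
    per_sample_top_sets: Sequence[set[tuple[str, str]]],
    min_frequency: int | None = None,
    top_fraction: float = 0.01,
) -> KeyLocalNetwork:
    """Keep edges that reach the top fraction in enough perturbed samples.

    ``min_frequency`` defaults to half the number of samples, rounded up.
    """
    n = len(per_sample_top_sets)
    if n == 0:
        raise ValueError("need at least one per-sample top set")
    if min_frequency is None:
        min_frequency = math.ceil(n / 2)
    if min_frequency < 1:
        raise ValueError("min_frequency must be a positive integer")
    if min_frequency > n:
        raise ValueError(
            f"min_frequency={min_frequency} exceeds the number of samples ({n})"
        )
    counts: dict[tuple[str, str], int] = {}
    for top in per_sample_top_sets:
        for e in top:
            key = tuple(sorted(e))
            counts[key] = counts.get(key, 0) + 1
    kept = sorted(e for e, c in counts.items() if c >= min_frequency)
    return KeyLocalNetwork(
        edges=kept,
        frequency={e: counts[e] for e in kept},
        top_fraction=top_fraction,
        min_frequency=min_frequency,
    )


def _score_of(result: NieeResult, key: KeyLocalNetwork | None, reduction: str) -> float:
    if key is None:
        if reduction == "mean":
            return result.global_score
        return local_score(result, result.edges, reduction=reduction)
    return local_score(result, key.edges, reduction=reduction)


def trajectory(
    results: Sequence[NieeResult],
    key: KeyLocalNetwork | None = None,
    reduction: str = "mean",
) -> ScoreTrajectory:
    """Per-sample local (over ``key``) or global (``key=None``) scores."""
    if not results:
        raise ValueError("need at least one result")
    labels = [r.sample for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels in trajectory: {labels}")
    values = np.array([_score_of(r, key, reduction) for r in results])
    return ScoreTrajectory(labels=labels, values=values)


def grouped_trajectory(
    results: Sequence[NieeResult],
    groups: Mapping[str, str],
    group_order: Sequence[str],
    key: KeyLocalNetwork | None = None,
    reduction: str = "mean",
) -> ScoreTrajectory:
    """Stage-wise trajectory: mean per-sample score within each group.

    Used when perturbed samples carry stage labels rather than individual
    time points (e.g. tumour stages); ``group_order`` fixes the stage
    progression explicitly.
    """
    unassigned = [r.sample for r in results if r.sample not in groups]
    if unassigned:
        raise ValueError(f"samples without a group assignment: {unassigned}")
    unknown = sorted({groups[r.sample] for r in results} - set(group_order))
    if unknown:
        raise ValueError(f"groups missing from group_order: {unknown}")
    per_group: dict[str, list[float]] = {g: [] for g in group_order}
    for r in results:
        per_group[groups[r.sample]].append(_score_of(r, key, reduction))
    empty = [g for g in group_order if not per_group[g]]
    if empty:
        raise ValueError(f"groups with no samples: {empty}")
    values = np.array([float(np.mean(per_group[g])) for g in group_order])
    return ScoreTrajectory(labels=list(group_order), values=values)


def detect_signals(
    traj: ScoreTrajectory, k: float = 2.0, min_history: int = 3
) -> ScoreTrajectory:
    """Flag positions whose score jumps above the running history.

    Position ``t`` (0-based) is flagged iff ``t >= min_history`` and
    ``value[t] > mean(values[:t]) + k · sd(values[:t])`` (sample SD,
    zero when the history has fewer than two distinct values' worth of
    spread).  Strictly causal: truncating the trajectory never changes
    earlier flags.  ``k`` and ``min_history`` are conventions of this
    implementation, not quantities with canonical values.
    """
    if k <= 0 or min_history < 1:
        raise ValueError("k must be > 0 and min_history >= 1")
    n = traj.values.size
    if n < min_history + 1:
        raise ValueError(
            f"trajectory of length {n} is too short for min_history={min_history}"
        )
    flags = np.zeros(n, dtype=bool)
    for t in range(min_history, n):
        hist = traj.values[:t]
        sd = float(np.std(hist, ddof=1)) if hist.size > 1 else 0.0
        flags[t] = traj.values[t] > float(hist.mean()) + k * sd
    return ScoreTrajectory(labels=list(traj.labels), values=traj.values, flags=flags)


def landscape_matrix(
    results: Sequence[NieeResult], key: KeyLocalNetwork
) -> pd.DataFrame:
    """Edge × sample matrix of differential scores for landscape plots.

    Rows are the key edges (lexicographic, labelled ``gene1--gene2``),
    columns the sample labels in input order.
    """
    if len(key) == 0:
        warnings.warn("key local network is empty; landscape matrix is empty")
        return pd.DataFrame(columns=[r.sample for r in results])
    data = {}
    for r in results:
        by_edge = r.delta_by_edge()
        missing = [e for e in key.edges if e not in by_edge]
        if missing:
            raise KeyError(
                f"sample {r.sample!r} lacks scores for key edges {missing}"
            )
        data[r.sample] = [by_edge[e] for e in key.edges]
    return pd.DataFrame(data, index=[f"{g1}--{g2}" for g1, g2 in key.edges])


def self_forming_subgraph(key: KeyLocalNetwork) -> BackgroundNetwork:
    """The graph induced by exactly the key edges (no pruning applied).

    Key edges often assemble spontaneously into connected sub-networks,
    but isolated edges are allowed and preserved.
    """
    if len(key) == 0:
        raise ValueError("key local network is empty")
    return BackgroundNetwork.from_edges([(g1, g2, 1.0) for g1, g2 in key.edges])
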