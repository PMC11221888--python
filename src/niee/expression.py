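"""Expression-matrix loading and reconciliation with the background network.

An expression matrix is represented as a :class:`pandas.DataFrame` with
gene identifiers on the index and sample labels on the columns (genes ×
samples).  Values are assumed pre-processed (normalised / log-transformed
as appropriate for the platform); this module does no normalisation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BackgroundNetwork, prune_isolated_nodes, prune_leaf_edges

__all__ = [
    "MIN_REFERENCE_SAMPLES",
    "RECOMMENDED_REFERENCE_SAMPLES",
    "load_expression_matrix",
    "load_sample_metadata",
    "validate_reference",
    "align_to_network",
    "build_sample_set",
]

#: Hard minimum cohort size: Pearson correlation over fewer than three
#: points is degenerate (always ±1 or undefined).
MIN_REFERENCE_SAMPLES = 3
#: Below this size a warning is emitted: correlation estimates over very
#: few samples are extremely noisy.
RECOMMENDED_REFERENCE_SAMPLES = 8


def load_expression_matrix(
    path: str | Path,
    missing_policy: str = "error",
    transpose: bool = False,
) -> pd.DataFrame:
    """Read a delimited genes × samples table.

    The first column holds gene identifiers and the header row holds
    sample labels.  Delimiter (TSV/CSV) is sniffed.  Set
    ``transpose=True`` only if the file is samples × genes; the
    orientation is never guessed.

    Parameters
    ----------
    missing_policy
        ``"error"`` rejects any missing/non-numeric cell, ``"drop_gene"``
        drops genes with any missing value, ``"impute_row_mean"`` fills
        missing cells with the gene's row mean.
    """
    if missing_policy not in ("error", "drop_gene", "impute_row_mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty expression table in {path}")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene identifiers: {dup_genes}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample labels: {dup_samples}")

    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        if missing_policy == "error":
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing or non-numeric values in genes {bad} "
                "(missing_policy='error')"
            )
        if missing_policy == "drop_gene":
            df = df.dropna(axis=0)
            if df.empty:
                raise ValueError("all genes dropped by missing_policy='drop_gene'")
        else:  # impute_row_mean
            means = df.mean(axis=1)
            if means.isna().any():
                bad = df.index[means.isna()].tolist()
                raise ValueError(f"genes with no numeric values at all: {bad}")
            df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
    return df.astype(float)


def load_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata table (columns: sample, group, [time/stage])."""
    meta = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError("sample metadata must contain a 'sample' column")
    if meta["sample"].duplicated().any():
        dups = meta["sample"][meta["sample"].duplicated()].tolist()
        raise ValueError(f"duplicate sample labels in metadata: {dups}")
    return meta.set_index("sample")


def validate_reference(reference: pd.DataFrame) -> None:
    """Enforce the minimum reference-cohort size (warn when small)."""
    s = reference.shape[1]
    if s < MIN_REFERENCE_SAMPLES:
        raise ValueError(
            f"reference cohort has {s} samples; at least "
            f"{MIN_REFERENCE_SAMPLES} are required for a non-degenerate "
            "Pearson correlation"
        )
    if s < RECOMMENDED_REFERENCE_SAMPLES:
        warnings.warn(
            f"reference cohort has only {s} samples; correlation estimates "
            f"will be noisy (recommended >= {RECOMMENDED_REFERENCE_SAMPLES})",
            UserWarning,
            stacklevel=2,
        )


def align_to_network(
    expr: pd.DataFrame,
    net: BackgroundNetwork,
    prune_leaves: bool = True,
    iterative: bool = True,
) -> tuple[pd.DataFrame, BackgroundNetwork]:
    """Restrict expression and network to their common genes.

    The network is reduced to the subgraph induced by the shared genes and
    then re-pruned (isolated nodes, then leaf edges with the same settings
    used to build it), so the minimum-degree guarantee still holds; the
    expression matrix is restricted to the surviving network nodes, in
    lexicographic gene order.  The operation is idempotent.
    """
    common = set(expr.index) & net.nodes
    if not common:
        raise ValueError(
            "empty intersection between expression genes and network nodes"
        )
    sub = net.induced_subgraph(common)
    sub = prune_isolated_nodes(sub)
    if prune_leaves:
        sub = prune_leaf_edges(sub, iterative=iterative)
    if sub.n_edges == 0:
        raise ValueError(
            "empty network after aligning to the expression matrix and "
            "re-pruning; the shared genes induce no usable edges"
        )
    genes = sub.sorted_nodes()
    return expr.loc[genes], sub


def build_sample_set(reference: pd.DataFrame, perturbed: pd.Series) -> pd.DataFrame:
    """Append one perturbed sample to the reference cohort.

    Returns the (s + 1)-column matrix used for the perturbed-side
    statistics: reference columns in their original order, the perturbed
    sample last.  Reference values are never mutated.
    """
    missing = set(reference.index) - set(perturbed.index)
    extra = set(perturbed.index) - set(reference.index)
    if missing or extra:
        raise ValueError(
            "perturbed sample genes do not match the reference: "
            f"missing={sorted(missing)} extra={sorted(extra)}"
        )
    label = perturbed.name if perturbed.name is not None else "perturbed"
    col = perturbed.reindex(reference.index).astype(float)
    out = reference.copy()
    out[label] = np.asarray(col)
    return out
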