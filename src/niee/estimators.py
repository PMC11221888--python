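"""Scikit-learn-style estimators wrapping the edge-entropy scoring.

``NieeScorer`` follows the novelty-scoring estimator shape: ``fit`` on
the reference cohort, then ``transform`` perturbed samples into a
per-sample × per-edge matrix of differential scores and ``score_samples``
into per-sample global scores.  ``KeyNetworkSelector`` is a transformer
that screens the recurrently top-scoring edge columns.  Both follow the
scikit-learn parameter and fitted-attribute conventions and compose with
``sklearn.pipeline.Pipeline``.

Estimator inputs are samples × genes/edges DataFrames (the scikit-learn
orientation); the functional core underneath uses the genomics
orientation (genes × samples) and the estimators transpose at the
boundary.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import NieeResult, score_sample
from .expression import align_to_network, validate_reference
from .keynet import (
    KeyLocalNetwork,
    select_key_network,
)
from .network import BackgroundNetwork

__all__ = ["NieeScorer", "KeyNetworkSelector"]


def _edge_label(g1: str, g2: str) -> str:
    return f"{g1}--{g2}"


class NieeScorer(TransformerMixin, BaseEstimator):
    """Edge-entropy perturbation scorer against a reference cohort.

    Parameters
    ----------
    network : BackgroundNetwork
        Confidence-filtered background network; it is aligned to the
        fitted genes (induced subgraph, re-pruned) during ``fit``.
    prune_leaves : bool, default=True
        Iteratively remove leaf edges when aligning, guaranteeing every
        node at least two neighbours.

    Attributes
    ----------
    network_ : BackgroundNetwork
        The pruned analysis network actually scored.
    reference_ : pandas.DataFrame
        Aligned reference matrix, genes × samples.
    genes_ : list of str
        Analysis genes in lexicographic order.
    edge_labels_ : list of str
        ``"gene1--gene2"`` labels of the scored edges, lexicographic;
        these are the columns of ``transform`` output.

    Examples
    --------
    >>> scorer = NieeScorer(network=net).fit(reference_samples_by_gene)
    >>> deltas = scorer.transform(case_samples_by_gene)   # samples × edges
    >>> global_scores = scorer.score_samples(case_samples_by_gene)
    """

    def __init__(self, network: BackgroundNetwork | None = None, prune_leaves: bool = True):
        self.network = network
        self.prune_leaves = prune_leaves

    def _as_samples_by_genes(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a samples × genes DataFrame (gene names are required)"
            )
        vals = X.to_numpy()
        if vals.dtype == object or not np.issubdtype(np.asarray(vals, float).dtype, np.floating):
            raise ValueError("X must be numeric")
        if np.isnan(np.asarray(vals, dtype=float)).any():
            raise ValueError("X contains missing values")
        return X.astype(float)

    def fit(self, X, y=None):
        """Fit on the reference cohort (samples × genes DataFrame)."""
        if self.network is None:
            raise ValueError("NieeScorer requires a background network")
        X = self._as_samples_by_genes(X)
        reference = X.T  # genes × samples
        reference.index = reference.index.astype(str)
        validate_reference(reference)
        self.reference_, self.network_ = align_to_network(
            reference, self.network, prune_leaves=self.prune_leaves
        )
        self.genes_ = self.network_.sorted_nodes()
        self.edge_labels_ = [
            _edge_label(g1, g2) for g1, g2 in self.network_.sorted_edges()
        ]
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def score_results(self, X) -> list[NieeResult]:
        """Full per-edge results, one :class:`NieeResult` per row of X."""
        check_is_fitted(self, "network_")
        X = self._as_samples_by_genes(X)
        missing = set(self.genes_) - set(map(str, X.columns))
        if missing:
            raise KeyError(f"analysis genes absent from X: {sorted(missing)}")
        results = []
        for label, row in X.iterrows():
            vec = pd.Series(
                row.reindex(self.genes_).to_numpy(dtype=float),
                index=self.genes_,
                name=str(label),
            )
            results.append(
                score_sample(self.network_, self.reference_, vec, label=str(label))
            )
        return results

    def transform(self, X) -> pd.DataFrame:
        """Per-edge differential scores: samples × edges DataFrame."""
        results = self.score_results(X)
        return pd.DataFrame(
            [r.records["delta"].to_numpy() for r in results],
            index=[r.sample for r in results],
            columns=self.edge_labels_,
        )

    def score_samples(self, X) -> np.ndarray:
        """Global differential score (mean over all edges) per sample."""
        return np.array([r.global_score for r in self.score_results(X)])

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.non_deterministic = False
        tags.input_tags.allow_nan = False
        return tags


class KeyNetworkSelector(TransformerMixin, BaseEstimator):
    """Select edges that recur in the top score fraction across samples.

    Operates on the samples × edges matrix produced by
    :meth:`NieeScorer.transform`: per sample, the top ``top_fraction`` of
    edge scores (ties included) are collected, and edges occurring in at
    least ``min_frequency`` samples are kept.

    Parameters
    ----------
    top_fraction : float, default=0.01
        Fraction of edges screened per sample (ceil, ties included).
    min_frequency : int or None, default=None
        Occurrence threshold; ``None`` means half the samples, rounded up.

    Attributes
    ----------
    key_network_ : KeyLocalNetwork
        The screened edge set with occurrence counts.
    selected_columns_ : list of str
        Edge column labels retained by ``transform``.
    """

    def __init__(self, top_fraction: float = 0.01, min_frequency: int | None = None):
        self.top_fraction = top_fraction
        self.min_frequency = min_frequency

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be the samples × edges DataFrame of delta scores")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        deltas = X.to_numpy(dtype=float)
        n_samples, n_edges = deltas.shape
        if n_edges == 0 or n_samples == 0:
            raise ValueError("need at least one sample and one edge")
        k = math.ceil(self.top_fraction * n_edges)
        top_sets = []
        for i in range(n_samples):
            row = deltas[i]
            cutoff = np.sort(row)[::-1][k - 1]
            top_sets.append(
                {tuple(c.split("--", 1)) for c in X.columns[row >= cutoff]}
            )
        self.key_network_: KeyLocalNetwork = select_key_network(
            top_sets, min_frequency=self.min_frequency, top_fraction=self.top_fraction
        )
        self.selected_columns_ = [
            _edge_label(g1, g2) for g1, g2 in self.key_network_.edges
        ]
        self.n_features_in_ = n_edges
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Restrict the edge-score matrix to the key-network columns."""
        check_is_fitted(self, "key_network_")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be the samples × edges DataFrame of delta scores")
        missing = [c for c in self.selected_columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"key-network columns absent from X: {missing}")
        return X[self.selected_columns_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "key_network_")
        return np.asarray(self.selected_columns_, dtype=object)
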