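"""Deliberately naive, loop-based transcription of the scoring equations.

Independent oracle for the production scoring path: explicit Python
loops, ``math``/``statistics`` from the standard library, and
``scipy.stats.pearsonr`` for the correlation.  Shares no code with the
package beyond consuming its network/DataFrame containers read-only.
"""

from __future__ import annotations

import math
import statistics

import pandas as pd
from scipy import stats


def o_pcc(x, y) -> float:
    """Pearson correlation; 0 for a zero-variance vector."""
    if len(set(map(float, x))) == 1 or len(set(map(float, y))) == 1:
        return 0.0
    return float(stats.pearsonr(list(x), list(y)).statistic)


def o_weights(gene: str, neighbors, expr: pd.DataFrame) -> list[float]:
    absc = [
        abs(o_pcc(expr.loc[gene].tolist(), expr.loc[n].tolist())) for n in neighbors
    ]
    total = sum(absc)
    if total == 0.0:
        return [1.0 / len(neighbors)] * len(neighbors)
    return [a / total for a in absc]


def o_entropy(weights) -> float:
    m = len(weights)
    acc = 0.0
    for p in weights:
        if p > 0.0:
            acc += p * math.log(p)
    return -acc / math.log(m)


def o_sd(gene: str, expr: pd.DataFrame) -> float:
    return statistics.stdev(expr.loc[gene].tolist())


def o_node_stats(net, gene: str, expr: pd.DataFrame) -> tuple[float, float]:
    h = o_entropy(o_weights(gene, net.neighbors(gene), expr))
    return h, o_sd(gene, expr)


def o_edge_record(net, g1: str, g2: str, reference: pd.DataFrame,
                  perturbed: pd.Series) -> dict:
    """Literal step-by-step evaluation of the edge score for one edge."""
    appended = reference.copy()
    appended["__pert__"] = perturbed.reindex(reference.index)
    alpha = net.degree(g1)
    beta = net.degree(g2)

    def edge_stats(expr):
        h1, sd1 = o_node_stats(net, g1, expr)
        h2, sd2 = o_node_stats(net, g2, expr)
        h_e = alpha / (alpha + beta) * h1 + beta / (alpha + beta) * h2
        sd_e = alpha / (alpha + beta) * sd1 + beta / (alpha + beta) * sd2
        return h_e, sd_e

    h_ref, sd_ref = edge_stats(reference)
    h_pert, sd_pert = edge_stats(appended)
    return {
        "gene1": g1,
        "gene2": g2,
        "H_ref": h_ref,
        "SD_ref": sd_ref,
        "H_pert": h_pert,
        "SD_pert": sd_pert,
        "delta": abs(sd_pert - sd_ref) * abs(h_pert - h_ref),
    }


def o_score_sample(net, reference: pd.DataFrame, perturbed: pd.Series) -> dict:
    """Per-edge records plus their plain mean as the global score."""
    records = [
        o_edge_record(net, g1, g2, reference, perturbed)
        for g1, g2 in net.sorted_edges()
    ]
    return {
        "records": records,
        "global_score": sum(r["delta"] for r in records) / len(records),
    }
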