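import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from niee import (
    EdgeContext,
    differential_edge_score,
    edge_context,
    edge_entropy,
    edge_sd,
    local_score,
    neighbor_weights,
    node_entropy,
    node_sd,
    pcc,
    score_sample,
)
from tests.conftest import random_instance
from tests.oracle import o_score_sample


def _expr(data: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(data).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df.astype(float)


class TestPcc:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
            ([1, 1, 1], [1, 2, 3], 0.0),  # zero-variance convention
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pcc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            pcc([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            pcc([1, 2], [3, 4])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.data(),
    )
    def test_symmetry_and_bounds(self, x, data):
        y = data.draw(
            st.lists(st.floats(-50, 50), min_size=len(x), max_size=len(x))
        )
        r = pcc(x, y)
        assert -1.0 <= r <= 1.0
        assert pcc(y, x) == pytest.approx(r, abs=1e-12)


class TestNodeEntropy:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0, 0.0], 0.0),
            ([0.75, 0.25], 0.8112781244591328),  # -(.75 log2 .75 + .25 log2 .25)
            ([1 / 3] * 3, 1.0),
        ],
    )
    def test_known_values(self, weights, expected):
        assert node_entropy(weights) == pytest.approx(expected, abs=1e-12)

    def test_log_base_independence(self):
        """1/log M normalisation cancels the base: compare against a base-2 evaluation."""
        w = [0.6, 0.3, 0.08, 0.02]
        base2 = -sum(p * math.log2(p) for p in w) / math.log2(len(w))
        assert node_entropy(w) == pytest.approx(base2, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            node_entropy([1.0])
        with pytest.raises(ValueError, match="probability"):
            node_entropy([0.5, 0.6])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=15))
    def test_in_unit_interval_and_uniform_is_max(self, raw):
        w = np.array(raw) / np.sum(raw)
        h = node_entropy(w)
        assert 0.0 <= h <= 1.0
        assert h <= node_entropy(np.full(len(w), 1.0 / len(w))) + 1e-12


class TestNodeSd:
    def test_known_values(self):
        expr = _expr({"A": [1, 2, 3], "B": [5, 5, 5], "C": [0, 10, 5]})
        assert node_sd("A", expr) == pytest.approx(1.0)
        assert node_sd("B", expr) == pytest.approx(0.0)
        assert node_sd("C", expr.iloc[:, :2]) == pytest.approx(math.sqrt(50.0))

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            node_sd("Z", _expr({"A": [1, 2, 3]}))


class TestNeighborWeights:
    def test_normalisation(self):
        # gene X with neighbours tracking it at different strengths
        expr = _expr(
            {"X": [1, 2, 3, 4], "N1": [1, 2, 3, 5], "N2": [4, 1, 3, 2]}
        )
        w = neighbor_weights("X", ["N1", "N2"], expr)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert w[0] > w[1]  # N1 correlates more strongly with X

    def test_all_zero_fallback_is_uniform(self):
        expr = _expr({"X": [1, 2, 3], "N1": [7, 7, 7], "N2": [4, 4, 4]})
        np.testing.assert_allclose(
            neighbor_weights("X", ["N1", "N2"], expr), [0.5, 0.5]
        )

    def test_missing_gene_or_neighbor(self):
        expr = _expr({"X": [1, 2, 3], "N1": [1, 3, 2]})
        with pytest.raises(KeyError):
            neighbor_weights("Z", ["N1", "X"], expr)
        with pytest.raises(KeyError):
            neighbor_weights("X", ["N1", "N2"], expr)


class TestEdgeCombination:
    def test_degree_weighted_convex_combination(self, triangle_net):
        # symmetric 3-cycle: all degrees 2, both endpoint entropies equal by symmetry
        expr = _expr({"A": [1, 2, 3, 4], "B": [2, 1, 4, 3], "C": [1, 3, 2, 4]})
        ctx = edge_context(triangle_net, "A", "B")
        h = edge_entropy(ctx, expr)
        h_a = node_entropy(neighbor_weights("A", ctx.neighbors1, expr))
        h_b = node_entropy(neighbor_weights("B", ctx.neighbors2, expr))
        assert h == pytest.approx((h_a + h_b) / 2)
        sd = edge_sd(ctx, expr)
        assert sd == pytest.approx((node_sd("A", expr) + node_sd("B", expr)) / 2)

    def test_edge_context_invariants(self, triangle_net):
        ctx = edge_context(triangle_net, "A", "B")
        assert ctx.gene2 in ctx.neighbors1 and ctx.gene1 in ctx.neighbors2
        assert ctx.M1 == ctx.alpha and ctx.M2 == ctx.beta
        with pytest.raises(ValueError, match="first-order"):
            EdgeContext("A", "B", 2, 2, ("C", "D"), ("A", "C"))


class TestDifferentialScore:
    def test_zero_when_entropy_factor_vanishes(self, triangle_net):
        # exactly (anti)correlated construction: the appended sample keeps
        # every |PCC| at 1, so both endpoint entropies are pinned at 1
        expr = _expr(
            {"A": [1, 2, 1, 2], "B": [1, 2, 1, 2], "C": [2, 1, 2, 1]}
        )
        vec = pd.Series([1.0, 1.0, 2.0], index=["A", "B", "C"], name="p")
        ctx = edge_context(triangle_net, "A", "B")
        rec = differential_edge_score(ctx, expr, vec)
        # |PCC| stays 1 for every pair, so both entropies stay at their value
        assert rec.H_pert == pytest.approx(rec.H_ref, abs=1e-12)
        assert rec.delta == pytest.approx(0.0, abs=1e-12)

    def test_delta_is_product_of_absolute_differences(self, small_instance):
        net, ref, pert = small_instance
        g1, g2 = net.sorted_edges()[0]
        rec = differential_edge_score(edge_context(net, g1, g2), ref, pert)
        assert rec.delta == pytest.approx(
            abs(rec.SD_pert - rec.SD_ref) * abs(rec.H_pert - rec.H_ref), abs=0
        )
        assert 0.0 <= rec.H_ref <= 1.0 and 0.0 <= rec.H_pert <= 1.0
        assert rec.delta >= 0.0


class TestScoreSample:
    def test_matches_naive_oracle(self, small_instance):
        net, ref, pert = small_instance
        result = score_sample(net, ref, pert)
        expected = o_score_sample(net, ref, pert)
        for got, want in zip(result.records.to_dict("records"), expected["records"]):
            for fieldname in ("H_ref", "SD_ref", "H_pert", "SD_pert", "delta"):
                assert got[fieldname] == pytest.approx(want[fieldname], abs=1e-10)
        assert result.global_score == pytest.approx(
            expected["global_score"], abs=1e-10
        )

    def test_single_edge_network_global_equals_delta(self):
        # 4-cycle: every node keeps two neighbours
        from niee import BackgroundNetwork

        net = BackgroundNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
        )
        rng = np.random.default_rng(1)
        ref = pd.DataFrame(
            rng.standard_normal((4, 6)),
            index=list("ABCD"),
            columns=[f"s{i}" for i in range(6)],
        )
        pert = pd.Series(rng.standard_normal(4), index=list("ABCD"), name="p")
        result = score_sample(net, ref, pert)
        assert result.global_score == pytest.approx(
            result.records["delta"].mean()
        )

    def test_reference_column_order_invariance(self, small_instance):
        net, ref, pert = small_instance
        shuffled = ref[list(ref.columns[::-1])]
        a = score_sample(net, ref, pert)
        b = score_sample(net, shuffled, pert)
        np.testing.assert_allclose(
            a.records["delta"], b.records["delta"], atol=1e-12
        )

    def test_scale_covariance(self, small_instance):
        """Scaling all expression by c leaves entropies unchanged, scales deltas by c."""
        net, ref, pert = small_instance
        c = 3.7
        a = score_sample(net, ref, pert)
        b = score_sample(net, ref * c, pert * c)
        np.testing.assert_allclose(b.records["H_ref"], a.records["H_ref"], atol=1e-10)
        np.testing.assert_allclose(b.records["H_pert"], a.records["H_pert"], atol=1e-10)
        np.testing.assert_allclose(b.records["SD_ref"], c * a.records["SD_ref"], rtol=1e-10)
        np.testing.assert_allclose(b.records["delta"], c * a.records["delta"], rtol=1e-9, atol=1e-15)

    def test_shifted_profile_scores_higher_than_mean_profile(self):
        """A 5-sigma-shifted sample perturbs the network more than the cohort mean."""
        wins = 0
        for seed in range(20):
            net, ref, _ = random_instance(seed=100 + seed)
            mean_profile = pd.Series(
                ref.mean(axis=1), index=ref.index, name="mean"
            )
            shifted = mean_profile + 5.0 * ref.std(axis=1, ddof=1)
            shifted.name = "shifted"
            low = score_sample(net, ref, mean_profile).global_score
            high = score_sample(net, ref, shifted).global_score
            wins += int(high > low)
        assert wins == 20

    def test_missing_genes_raise(self, small_instance):
        net, ref, pert = small_instance
        with pytest.raises(KeyError):
            score_sample(net, ref.iloc[1:], pert)
        with pytest.raises(KeyError):
            score_sample(net, ref, pert.iloc[1:])


class TestLocalScore:
    def test_full_subset_equals_global_bitwise(self, small_instance):
        net, ref, pert = small_instance
        result = score_sample(net, ref, pert)
        assert local_score(result, result.edges) == result.global_score

    def test_single_edge_and_arithmetic(self, small_instance):
        net, ref, pert = small_instance
        result = score_sample(net, ref, pert)
        e0 = result.edges[0]
        assert local_score(result, [e0]) == pytest.approx(
            result.delta_by_edge()[e0]
        )
        two = result.edges[:2]
        deltas = [result.delta_by_edge()[e] for e in two]
        assert local_score(result, two) == pytest.approx(np.mean(deltas))
        assert local_score(result, two, reduction="sum") == pytest.approx(sum(deltas))

    def test_errors(self, small_instance):
        net, ref, pert = small_instance
        result = score_sample(net, ref, pert)
        with pytest.raises(ValueError, match="non-empty"):
            local_score(result, [])
        with pytest.raises(KeyError):
            local_score(result, [("no", "pe")])
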