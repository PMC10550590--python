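"""Explainer: mask arithmetic, loss closed forms, AUC oracle, recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pglcn import (
    ExplainerConfig,
    PGLCN,
    TrainConfig,
    explanation_auc,
    extract_subgraph,
    fit_explanation,
    fit_node_explanation,
    masked_forward,
)
from pglcn.explainer import (
    ExplanationMasks,
    _binary_entropy,
    _regularizers,
    khop_subgraph,
)
from pglcn.autodiff import Tensor, parameter
from pglcn.model import softmax, support_edges, train_transductive


def _pairwise_auc_oracle(scores, flags):
    """Exhaustive concordant-pair count, ties half."""
    pos = [s for s, f in zip(scores, flags) if f]
    neg = [s for s, f in zip(scores, flags) if not f]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestExplanationAuc:
    def test_perfect_separation(self):
        assert explanation_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert explanation_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_case(self):
        assert explanation_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_degenerate_is_nan(self):
        assert np.isnan(explanation_auc([0.1, 0.9], [1, 1]))
        assert np.isnan(explanation_auc([0.1, 0.9], [0, 0]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9, 1.0]),
                 min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_exhaustive_oracle(self, scores, data):
        flags = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        expected = _pairwise_auc_oracle(scores, flags)
        got = explanation_auc(scores, flags)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_all_binary_flag_patterns_up_to_five_edges(self):
        scores = [0.9, 0.4, 0.6, 0.4, 0.2]
        for flags in itertools.product([0, 1], repeat=5):
            expected = _pairwise_auc_oracle(scores, flags)
            got = explanation_auc(scores, list(flags))
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestLossComponents:
    def test_half_probability_closed_forms(self):
        cfg = ExplainerConfig(edge_ent=1.0, feat_ent=1.0, edge_size=1.0, feat_size=1.0)
        zeros = parameter(np.zeros(4))  # sigma(0) = 0.5
        comps = _regularizers(zeros, zeros, cfg)
        assert comps["edge_entropy"].value == pytest.approx(np.log(2))
        assert comps["feat_entropy"].value == pytest.approx(np.log(2))
        assert comps["edge_size"].value == pytest.approx(0.5)
        assert comps["feat_size"].value == pytest.approx(0.5)

    def test_theta_scales_linearly(self):
        cfg = ExplainerConfig(edge_ent=0.3, feat_ent=0.0, edge_size=2.0, feat_size=0.0)
        zeros = parameter(np.zeros(3))
        comps = _regularizers(zeros, zeros, cfg)
        assert comps["edge_entropy"].value == pytest.approx(0.3 * np.log(2))
        assert comps["edge_size"].value == pytest.approx(2.0 * 0.5)

    def test_saturated_mask_has_near_zero_entropy(self):
        big = parameter(np.array([50.0, -50.0]))
        assert _binary_entropy(big.sigmoid()).mean().value < 1e-4

    def test_two_by_two_mask_hand_value(self):
        probs = np.array([0.9, 0.1, 0.5, 0.5])
        h = -probs * np.log(probs) - (1 - probs) * np.log(1 - probs)
        logits = np.log(probs / (1 - probs))
        got = _binary_entropy(parameter(logits).sigmoid()).mean().value
        assert got == pytest.approx(h.mean(), abs=1e-9)
        assert h.mean() == pytest.approx(0.5091, abs=1e-4)


def test_explainer_loss_components_reported_separately():
    from pglcn.explainer import explainer_loss

    model, x, edges = _toy_transductive_model()
    masks = fit_node_explanation(model, x, edges, 2, ExplainerConfig(epochs=3, seed=0))
    comps = explainer_loss(model, x, None, masks, ExplainerConfig())
    assert set(comps) == {"pred", "edge_entropy", "feat_entropy", "edge_size",
                          "feat_size", "total"}
    assert comps["pred"] >= 0
    assert comps["total"] == pytest.approx(
        sum(v for k, v in comps.items() if k != "total")
    )


def _toy_transductive_model(seed=0):
    """Tiny trained model on a 6-node graph with two classes."""
    rng = np.random.default_rng(seed)
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 0]])
    x = rng.normal(size=(6, 4))
    y = np.array([0, 1, 0, 1, 0, 1])
    cfg = TrainConfig(mode="transductive", embed_dim=2, conv_dims=(4,), epochs=30,
                      patience=0, seed=seed)
    res = train_transductive(x, edges, y, [0, 1, 2, 3], [4, 5], cfg)
    return res.model, x, edges


class TestMaskedForward:
    def test_saturated_masks_reproduce_unmasked_prediction(self):
        model, x, edges = _toy_transductive_model()
        node = 2
        masks = fit_node_explanation(model, x, edges, node,
                                     ExplainerConfig(epochs=1, seed=0))
        masks.edge_logits[:] = 50.0       # sigma -> 1
        masks.feature_logits[:] = 50.0
        p_masked = masked_forward(model, x, None, masks)
        n = x.shape[0]
        a = np.eye(n, dtype=int)
        a[edges[:, 0], edges[:, 1]] = 1
        a[edges[:, 1], edges[:, 0]] = 1
        p_full = model.predict_proba(x, prior_A=a)
        local = int(np.where(masks.node_ids == node)[0][0])
        assert p_masked[local] == pytest.approx(p_full[node], abs=1e-9)

    def test_negative_masks_reduce_to_self_loops(self):
        """sigma(M) -> 0 off-diagonal: only self-loop propagation survives
        (with its original softmax share; deleted mass is not redistributed)."""
        model, x, edges = _toy_transductive_model()
        masks = fit_node_explanation(model, x, edges, 2,
                                     ExplainerConfig(epochs=1, seed=0))
        masks.edge_logits[:] = -60.0      # sigma -> 0: off-diagonal removed
        masks.feature_logits[:] = 50.0
        p_masked = masked_forward(model, x, None, masks)
        nodes = masks.node_ids
        sub_x = x[nodes]
        n = len(nodes)
        a = np.eye(n, dtype=int)
        local = {g: i for i, g in enumerate(nodes)}
        for u, v in masks.pairs:
            a[local[u], local[v]] = a[local[v], local[u]] = 1
        row, col = support_edges(a)
        s_full = model._affinity(Tensor(sub_x), row, col, n).value.reshape(-1)
        s_dense = np.zeros((n, n))
        s_dense[row, col] = s_full
        s_dense[~np.eye(n, dtype=bool)] = 0.0  # masked off-diagonal
        h = sub_x
        for w in model.conv_ws:
            h = np.maximum(s_dense @ h @ w.value, 0.0)
        oracle = softmax(h @ model.head_w.value + model.head_b.value[None, :])
        assert p_masked == pytest.approx(oracle, abs=1e-6)

    def test_mask_composition_matches_numpy_oracle(self):
        """Finite masks: probabilities equal composing sigma-mask arithmetic
        with a dense numpy re-implementation of the forward pass."""
        model, x, edges = _toy_transductive_model(seed=3)
        masks = fit_node_explanation(model, x, edges, 1,
                                     ExplainerConfig(epochs=5, seed=1))
        p_masked = masked_forward(model, x, None, masks)
        nodes = masks.node_ids
        sub_x = x[nodes] * (1 / (1 + np.exp(-masks.feature_logits)))[None, :]
        n = len(nodes)
        local = {g: i for i, g in enumerate(nodes)}
        a = np.eye(n)
        mask_val = np.zeros((n, n))
        for (u, v), ml in zip(masks.pairs, masks.edge_logits):
            i, j = local[u], local[v]
            a[i, j] = a[j, i] = 1
            mask_val[i, j] = mask_val[j, i] = 1 / (1 + np.exp(-ml))
        np.fill_diagonal(mask_val, 1.0)
        g = sub_x @ model.P.value
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if a[i, j]:
                    w[i, j] = np.exp(max(0.0, float(
                        model.a.value.reshape(-1) @ np.abs(g[i] - g[j]))))
        s = (w / w.sum(axis=1, keepdims=True)) * mask_val
        h = sub_x
        for wmat in model.conv_ws:
            h = np.maximum(s @ h @ wmat.value, 0.0)
        oracle = softmax(h @ model.head_w.value + model.head_b.value[None, :])
        assert p_masked == pytest.approx(oracle, abs=1e-8)


class TestFitting:
    def test_same_seed_identical_masks(self):
        model, x, edges = _toy_transductive_model()
        cfg = ExplainerConfig(epochs=20, seed=7)
        m1 = fit_node_explanation(model, x, edges, 3, cfg)
        m2 = fit_node_explanation(model, x, edges, 3, cfg)
        assert m1.edge_logits == pytest.approx(m2.edge_logits, abs=0)
        assert m1.target == m2.target

    def test_model_parameters_unchanged_by_explanation(self):
        model, x, edges = _toy_transductive_model()
        before = [p.value.copy() for p in model.parameters()]
        fit_node_explanation(model, x, edges, 0, ExplainerConfig(epochs=10, seed=0))
        for b, p in zip(before, model.parameters()):
            assert np.array_equal(b, p.value)

    def test_critical_edge_ranks_first_in_engineered_model(self):
        """A model whose target-class evidence comes only from node 2's
        feature, reachable from node 0 only through edge (0, 2): that edge
        must get the largest mask weight."""
        cfg = TrainConfig(mode="transductive", embed_dim=1, conv_dims=(2,), seed=0)
        model = PGLCN(2, 2, 4, cfg)
        # star around node 0 with leaves 1, 2, 3; only node 2 carries signal
        edges = np.array([[0, 1], [0, 2], [0, 3]])
        x = np.zeros((4, 2))
        x[:, 0] = 1.0
        x[2, 1] = 5.0
        model.P.value[:] = [[1.0], [0.0]]
        model.a.value[:] = 0.0            # uniform affinity
        model.conv_ws[0].value[:] = [[0.0, 0.0], [1.0, 0.0]]
        model.head_w.value[:] = [[4.0, -4.0], [0.0, 0.0]]
        model.head_b.value[:] = [0.0, 2.0]
        masks = fit_node_explanation(
            model, x, edges, 0, ExplainerConfig(epochs=150, seed=0)
        )
        probs = {tuple(p): v for p, v in zip(masks.pairs, masks.edge_probs)}
        assert masks.target == 0
        assert probs[(0, 2)] == max(probs.values())

    def test_cohort_explanation_runs_and_is_seeded(self, tiny_pathway_graph):
        rng = np.random.default_rng(0)
        cfg = TrainConfig(mode="cohort", embed_dim=2, conv_dims=(4,), fc_dims=(8,), seed=0)
        model = PGLCN(6, 2, 5, cfg)
        inst = rng.normal(size=(5, 6))
        ecfg = ExplainerConfig(epochs=10, seed=4)
        m1 = fit_explanation(model, inst, tiny_pathway_graph.adjacency, ecfg, instance=0)
        m2 = fit_explanation(model, inst, tiny_pathway_graph.adjacency, ecfg, instance=0)
        assert m1.edge_logits == pytest.approx(m2.edge_logits, abs=0)
        assert len(m1.pairs) == 4  # chain prior: 4 off-diagonal pairs


class TestSubgraphExtraction:
    def _masks(self, probs):
        logits = np.log(np.asarray(probs) / (1 - np.asarray(probs)))
        pairs = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])[: len(probs)]
        return ExplanationMasks(
            instance=0, pairs=pairs, edge_logits=logits,
            feature_logits=np.zeros(2), target=0,
        )

    def test_topk_equal_to_edge_count_returns_all(self):
        res = extract_subgraph(self._masks([0.9, 0.5, 0.2]), top_k=3)
        assert len(res.edges) == 3

    def test_topk_larger_than_edges_returns_all(self):
        res = extract_subgraph(self._masks([0.9, 0.5]), top_k=10)
        assert len(res.edges) == 2

    def test_threshold_one_is_empty(self):
        res = extract_subgraph(self._masks([0.99, 0.8]), threshold=1.0)
        assert res.edges == []

    def test_dominant_edges_selected(self):
        res = extract_subgraph(self._masks([0.95, 0.1, 0.9, 0.2]), top_k=2)
        kept = {(u, v) for u, v, _ in res.edges}
        assert kept == {(0, 1), (2, 3)}
        weights = [w for _, _, w in res.edges]
        assert weights == sorted(weights, reverse=True)


class TestKhopSubgraph:
    def test_hops_and_induced_edges(self):
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [1, 5]])
        nodes, pairs = khop_subgraph(edges, 0, 2)
        assert nodes.tolist() == [0, 1, 2, 5]
        assert [tuple(p) for p in pairs] == [(0, 1), (1, 2), (1, 5)]

    def test_full_graph_at_large_k(self):
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        nodes, pairs = khop_subgraph(edges, 0, 10)
        assert nodes.tolist() == [0, 1, 2, 3]
        assert len(pairs) == 3
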