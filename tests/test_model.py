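import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scattn.model as model_mod
from scattn.graph import EdgeList
from scattn.model import (
    AGNNClassifier,
    TrainConfig,
    _edge_arrays,
    _loss_and_gradients,
    architecture_search,
    attention_weights,
    forward,
    init_model,
    learning_rate_at,
    nll_loss,
    predict,
    train,
)


def _path_graph(n):
    pairs = [(i, i + 1) for i in range(n - 1)]
    edges = np.array(pairs + [(b, a) for a, b in pairs])
    return EdgeList(edges=edges, n_nodes=n)


def _cycle_graph(n):
    pairs = [(i, (i + 1) % n) for i in range(n)]
    edges = np.array(pairs + [(b, a) for a, b in pairs])
    return EdgeList(edges=edges, n_nodes=n)


def _dense_forward_oracle(model, F, edges):
    """From-scratch forward pass using explicit dense loops."""
    n = edges.n_nodes
    neigh = [set([i]) for i in range(n)]
    for a, b in edges.edges:
        neigh[a].add(b)
    H = np.maximum(F @ model.W0, 0.0)
    for beta in model.betas:
        norms = np.linalg.norm(H, axis=1)
        newH = np.zeros_like(H)
        for i in range(n):
            js = sorted(neigh[i])
            scores = []
            for j in js:
                if norms[i] > 1e-12 and norms[j] > 1e-12:
                    c = H[i] @ H[j] / (norms[i] * norms[j])
                else:
                    c = 0.0
                scores.append(beta * c)
            scores = np.array(scores)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for wj, j in zip(w, js):
                newH[i] += wj * H[j]
        H = newH
    logits = H @ model.W1
    E = np.exp(logits - logits.max(axis=1, keepdims=True))
    return E / E.sum(axis=1, keepdims=True)


class TestAttentionWeights:
    def test_beta_zero_gives_uniform_weights(self, rng):
        edges = _path_graph(4)
        h = rng.normal(size=(4, 3))
        P = attention_weights(h, edges, beta=0.0).toarray()
        # node 0 has neighbours {0, 1} -> 1/2 each; node 1 has {0,1,2} -> 1/3
        np.testing.assert_allclose(P[0, [0, 1]], 0.5)
        np.testing.assert_allclose(P[1, [0, 1, 2]], 1 / 3)

    def test_isolated_node_self_weight_one(self, rng):
        edges = EdgeList(edges=np.array([[0, 1], [1, 0]]), n_nodes=3)
        P = attention_weights(rng.normal(size=(3, 2)), edges, beta=1.5).toarray()
        assert P[2, 2] == pytest.approx(1.0)

    def test_hand_computed_softmax_on_path(self):
        h = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        beta = 2.0
        P = attention_weights(h, _path_graph(3), beta).toarray()
        # node 1: neighbours {0, 1, 2}; cos to both ends = 1/sqrt(2), to self = 1
        c01 = 1 / np.sqrt(2)
        w = np.exp(beta * np.array([c01, 1.0, c01]))
        w /= w.sum()
        np.testing.assert_allclose(P[1, [0, 1, 2]], w, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(2, 12),
        beta=st.floats(-3, 3),
        seed=st.integers(0, 1000),
    )
    def test_rows_are_probability_distributions(self, n, beta, seed):
        rng = np.random.default_rng(seed)
        n_edges = int(rng.integers(0, n * 2))
        pairs = rng.integers(0, n, size=(n_edges, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        if len(pairs):
            both = np.vstack([pairs, pairs[:, ::-1]])
            edges = EdgeList(edges=np.unique(both, axis=0), n_nodes=n)
        else:
            edges = EdgeList(edges=np.empty((0, 2), dtype=int), n_nodes=n)
        h = rng.normal(size=(n, 4))
        h[0] = 0.0  # exercise the zero-norm guard
        P = attention_weights(h, edges, beta)
        np.testing.assert_allclose(P.sum(axis=1).A1, 1.0, atol=1e-9)
        assert P.toarray().min() >= 0


class TestForward:
    def test_output_rows_sum_to_one(self, rng):
        edges = _cycle_graph(6)
        model = init_model(5, 4, 2, 3, seed=0)
        probs = forward(model, rng.random((6, 5)), edges)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_features_on_regular_graph_give_identical_rows(self):
        edges = _cycle_graph(5)
        model = init_model(3, 4, 1, 2, seed=1)
        model.betas[:] = 0.0
        F = np.tile([0.2, 0.5, 0.3], (5, 1))
        probs = forward(model, F, edges)
        np.testing.assert_allclose(probs, np.tile(probs[0], (5, 1)), atol=1e-12)

    @pytest.mark.parametrize("n_layers", [1, 2, 3])
    def test_matches_dense_oracle(self, rng, n_layers):
        n = 8
        pairs = rng.integers(0, n, size=(10, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        both = np.unique(np.vstack([pairs, pairs[:, ::-1]]), axis=0)
        edges = EdgeList(edges=both, n_nodes=n)
        model = init_model(6, 5, n_layers, 3, seed=2)
        F = rng.random((n, 6))
        got = forward(model, F, edges)
        want = _dense_forward_oracle(model, F, edges)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_beta_zero_propagation_is_uniform_neighbourhood_average(self, rng):
        # closed-form limit: with beta = 0 a propagation layer averages
        # each neighbourhood (self included) uniformly
        from scattn.model import _attention_layer_forward

        edges = _cycle_graph(7)
        src, dst = _edge_arrays(edges)
        H = rng.normal(size=(7, 4))
        out, _ = _attention_layer_forward(H, src, dst, 0.0)
        want = np.stack(
            [(H[i] + H[(i - 1) % 7] + H[(i + 1) % 7]) / 3 for i in range(7)]
        )
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_propagation_stays_in_convex_hull_per_coordinate(self, rng):
        from scattn.model import _attention_layer_forward

        edges = _cycle_graph(9)
        src, dst = _edge_arrays(edges)
        H = rng.normal(size=(9, 3))
        out, _ = _attention_layer_forward(H, src, dst, 1.7)
        assert np.all(out.max(axis=0) <= H.max(axis=0) + 1e-12)
        assert np.all(out.min(axis=0) >= H.min(axis=0) - 1e-12)

    def test_dimension_mismatch_raises(self, rng):
        model = init_model(5, 4, 1, 2, seed=0)
        with pytest.raises(ValueError):
            forward(model, rng.random((3, 4)), _path_graph(3))


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)
        labels = np.array([0, 1, 2])
        assert nll_loss(probs, labels, np.arange(3)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_L(self):
        L = 4
        probs = np.full((5, L), 1 / L)
        labels = np.zeros(5, dtype=int)
        assert nll_loss(probs, labels, np.arange(5)) == pytest.approx(np.log(L))

    def test_mixed_case_matches_hand_arithmetic(self):
        probs = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        labels = np.array([0, 0, 1])
        want = -(np.log(0.7) + np.log(0.2) + np.log(0.5)) / 3
        assert nll_loss(probs, labels, np.arange(3)) == pytest.approx(want)

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            nll_loss(np.eye(2), np.array([0, 1]), np.array([], dtype=int))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        n, m, L = 7, 4, 3
        pairs = np.array([[0, 1], [1, 2], [2, 3], [4, 5], [0, 6]])
        edges = EdgeList(
            edges=np.vstack([pairs, pairs[:, ::-1]]), n_nodes=n
        )
        F = rng.random((n, m))
        labels = rng.integers(0, L, n)
        train_idx = np.array([0, 1, 2, 4])
        model = init_model(m, 3, 2, L, seed=1)
        ea = _edge_arrays(edges)
        _, _, grads = _loss_and_gradients(model, F, ea, labels, train_idx)

        eps = 1e-6
        for name in ("W0", "betas", "W1"):
            arr = getattr(model, name)
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = _loss_and_gradients(model, F, ea, labels, train_idx)
                arr[idx] = orig - eps
                lm, _, _ = _loss_and_gradients(model, F, ea, labels, train_idx)
                arr[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            scale = np.max(np.abs(num)) + 1e-12
            assert np.max(np.abs(num - grads[name])) / scale < 1e-6, name


class TestTraining:
    def test_step_learning_rate_schedule(self):
        cfg = TrainConfig(learning_rate=0.01, step_size=10, gamma=0.8)
        assert learning_rate_at(0, cfg) == pytest.approx(0.01)
        assert learning_rate_at(9, cfg) == pytest.approx(0.01)
        assert learning_rate_at(10, cfg) == pytest.approx(0.008)
        assert learning_rate_at(20, cfg) == pytest.approx(0.01 * 0.8**2)
        for e in range(50):
            assert learning_rate_at(e, cfg) == pytest.approx(
                0.01 * 0.8 ** (e // 10)
            )

    def test_lr_history_non_increasing_steps_at_multiples(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=10)
        cfg = TrainConfig(patience=25, max_epochs=35, step_size=10, gamma=0.8)
        _, hist = train(init_model(2, 4, 1, 2, seed=0), F, edges, labels, tr, va, cfg)
        lrs = np.array(hist.learning_rate)
        assert np.all(np.diff(lrs) <= 1e-15)
        changes = np.flatnonzero(np.diff(lrs) < 0) + 1
        assert all(c % 10 == 0 for c in changes)

    def test_early_stop_exactly_patience_after_best(self, rng, monkeypatch):
        monkeypatch.setattr(model_mod, "_validation_accuracy", lambda *a: 0.5)
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=8)
        cfg = TrainConfig(patience=7, max_epochs=500)
        _, hist = train(init_model(2, 3, 1, 2, seed=0), F, edges, labels, tr, va, cfg)
        assert hist.stopped_early
        assert hist.best_epoch == 0
        assert hist.n_epochs == cfg.patience + 1

    def test_separable_two_class_graph_reaches_full_training_accuracy(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=30)
        cfg = TrainConfig(patience=200, max_epochs=200)
        best, hist = train(
            init_model(2, 8, 2, 2, seed=3), F, edges, labels, tr, va, cfg
        )
        pred = predict(best, F, edges, tr)
        acc = float(np.mean(pred == labels[tr]))
        assert acc == 1.0  # majority baseline would give 0.5

    def test_non_finite_loss_aborts(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=5)
        model = init_model(2, 3, 1, 2, seed=0)
        model.W1[:] = np.nan
        with pytest.raises(FloatingPointError):
            train(model, F, edges, labels, tr, va, TrainConfig(max_epochs=5))


def _separable_problem(rng, n_per_class=20):
    """Two well-separated clusters, intra-class edges only."""
    n = 2 * n_per_class
    F = np.vstack(
        [
            rng.normal([0, 5], 0.3, size=(n_per_class, 2)),
            rng.normal([5, 0], 0.3, size=(n_per_class, 2)),
        ]
    )
    F = np.abs(F)
    pairs = []
    for c in range(2):
        base = c * n_per_class
        for i in range(n_per_class - 1):
            pairs.append((base + i, base + i + 1))
    pairs = np.array(pairs)
    edges = EdgeList(edges=np.vstack([pairs, pairs[:, ::-1]]), n_nodes=n)
    labels = np.repeat([0, 1], n_per_class)
    idx = rng.permutation(n)
    tr, va = idx[: int(0.8 * n)], idx[int(0.8 * n) :]
    return F, edges, labels, tr, va


class TestPredict:
    def test_one_hot_rows_recovered(self):
        model = init_model(3, 2, 1, 3, seed=0)
        # direct argmax semantics via the functional predict on known probs
        probs = np.array([[0.1, 0.8, 0.1], [0.9, 0.05, 0.05]])
        assert np.argmax(probs, axis=1).tolist() == [1, 0]

    def test_uniform_row_ties_break_to_lowest_class(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=4)
        model = init_model(2, 3, 1, 2, seed=0)
        model.W1[:] = 0.0  # uniform output distribution everywhere
        pred = predict(model, F, edges)
        assert np.all(pred == 0)

    def test_prediction_count_matches_subset(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=6)
        model = init_model(2, 3, 1, 2, seed=0)
        subset = np.array([0, 3, 5])
        assert predict(model, F, edges, subset).shape == (3,)


class TestArchitectureSearch:
    @staticmethod
    def _scripted_trainer(table):
        def trainer(model, F, edges, labels, tr, va, cfg):
            from scattn.model import TrainHistory

            acc = table[(model.n_hidden, model.n_layers)]
            h = TrainHistory()
            h.val_accuracy = [acc]
            h.loss = [1.0]
            h.learning_rate = [cfg.learning_rate]
            return model, h

        return trainer

    def test_default_grid_trains_sixteen_configs_and_picks_scripted_max(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=5)
        grid_h, grid_t = (32, 64, 128, 256), (2, 3, 4, 5)
        table = {
            (H, T): 0.5 + 0.01 * (H == 128) * T for H in grid_h for T in grid_t
        }
        best, sweep = architecture_search(
            F, edges, labels, tr, va,
            grid_hidden=grid_h, grid_layers=grid_t,
            trainer=self._scripted_trainer(table),
        )
        assert len(sweep) == 16
        assert best.n_hidden == 128 and best.n_layers == 5

    def test_accuracy_tie_prefers_fewer_parameters(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=5)
        table = {(32, 2): 0.9, (256, 2): 0.9}
        best, _ = architecture_search(
            F, edges, labels, tr, va,
            grid_hidden=(32, 256), grid_layers=(2,),
            trainer=self._scripted_trainer(table),
        )
        assert best.n_hidden == 32

    def test_same_seed_same_selection(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=8)
        cfg = TrainConfig(patience=10, max_epochs=15, seed=5)
        b1, s1 = architecture_search(
            F, edges, labels, tr, va, grid_hidden=(4, 8), grid_layers=(1, 2), cfg=cfg
        )
        b2, s2 = architecture_search(
            F, edges, labels, tr, va, grid_hidden=(4, 8), grid_layers=(1, 2), cfg=cfg
        )
        assert (b1.n_hidden, b1.n_layers) == (b2.n_hidden, b2.n_layers)
        np.testing.assert_allclose(s1["val_accuracy"], s2["val_accuracy"])


class TestClassifierEstimator:
    def test_sklearn_estimator_interface(self, rng):
        clf = AGNNClassifier(n_hidden=8, n_layers=1, max_epochs=30, patience=30)
        params = clf.get_params()
        assert params["n_hidden"] == 8
        clf.set_params(n_hidden=4)
        assert clf.n_hidden == 4

    def test_fit_predict_on_separable_graph(self, rng):
        F, edges, labels, tr, va = _separable_problem(rng, n_per_class=20)
        y = labels.astype(object).copy()
        clf = AGNNClassifier(
            n_hidden=8, n_layers=2, patience=100, max_epochs=150, random_state=0
        )
        clf.fit(F, labels, edges=edges, train_idx=tr, val_idx=va)
        pred = clf.predict(F, edges=edges)
        assert np.mean(pred == labels) > 0.9
        proba = clf.predict_proba(F, edges=edges)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
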