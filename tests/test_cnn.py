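import json

import numpy as np
import pytest

from ncstruct.cnn import (
    CnnConfig,
    _forward_batch,
    _init_model,
    _loss_and_grads,
    conv_layer_forward,
    forward,
    load_model,
    max_pool,
    predict,
    save_model,
    train,
)
from ncstruct.features import FeatureMatrix
from ncstruct.mining import Fragment


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def make_matrix(values, codes=None):
    values = np.asarray(values, dtype=np.uint8)
    codes = codes or [f"f{j}" for j in range(values.shape[1])]
    frags = tuple(Fragment(c, ("A",), (), 0) for c in codes)
    gids = tuple(f"g{i}" for i in range(values.shape[0]))
    return FeatureMatrix(gids, frags, values)


class TestConvLayer:
    def test_single_kernel_direct_evaluation(self):
        x = np.array([1, 1, 1, 1, 1, 0, 0], dtype=float)
        out = conv_layer_forward(x, np.ones((1, 5)), np.zeros(1))
        np.testing.assert_allclose(out[0], sigmoid(np.array([5.0, 4.0, 3.0])), atol=1e-12)

    def test_zero_kernels_give_half(self):
        x = np.arange(8, dtype=float)
        out = conv_layer_forward(x, np.zeros((3, 4)), np.zeros(3))
        np.testing.assert_allclose(out, 0.5)

    def test_multichannel_matches_explicit_double_loop(self):
        rng = np.random.default_rng(0)
        C, L, n, k = 3, 11, 4, 5
        x = rng.normal(size=(C, L))
        w = rng.normal(size=(n, C, k))
        b = rng.normal(size=n)
        out = conv_layer_forward(x, w, b)
        expected = np.zeros((n, L - k + 1))
        for j in range(n):
            for t in range(L - k + 1):
                acc = b[j]
                for c in range(C):
                    for u in range(k):
                        acc += w[j, c, u] * x[c, t + u]
                expected[j, t] = acc
        np.testing.assert_allclose(out, sigmoid(expected), atol=1e-12)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            conv_layer_forward(np.ones(3), np.ones((1, 5)), np.zeros(1))


class TestMaxPool:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([0.2, 0.8, 0.5, 0.4], [0.8, 0.5]),
            ([0.9, 0.1, 0.3], [0.9]),  # trailing element dropped
            ([0.7], []),  # length-1 input -> empty
        ],
    )
    def test_examples(self, vec, expected):
        np.testing.assert_allclose(max_pool(np.array(vec)), expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.array([]))


def chain(L, k1, k2, n2):
    l1 = L - k1 + 1
    p1 = l1 // 2
    l2 = p1 - k2 + 1
    p2 = l2 // 2
    return l1, p1, l2, p2, n2 * p2


class TestDimensionChain:
    def test_reference_feature_count(self):
        """L=6443 with k=5/5 kernels and pool 2 flattens to 20 x 1607 = 32140."""
        cfg = CnnConfig(input_length=6443, n_classes=13)
        dims = cfg.dims()
        assert (dims["conv1"], dims["pool1"], dims["conv2"], dims["pool2"]) == (
            6439, 3219, 3215, 1607,
        )
        assert dims["flat"] == 32140

    def test_random_configs_match_closed_form(self):
        rng = np.random.default_rng(5)
        done = 0
        while done < 20:
            L = int(rng.integers(20, 4000))
            k1 = int(rng.integers(2, 9))
            k2 = int(rng.integers(2, 9))
            n2 = int(rng.integers(1, 30))
            try:
                cfg = CnnConfig(input_length=L, n_classes=3, k1=k1, k2=k2, n2=n2)
            except ValueError:
                continue
            l1, p1, l2, p2, flat = chain(L, k1, k2, n2)
            dims = cfg.dims()
            assert (dims["conv1"], dims["pool1"], dims["conv2"], dims["pool2"], dims["flat"]) == (
                l1, p1, l2, p2, flat,
            )
            done += 1

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            CnnConfig(input_length=8, n_classes=2)  # pooled length < k2


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self):
        cfg = CnnConfig(input_length=30, n_classes=4, n1=2, n2=3, hidden=5)
        model = _init_model(cfg, list("abcd"), ["f"] * 30, np.random.default_rng(0))
        for name in ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2"):
            getattr(model, name)[...] = 0.0
        p = forward(model, np.ones(30))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        cfg = CnnConfig(input_length=40, n_classes=3, n1=3, n2=4, hidden=8)
        model = _init_model(cfg, list("abc"), ["f"] * 40, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = forward(model, rng.integers(0, 2, size=40))
            assert np.all(p >= 0)
            assert abs(p.sum() - 1.0) < 1e-9

    def test_wrong_length_rejected(self):
        cfg = CnnConfig(input_length=30, n_classes=2, n1=2, n2=2, hidden=4)
        model = _init_model(cfg, list("ab"), ["f"] * 30, np.random.default_rng(0))
        with pytest.raises(ValueError, match="30"):
            forward(model, np.ones(29))


class TestGradients:
    def test_analytic_matches_central_differences(self):
        """Backprop gradients agree with finite differences on a tiny net."""
        cfg = CnnConfig(
            input_length=12, n_classes=3, k1=3, n1=2, k2=2, n2=2, hidden=5, seed=7
        )
        rng = np.random.default_rng(1)
        model = _init_model(cfg, list("abc"), ["f"] * 12, rng)
        X = rng.integers(0, 2, size=(6, 12)).astype(float)
        t = np.array([0, 1, 2, 0, 1, 2])
        _, grads = _loss_and_grads(model, X, t)
        eps = 1e-6
        worst = 0.0
        for name, g in grads.items():
            flat = getattr(model, name).reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _loss_and_grads(model, X, t)
                flat[idx] = orig - eps
                lm, _ = _loss_and_grads(model, X, t)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[idx]
                worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
        assert worst < 1e-4

    def test_full_batch_loss_non_increasing_at_small_lr(self):
        cfg = CnnConfig(input_length=20, n_classes=2, k1=3, n1=2, k2=2, n2=2, hidden=4)
        rng = np.random.default_rng(3)
        model = _init_model(cfg, list("ab"), ["f"] * 20, rng)
        X = rng.integers(0, 2, size=(8, 20)).astype(float)
        t = np.array([0, 1] * 4)
        prev = np.inf
        for _ in range(30):
            loss, grads = _loss_and_grads(model, X, t)
            assert loss <= prev + 1e-9
            prev = loss
            for name, g in grads.items():
                getattr(model, name).__isub__(1e-3 * g)


def separable_matrix():
    """Two classes marked by disjoint 5-bit feature blocks."""
    rng = np.random.default_rng(4)
    X = np.zeros((200, 40), dtype=np.uint8)
    X[:100, 5:10] = 1
    X[100:, 25:30] = 1
    labels = ["blockA"] * 100 + ["blockB"] * 100
    return make_matrix(X), labels


class TestTraining:
    def test_separable_classes_fit_exactly(self):
        matrix, labels = separable_matrix()
        cfg = CnnConfig(n1=4, n2=4, hidden=16, epochs=120, seed=0)
        model = train(matrix, labels, cfg)
        pred, probs = predict(model, matrix)
        assert pred == labels
        assert probs.shape == (200, 2)

    def test_seeded_determinism(self):
        matrix, labels = separable_matrix()
        cfg = CnnConfig(n1=2, n2=2, hidden=8, epochs=5, seed=9)
        m1 = train(matrix, labels, cfg)
        m2 = train(matrix, labels, cfg)
        for name in ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2"):
            assert np.array_equal(getattr(m1, name), getattr(m2, name))

    def test_label_length_mismatch(self):
        matrix, labels = separable_matrix()
        with pytest.raises(ValueError):
            train(matrix, labels[:-1], CnnConfig(n1=2, n2=2, hidden=4, epochs=1))

    def test_empty_class_rejected(self):
        matrix, labels = separable_matrix()
        with pytest.raises(ValueError, match="zero examples"):
            train(
                matrix,
                labels,
                CnnConfig(n1=2, n2=2, hidden=4, epochs=1),
                class_order=["blockA", "blockB", "ghost"],
            )

    def test_non_boolean_matrix_rejected(self):
        m = make_matrix(np.zeros((4, 30), dtype=np.uint8))
        bad = FeatureMatrix(m.graph_ids, m.fragments, m.values)
        object.__setattr__(bad, "values", np.full((4, 30), 0.5))
        with pytest.raises(ValueError, match="boolean"):
            train(bad, ["a", "a", "b", "b"], CnnConfig(n1=2, n2=2, hidden=4, epochs=1))


class TestPredict:
    def test_zero_weight_model_takes_first_class(self):
        matrix, _ = separable_matrix()
        cfg = CnnConfig(input_length=40, n_classes=2, n1=2, n2=2, hidden=4)
        model = _init_model(
            cfg, ["first", "second"], matrix.fragment_codes, np.random.default_rng(0)
        )
        for name in ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2"):
            getattr(model, name)[...] = 0.0
        pred, _ = predict(model, matrix)
        assert set(pred) == {"first"}

    def test_feature_space_mismatch_rejected(self):
        matrix, labels = separable_matrix()
        model = train(matrix, labels, CnnConfig(n1=2, n2=2, hidden=4, epochs=1))
        other = make_matrix(matrix.values, codes=[f"other{j}" for j in range(40)])
        with pytest.raises(ValueError, match="feature space mismatch"):
            predict(model, other)

    def test_single_row(self):
        matrix, labels = separable_matrix()
        model = train(matrix, labels, CnnConfig(n1=2, n2=2, hidden=4, epochs=1))
        one = make_matrix(matrix.values[:1])
        pred, probs = predict(model, one)
        assert len(pred) == 1 and probs.shape == (1, 2)


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        matrix, labels = separable_matrix()
        model = train(matrix, labels, CnnConfig(n1=2, n2=2, hidden=4, epochs=3, seed=2))
        p = tmp_path / "model.json"
        save_model(model, p)
        back = load_model(p)
        assert back.class_labels == model.class_labels
        assert back.fragment_codes == model.fragment_codes
        for name in ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2"):
            assert np.array_equal(getattr(back, name), getattr(model, name))
        # predictions identical through the reloaded model
        p1, _ = predict(model, matrix)
        p2, _ = predict(back, matrix)
        assert p1 == p2

    def test_format_guard(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"format": "something else"}))
        with pytest.raises(ValueError):
            load_model(p)
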