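"""Gate recurrence semantics, architectures, training and prediction."""

import numpy as np
import pytest

from preictal.lstm import (
    ARCHITECTURES,
    LstmSequenceClassifier,
    LstmWeights,
    ModelConfig,
    build_model,
    expected_parameter_count,
    lstm_cell_step,
)


def reference_cell_step(x_t, g_prev, y_prev, w):
    """Independent straight-line transcription of the gate recurrence."""
    z = np.concatenate([g_prev, x_t])

    def sigmoid(v):
        return 1.0 / (1.0 + np.exp(-v))

    i_g = sigmoid(w.w_i @ z + w.a_i)
    f_g = sigmoid(w.w_f @ z + w.a_f)
    o_g = sigmoid(w.w_o @ z + w.a_o)
    ybar = np.tanh(w.w_c @ z + w.a_c)
    y_t = f_g * y_prev + i_g * ybar
    g_t = o_g * np.tanh(y_t)
    return g_t, y_t


def random_weights(rng, h, d):
    return LstmWeights(
        *[rng.standard_normal((h, h + d)) for _ in range(4)],
        *[rng.standard_normal(h) for _ in range(4)],
    )


class TestCellStep:
    def test_all_zero_weights_zero_state(self):
        w = LstmWeights(*[np.zeros((2, 5))] * 4, *[np.zeros(2)] * 4)
        g, y = lstm_cell_step(np.zeros(3), np.zeros(2), np.zeros(2), w)
        assert np.allclose(y, 0.0) and np.allclose(g, 0.0)

    def test_all_zero_weights_unit_cell_state(self):
        """sigma(0)=0.5 gates halve the carried state: y=0.5,
        g = 0.5*tanh(0.5)."""
        w = LstmWeights(*[np.zeros((2, 5))] * 4, *[np.zeros(2)] * 4)
        g, y = lstm_cell_step(np.zeros(3), np.zeros(2), np.ones(2), w)
        assert np.allclose(y, 0.5)
        assert np.allclose(g, 0.5 * np.tanh(0.5))
        assert g[0] == pytest.approx(0.23106, abs=1e-5)

    def test_matches_independent_transcription(self, rng):
        h, d = 8, 5
        for _ in range(10):
            w = random_weights(rng, h, d)
            x = rng.standard_normal(d)
            g0 = rng.standard_normal(h)
            y0 = rng.standard_normal(h)
            g, y = lstm_cell_step(x, g0, y0, w)
            g_ref, y_ref = reference_cell_step(x, g0, y0, w)
            assert np.max(np.abs(g - g_ref)) < 1e-6
            assert np.max(np.abs(y - y_ref)) < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        w = random_weights(rng, 4, 3)
        with pytest.raises(ValueError):
            lstm_cell_step(np.zeros(5), np.zeros(4), np.zeros(4), w)


class TestForwardEquivalence:
    def test_classifier_forward_equals_cell_recurrence(self, rng):
        """The vectorized stacked forward pass must reproduce the reference
        single-cell recurrence unrolled over time and layers."""
        model = LstmSequenceClassifier(dropout_rate=0.0, standardize=False,
                                       seed=3)
        L, d = 4, 6
        model.initialize(d)
        h = model.hidden_size_
        X = rng.standard_normal((1, L, d))
        fwd = model._forward(X)
        # unroll by hand with per-gate slices of the packed matrix
        W, b = model.layers_[0]["W"], model.layers_[0]["b"]
        w = LstmWeights(
            W[:h], W[h:2 * h], W[2 * h:3 * h], W[3 * h:],
            b[:h], b[h:2 * h], b[2 * h:3 * h], b[3 * h:],
        )
        g = np.zeros(h)
        y = np.zeros(h)
        for t in range(L):
            g, y = reference_cell_step(X[0, t], g, y, w)
        assert np.max(np.abs(fwd["caches"][0]["outs"][0, -1] - g)) < 1e-6


class TestArchitectures:
    @pytest.mark.parametrize("name,layers,hidden", [
        ("LSTM_1", 1, 32), ("LSTM_2", 1, 128), ("LSTM_3", 2, 128),
    ])
    def test_named_architectures(self, name, layers, hidden):
        assert ARCHITECTURES[name] == (layers, hidden)
        model = build_model(ModelConfig(architecture=name), input_dim=7)
        assert model.n_layers_ == layers
        assert model.hidden_size_ == hidden
        assert model.head_["W1"].shape == (30, hidden)
        assert model.head_["W2"].shape == (2, 30)

    def test_parameter_count_analytic(self):
        d = 7
        model = build_model(ModelConfig(architecture="LSTM_1"), input_dim=d)
        assert model.n_parameters_ == expected_parameter_count(d, 32, 1)
        assert model.n_parameters_ == (
            4 * (32 * (32 + d) + 32) + 30 * 32 + 30 + 2 * 30 + 2
        )
        model3 = build_model(ModelConfig(architecture="LSTM_3"), input_dim=d)
        assert model3.n_parameters_ == expected_parameter_count(d, 128, 2)

    def test_three_layers_outside_design_space(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture=None, n_layers=3, hidden=32)

    def test_unknown_architecture_name(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            ModelConfig(architecture="LSTM_9")


def _separable_data(rng, n_per_class=60, L=1, d=4, gap=6.0):
    X0 = rng.standard_normal((n_per_class, L, d)) + gap
    X1 = rng.standard_normal((n_per_class, L, d)) - gap
    X = np.concatenate([X0, X1])
    y = np.array(["interictal"] * n_per_class + ["preictal"] * n_per_class)
    return X, y


class TestTraining:
    def test_separable_clusters_learned(self, rng):
        """Two 6-sigma-apart Gaussian clusters: nearest-centroid oracle is
        ~perfect, the trained network must reach 95% training accuracy."""
        X, y = _separable_data(rng)
        centro = {c: X[y == c].mean(axis=(0, 1)) for c in ("interictal",
                                                           "preictal")}
        oracle_pred = np.array([
            min(centro, key=lambda c: np.linalg.norm(x.mean(axis=0)
                                                     - centro[c]))
            for x in X
        ])
        assert (oracle_pred == y).mean() >= 0.99
        model = LstmSequenceClassifier(epochs=10, seed=0)
        model.fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.95
        assert len(model.loss_trace_) == 10
        assert model.loss_trace_[-1] < model.loss_trace_[0]

    def test_identical_seed_identical_trace(self, rng):
        X, y = _separable_data(rng, n_per_class=20)
        t1 = LstmSequenceClassifier(epochs=3, seed=7).fit(X, y).loss_trace_
        t2 = LstmSequenceClassifier(epochs=3, seed=7).fit(X, y).loss_trace_
        assert t1 == t2  # bit-identical: pure NumPy training

    def test_shuffled_labels_give_chance_accuracy(self):
        """Permutation null: with labels shuffled, held-out accuracy ~0.5."""
        rng = np.random.default_rng(42)
        X, y = _separable_data(rng, n_per_class=100)
        y_shuf = rng.permutation(y)
        model = LstmSequenceClassifier(epochs=3, seed=1)
        model.fit(X[:160], y_shuf[:160])
        acc = (model.predict(X[160:]) == y_shuf[160:]).mean()
        assert 0.3 <= acc <= 0.7

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2, 3))
        with pytest.raises(ValueError, match="two classes"):
            LstmSequenceClassifier().fit(X, np.array(["a"] * 10))

    def test_sklearn_get_set_params(self):
        model = LstmSequenceClassifier()
        params = model.get_params()
        assert params["architecture"] == "LSTM_1"
        model.set_params(epochs=3)
        assert model.epochs == 3


class TestPrediction:
    def test_probabilities_sum_to_one(self, rng):
        X, y = _separable_data(rng, n_per_class=15)
        model = LstmSequenceClassifier(epochs=2, seed=0).fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_zero_head_gives_half_half(self, rng):
        model = LstmSequenceClassifier(dropout_rate=0.0, standardize=False)
        model.initialize(3)
        model.head_["W2"][:] = 0.0
        model.head_["b2"][:] = 0.0
        proba = model._forward(rng.standard_normal((4, 2, 3)))["proba"]
        assert np.allclose(proba, 0.5)

    def test_dropout_off_at_prediction(self, rng):
        X, y = _separable_data(rng, n_per_class=15)
        model = LstmSequenceClassifier(epochs=2, dropout_rate=0.5,
                                       seed=0).fit(X, y)
        p1 = model.predict_proba(X)
        p2 = model.predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _separable_data(rng, n_per_class=15, d=4)
        model = LstmSequenceClassifier(epochs=1, seed=0).fit(X, y)
        with pytest.raises(ValueError):
            model.predict(rng.standard_normal((3, 1, 5)))

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = _separable_data(rng, n_per_class=15)
        model = LstmSequenceClassifier(epochs=2, seed=0).fit(X, y)
        path = tmp_path / "model.npz"
        model.save(path)
        back = LstmSequenceClassifier.load(path)
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))
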