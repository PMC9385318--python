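"""LSTM sequence classifier for preictal/interictal discrimination.

The recurrence is the standard gated memory cell.  With ``[g, x]`` the
concatenation of the previous hidden state and the current input,
``phi`` the logistic sigmoid and ``.`` elementwise product:

    i_t = phi(w_i [g_{t-1}, x_t] + a_i)          input gate
    f_t = phi(w_f [g_{t-1}, x_t] + a_f)          forget gate
    o_t = phi(w_o [g_{t-1}, x_t] + a_o)          output gate
    ybar_t = tanh(w_c [g_{t-1}, x_t] + a_c)      candidate state
    y_t = f_t . y_{t-1} + i_t . ybar_t           cell state
    g_t = o_t . tanh(y_t)                        hidden state

Three named architectures are provided: LSTM_1 (1 layer x 32 cells),
LSTM_2 (1 x 128) and LSTM_3 (2 x 128).  The classification head is a
30-unit ReLU dense layer followed by a 2-unit softmax; training minimizes
cross-entropy with Adam (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8,
decay 0) on mini-batches of 10 for 10 epochs by default.  Dropout layers
(rate 0.2 by default) sit after every recurrent layer during training only.

Everything — forward pass, backpropagation through time, Adam — is
implemented in NumPy, so training is exactly reproducible from the seed.
:class:`LstmSequenceClassifier` follows the sklearn estimator contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``) and accepts
``X`` of shape (n_sequences, L, n_features).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

ARCHITECTURES: dict[str, tuple[int, int]] = {
    "LSTM_1": (1, 32),
    "LSTM_2": (1, 128),
    "LSTM_3": (2, 128),
}

HEAD_UNITS = 30
N_CLASSES = 2


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# Single-cell recurrence (reference form, one gate matrix per gate)
# --------------------------------------------------------------------------

@dataclass
class LstmWeights:
    """Per-gate weight matrices applied to ``[g_prev, x_t]`` plus biases."""

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    a_i: np.ndarray
    a_f: np.ndarray
    a_o: np.ndarray
    a_c: np.ndarray


def lstm_cell_step(
    x_t: np.ndarray, g_prev: np.ndarray, y_prev: np.ndarray, w: LstmWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gate recurrence; returns (g_t, y_t).

    Shapes: ``x_t`` (d,), ``g_prev``/``y_prev`` (h,), each gate matrix
    (h, h + d).
    """
    x_t = np.asarray(x_t, float)
    g_prev = np.asarray(g_prev, float)
    y_prev = np.asarray(y_prev, float)
    h = g_prev.size
    if w.w_i.shape != (h, h + x_t.size) or y_prev.size != h:
        raise ValueError("inconsistent weight/state shapes")
    z = np.concatenate([g_prev, x_t])
    i = _sigmoid(w.w_i @ z + w.a_i)
    f = _sigmoid(w.w_f @ z + w.a_f)
    o = _sigmoid(w.w_o @ z + w.a_o)
    ybar = np.tanh(w.w_c @ z + w.a_c)
    y_t = f * y_prev + i * ybar
    g_t = o * np.tanh(y_t)
    return g_t, y_t


# --------------------------------------------------------------------------
# Model configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Network and training hyperparameters.

    Either name one of the three architectures or give explicit
    ``n_layers``/``hidden`` (layers in {1, 2}, hidden in {32, 128}).
    """

    architecture: str | None = "LSTM_1"
    n_layers: int | None = None
    hidden: int | None = None
    dropout_rate: float = 0.2
    sequence_length: int = 10
    batch_size: int = 10
    epochs: int = 10
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    standardize: bool = True
    seed: int = 0

    def resolve(self) -> tuple[int, int]:
        """Return (n_layers, hidden), validating the design space."""
        if self.architecture is not None:
            if self.architecture not in ARCHITECTURES:
                raise ValueError(
                    f"unknown architecture {self.architecture!r}; "
                    f"choose from {sorted(ARCHITECTURES)}"
                )
            return ARCHITECTURES[self.architecture]
        if self.n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 or 2")
        if self.hidden not in (32, 128):
            raise ValueError("hidden size must be 32 or 128")
        return self.n_layers, self.hidden

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 1 <= self.sequence_length <= 50:
            raise ValueError("sequence_length must be in [1, 50]")
        self.resolve()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# Estimator
# --------------------------------------------------------------------------

class LstmSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Gated-recurrence sequence classifier with a ReLU(30) + softmax(2) head.

    Parameters mirror :class:`ModelConfig`; fitted attributes follow the
    sklearn trailing-underscore convention (``classes_``, ``loss_trace_``,
    ``n_parameters_``, ...).  Dropout is active only inside :meth:`fit`.
    """

    def __init__(
        self,
        architecture: str | None = "LSTM_1",
        n_layers: int | None = None,
        hidden: int | None = None,
        dropout_rate: float = 0.2,
        batch_size: int = 10,
        epochs: int = 10,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
        decay: float = 0.0,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.architecture = architecture
        self.n_layers = n_layers
        self.hidden = hidden
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.decay = decay
        self.standardize = standardize
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _layout(self) -> tuple[int, int]:
        cfg = ModelConfig(
            architecture=self.architecture,
            n_layers=self.n_layers,
            hidden=self.hidden,
            dropout_rate=self.dropout_rate,
        )
        return cfg.resolve()

    def initialize(self, input_dim: int) -> "LstmSequenceClassifier":
        """Allocate weights (Glorot uniform; forget-gate bias 1) from seed."""
        if input_dim < 1:
            raise ValueError("input_dim must be positive")
        n_layers, h = self._layout()
        rng = np.random.default_rng(self.seed)

        def glorot(fan_out: int, fan_in: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_out, fan_in))

        self.layers_ = []
        d = input_dim
        for _ in range(n_layers):
            W = np.vstack([glorot(h, h + d) for _ in range(4)])  # i, f, o, c
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias: remember by default
            self.layers_.append({"W": W, "b": b})
            d = h
        self.head_ = {
            "W1": glorot(HEAD_UNITS, h),
            "b1": np.zeros(HEAD_UNITS),
            "W2": glorot(N_CLASSES, HEAD_UNITS),
            "b2": np.zeros(N_CLASSES),
        }
        self.n_features_in_ = input_dim
        self.hidden_size_ = h
        self.n_layers_ = n_layers
        self.n_parameters_ = sum(
            p.size for lay in self.layers_ for p in lay.values()
        ) + sum(p.size for p in self.head_.values())
        return self

    # -- forward ------------------------------------------------------------

    def _forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Run the stacked recurrence; returns probabilities and caches."""
        B, L, _ = X.shape
        h = self.hidden_size_
        caches = []
        inputs = X
        for lay in self.layers_:
            W, b = lay["W"], lay["b"]
            g = np.zeros((B, h))
            y = np.zeros((B, h))
            steps = []
            outs = np.empty((B, L, h))
            for t in range(L):
                z = np.concatenate([g, inputs[:, t, :]], axis=1)
                pre = z @ W.T + b
                i_g = _sigmoid(pre[:, :h])
                f_g = _sigmoid(pre[:, h : 2 * h])
                o_g = _sigmoid(pre[:, 2 * h : 3 * h])
                ybar = np.tanh(pre[:, 3 * h :])
                y = f_g * y + i_g * ybar
                tanh_y = np.tanh(y)
                g = o_g * tanh_y
                steps.append(
                    {"z": z, "i": i_g, "f": f_g, "o": o_g, "ybar": ybar,
                     "y_prev": steps[-1]["y"] if steps else np.zeros((B, h)),
                     "y": y, "tanh_y": tanh_y}
                )
                outs[:, t, :] = g
            if train and self.dropout_rate > 0:
                mask = (
                    rng.random(outs.shape) >= self.dropout_rate
                ) / (1.0 - self.dropout_rate)
                dropped = outs * mask
            else:
                mask = None
                dropped = outs
            caches.append({"steps": steps, "outs": outs, "mask": mask,
                           "inputs": inputs})
            inputs = dropped
        last = inputs[:, -1, :]  # top layer output (dropout applied in train)
        a1 = last @ self.head_["W1"].T + self.head_["b1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ self.head_["W2"].T + self.head_["b2"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        proba = expz / expz.sum(axis=1, keepdims=True)
        return {"caches": caches, "last": last, "a1": a1, "r1": r1,
                "proba": proba}

    # -- backward -----------------------------------------------------------

    def _backward(self, X: np.ndarray, y01: np.ndarray, fwd: dict) -> dict:
        B, L, _ = X.shape
        h = self.hidden_size_
        grads: dict[str, np.ndarray] = {}

        dlogits = fwd["proba"].copy()
        dlogits[np.arange(B), y01] -= 1.0
        dlogits /= B
        grads["head.W2"] = dlogits.T @ fwd["r1"]
        grads["head.b2"] = dlogits.sum(axis=0)
        dr1 = dlogits @ self.head_["W2"]
        da1 = dr1 * (fwd["a1"] > 0)
        grads["head.W1"] = da1.T @ fwd["last"]
        grads["head.b1"] = da1.sum(axis=0)
        dlast = da1 @ self.head_["W1"]

        # external gradient on each layer's (pre-dropout) output per timestep
        n_layers = len(self.layers_)
        d_ext = [np.zeros((B, L, h)) for _ in range(n_layers)]
        top_cache = fwd["caches"][-1]
        if top_cache["mask"] is not None:
            d_ext[-1][:, -1, :] = dlast * top_cache["mask"][:, -1, :]
        else:
            d_ext[-1][:, -1, :] = dlast

        for li in range(n_layers - 1, -1, -1):
            cache = fwd["caches"][li]
            W = self.layers_[li]["W"]
            dW = np.zeros_like(W)
            db = np.zeros_like(self.layers_[li]["b"])
            dg_carry = np.zeros((B, h))
            dy_carry = np.zeros((B, h))
            d_in = np.zeros_like(cache["inputs"])
            for t in range(L - 1, -1, -1):
                st = cache["steps"][t]
                dg = dg_carry + d_ext[li][:, t, :]
                do = dg * st["tanh_y"]
                dy = dy_carry + dg * st["o"] * (1.0 - st["tanh_y"] ** 2)
                di = dy * st["ybar"]
                dybar = dy * st["i"]
                df = dy * st["y_prev"]
                dy_carry = dy * st["f"]
                dpre = np.concatenate(
                    [
                        di * st["i"] * (1 - st["i"]),
                        df * st["f"] * (1 - st["f"]),
                        do * st["o"] * (1 - st["o"]),
                        dybar * (1 - st["ybar"] ** 2),
                    ],
                    axis=1,
                )
                dW += dpre.T @ st["z"]
                db += dpre.sum(axis=0)
                dz = dpre @ W
                dg_carry = dz[:, :h]
                d_in[:, t, :] = dz[:, h:]
            grads[f"layer{li}.W"] = dW
            grads[f"layer{li}.b"] = db
            if li > 0:
                below = fwd["caches"][li - 1]
                if below["mask"] is not None:
                    d_ext[li - 1] += d_in * below["mask"]
                else:
                    d_ext[li - 1] += d_in
        return grads

    # -- parameter bookkeeping ---------------------------------------------

    def _params_flat(self) -> dict[str, np.ndarray]:
        out = {}
        for li, lay in enumerate(self.layers_):
            out[f"layer{li}.W"] = lay["W"]
            out[f"layer{li}.b"] = lay["b"]
        for k, v in self.head_.items():
            out[f"head.{k}"] = v
        return out

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LstmSequenceClassifier":
        """Train with Adam on mini-batches; deterministic under ``seed``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_sequences, L, n_features)")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"need exactly two classes, got {self.classes_.tolist()}"
            )
        y01 = np.searchsorted(self.classes_, y)

        if self.standardize:
            flat = X.reshape(-1, X.shape[-1])
            self.scaler_mean_ = flat.mean(axis=0)
            scale = flat.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.scaler_scale_ = scale
            X = (X - self.scaler_mean_) / self.scaler_scale_
        else:
            self.scaler_mean_ = None
            self.scaler_scale_ = None

        self.initialize(X.shape[-1])
        rng = np.random.default_rng(self.seed + 1)  # batching/dropout stream
        params = self._params_flat()
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(vv) for k, vv in params.items()}
        step = 0
        n = X.shape[0]
        self.loss_trace_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for b0 in range(0, n, self.batch_size):
                idx = order[b0 : b0 + self.batch_size]
                Xb, yb = X[idx], y01[idx]
                fwd = self._forward(Xb, train=True, rng=rng)
                p = fwd["proba"][np.arange(len(idx)), yb]
                epoch_losses.append(float(-np.mean(np.log(p + 1e-12))))
                grads = self._backward(Xb, yb, fwd)
                step += 1
                lr = self.learning_rate / (1.0 + self.decay * step)
                for k, g in grads.items():
                    m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                    v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                    mhat = m[k] / (1 - self.beta1**step)
                    vhat = v[k] / (1 - self.beta2**step)
                    params[k] -= lr * mhat / (np.sqrt(vhat) + self.epsilon)
            self.loss_trace_.append(float(np.mean(epoch_losses)))
        return self

    # -- inference ----------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "layers_"):
            raise ValueError("model is not fitted/initialized")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X must have shape (n, L, {self.n_features_in_})"
            )
        if self.scaler_mean_ is not None:
            X = (X - self.scaler_mean_) / self.scaler_scale_
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, columns ordered as ``classes_``."""
        X = self._check_input(X)
        out = np.empty((X.shape[0], N_CLASSES))
        chunk = 256
        for b0 in range(0, X.shape[0], chunk):
            out[b0 : b0 + chunk] = self._forward(X[b0 : b0 + chunk])["proba"]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar of the configuration."""
        path = Path(path)
        arrays = dict(self._params_flat())
        arrays["classes"] = self.classes_
        if self.scaler_mean_ is not None:
            arrays["scaler_mean"] = self.scaler_mean_
            arrays["scaler_scale"] = self.scaler_scale_
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.get_params(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LstmSequenceClassifier":
        path = Path(path)
        params = json.loads(path.with_suffix(".json").read_text())
        model = cls(**params)
        data = np.load(path if path.suffix else path.with_suffix(".npz"),
                       allow_pickle=False)
        n_layers, h = model._layout()
        input_dim = data["layer0.W"].shape[1] - h
        model.initialize(input_dim)
        for li in range(n_layers):
            model.layers_[li]["W"] = data[f"layer{li}.W"]
            model.layers_[li]["b"] = data[f"layer{li}.b"]
        for k in ("W1", "b1", "W2", "b2"):
            model.head_[k] = data[f"head.{k}"]
        model.classes_ = data["classes"]
        if "scaler_mean" in data:
            model.scaler_mean_ = data["scaler_mean"]
            model.scaler_scale_ = data["scaler_scale"]
        else:
            model.scaler_mean_ = model.scaler_scale_ = None
        return model


def expected_parameter_count(
    input_dim: int, hidden: int, n_layers: int
) -> int:
    """Analytic parameter count: 4(h(h+d)+h) per layer plus the dense head."""
    total = 0
    d = input_dim
    for _ in range(n_layers):
        total += 4 * (hidden * (hidden + d) + hidden)
        d = hidden
    total += HEAD_UNITS * hidden + HEAD_UNITS
    total += N_CLASSES * HEAD_UNITS + N_CLASSES
    return total


def build_model(cfg: ModelConfig, input_dim: int) -> LstmSequenceClassifier:
    """Untrained classifier for ``cfg`` with weights allocated (so the
    parameter count is reported immediately)."""
    model = LstmSequenceClassifier(
        architecture=cfg.architecture,
        n_layers=cfg.n_layers,
        hidden=cfg.hidden,
        dropout_rate=cfg.dropout_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        epsilon=cfg.epsilon,
        decay=cfg.decay,
        standardize=cfg.standardize,
        seed=cfg.seed,
    )
    model.initialize(input_dim)
    return model
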