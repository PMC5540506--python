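"""A small 1-D convolutional network over boolean fragment vectors.

Architecture: two valid (no padding, stride 1) convolution layers with
logistic activations, each followed by width-2 non-overlapping max-pooling,
then a one-hidden-layer perceptron (tanh hidden units, softmax output),
trained by mini-batch stochastic gradient descent on the categorical
cross-entropy.  The first layer slides ``n1`` kernels of width ``k1`` over
the binary input vector; the second operates on the ``n1``-channel pooled
output with ``n2`` multi-channel kernels of width ``k2``.

Everything is plain numpy: forward, backward and the update rule are
written out explicitly and the analytic gradients are verified against
central finite differences in the test suite.  All randomness (weight
initialisation, epoch shuffling) is driven by a single integer seed, so a
given (data, config) pair always yields bit-identical weights.

Default hyper-parameters: k1 = k2 = 5 kernels, n1 = 10 and n2 = 20 feature
maps, pool width fixed at 2, 500 hidden units.  Odd-length vectors lose
their trailing element under pooling (floor semantics).  With binary inputs
a width-k kernel can meet at most 2^k - 1 distinct nonzero bit patterns,
which bounds the number of genuinely distinct first-layer kernels (31 for
k = 5); ``n1`` stays well below that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .features import FeatureMatrix

__all__ = [
    "CnnConfig",
    "TrainedModel",
    "conv_layer_forward",
    "max_pool",
    "forward",
    "train",
    "predict",
    "save_model",
    "load_model",
]


def _logistic(z: np.ndarray) -> np.ndarray:
    return expit(z)


@dataclass(frozen=True)
class CnnConfig:
    """Network shape and SGD hyper-parameters.

    ``input_length``/``n_classes`` may be left None in a template and are
    resolved when training starts (e.g. per cross-validation fold, where
    the feature count varies).
    """

    input_length: int | None = None
    n_classes: int | None = None
    k1: int = 5
    n1: int = 10
    k2: int = 5
    n2: int = 20
    pool: int = 2
    hidden: int = 500
    learning_rate: float = 0.1
    batch_size: int = 20
    epochs: int = 200
    seed: int = 0
    dtype: str = "float64"  # arithmetic precision for training and inference

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        for name in ("k1", "n1", "k2", "n2", "hidden", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.pool != 2:
            raise ValueError("pool width is fixed at 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.input_length is not None:
            self.dims()  # raises if the chain collapses

    def resolved(self, input_length: int, n_classes: int) -> "CnnConfig":
        return replace(self, input_length=input_length, n_classes=n_classes)

    def dims(self) -> dict[str, int]:
        """The deterministic dimension chain L -> conv -> pool -> conv -> pool."""
        L = self.input_length
        if L is None:
            raise ValueError("input_length not set")
        if L < self.k1:
            raise ValueError(f"input_length {L} < first kernel width {self.k1}")
        l1 = L - self.k1 + 1
        p1 = l1 // self.pool
        if p1 < self.k2:
            raise ValueError(
                f"pooled length {p1} < second kernel width {self.k2}; "
                f"input_length {L} is too small for this architecture"
            )
        l2 = p1 - self.k2 + 1
        p2 = l2 // self.pool
        if p2 < 1:
            raise ValueError("second pooled length is zero")
        return {
            "conv1": l1,
            "pool1": p1,
            "conv2": l2,
            "pool2": p2,
            "flat": self.n2 * p2,
        }


@dataclass
class TrainedModel:
    """CNN weights plus the frozen feature space and class order."""

    config: CnnConfig
    W1: np.ndarray  # (n1, k1)
    b1: np.ndarray  # (n1,)
    W2: np.ndarray  # (n2, n1, k2)
    b2: np.ndarray  # (n2,)
    M1: np.ndarray  # (flat, hidden)
    c1: np.ndarray  # (hidden,)
    M2: np.ndarray  # (hidden, n_classes)
    c2: np.ndarray  # (n_classes,)
    class_labels: tuple[str, ...] = ()
    fragment_codes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def conv_layer_forward(
    x: np.ndarray, kernels: np.ndarray, biases: np.ndarray
) -> np.ndarray:
    """Valid cross-correlation (stride 1) followed by the logistic function.

    ``x`` is a single input: shape (L,) for the first layer, or (C, L) for a
    multi-channel layer whose kernels have shape (n, C, k) and sum the
    channel contributions before bias and activation.  Returns (n, L-k+1).
    """
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim == 1:
        if kernels.ndim != 2:
            raise ValueError("1-D input expects kernels of shape (n, k)")
        k = kernels.shape[1]
        if x.shape[0] < k:
            raise ValueError(f"input length {x.shape[0]} < kernel width {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k)  # (L-k+1, k)
        z = np.einsum("tk,ik->it", windows, kernels) + np.asarray(biases)[:, None]
        return _logistic(z)
    if x.ndim == 2:
        if kernels.ndim != 3 or kernels.shape[1] != x.shape[0]:
            raise ValueError("multi-channel input expects kernels of shape (n, C, k)")
        k = kernels.shape[2]
        if x.shape[1] < k:
            raise ValueError(f"input length {x.shape[1]} < kernel width {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (C, L-k+1, k)
        z = np.einsum("ltk,jlk->jt", windows, kernels) + np.asarray(biases)[:, None]
        return _logistic(z)
    raise ValueError("input must be 1-D or 2-D")


def max_pool(f: np.ndarray, pool: int = 2) -> np.ndarray:
    """Non-overlapping max-pooling along the last axis; trailing remainder
    dropped (floor length).  A length-1 input yields an empty vector."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] == 0:
        raise ValueError("cannot pool an empty vector")
    p = f.shape[-1] // pool
    trimmed = f[..., : p * pool]
    return trimmed.reshape(*f.shape[:-1], p, pool).max(axis=-1)


# ---------------------------------------------------------------------------
# batched forward / backward
# ---------------------------------------------------------------------------

def _forward_batch(model: TrainedModel, X: np.ndarray, want_cache: bool = False):
    cfg = model.config
    B = X.shape[0]
    win1 = np.lib.stride_tricks.sliding_window_view(X, cfg.k1, axis=1)  # (B, L1, k1)
    z1 = (win1 @ model.W1.T).transpose(0, 2, 1) + model.b1[None, :, None]
    a1 = _logistic(z1)  # (B, n1, L1)
    p1 = a1.shape[2] // 2
    a1t = a1[:, :, : 2 * p1].reshape(B, cfg.n1, p1, 2)
    idx1 = a1t[..., 1] > a1t[..., 0]  # True where the right element wins
    v1 = np.where(idx1, a1t[..., 1], a1t[..., 0])  # (B, n1, P1)

    win2 = np.lib.stride_tricks.sliding_window_view(v1, cfg.k2, axis=2)  # (B, n1, L2, k2)
    L2 = win2.shape[2]
    # contract channel and kernel axes with one gemm: (B*L2, n1*k2) @ (n1*k2, n2)
    win2_flat = np.ascontiguousarray(win2.transpose(0, 2, 1, 3)).reshape(
        B * L2, cfg.n1 * cfg.k2
    )
    z2 = (
        (win2_flat @ model.W2.reshape(cfg.n2, -1).T)
        .reshape(B, L2, cfg.n2)
        .transpose(0, 2, 1)
    ) + model.b2[None, :, None]
    a2 = _logistic(z2)  # (B, n2, L2)
    p2 = a2.shape[2] // 2
    a2t = a2[:, :, : 2 * p2].reshape(B, cfg.n2, p2, 2)
    idx2 = a2t[..., 1] > a2t[..., 0]
    v2 = np.where(idx2, a2t[..., 1], a2t[..., 0])  # (B, n2, P2)

    y = v2.reshape(B, -1)
    h = np.tanh(y @ model.M1 + model.c1)
    o = h @ model.M2 + model.c2
    o = o - o.max(axis=1, keepdims=True)
    eo = np.exp(o)
    probs = eo / eo.sum(axis=1, keepdims=True)
    if not want_cache:
        return probs
    return probs, {
        "X": X, "win1": win1, "a1": a1, "idx1": idx1, "v1": v1,
        "win2_flat": win2_flat, "a2": a2, "idx2": idx2, "y": y, "h": h,
    }


def _loss_and_grads(model: TrainedModel, X: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch and gradients for every parameter."""
    cfg = model.config
    B = X.shape[0]
    probs, cache = _forward_batch(model, X, want_cache=True)
    loss = -np.mean(np.log(probs[np.arange(B), targets] + 1e-300))

    T = np.zeros_like(probs)
    T[np.arange(B), targets] = 1.0
    do = (probs - T) / B  # (B, C)
    h, y = cache["h"], cache["y"]
    gM2 = h.T @ do
    gc2 = do.sum(axis=0)
    dh = (do @ model.M2.T) * (1.0 - h**2)
    gM1 = y.T @ dh
    gc1 = dh.sum(axis=0)
    dy = dh @ model.M1.T  # (B, flat)

    a2, idx2 = cache["a2"], cache["idx2"]
    p2 = a2.shape[2] // 2
    dv2 = dy.reshape(B, cfg.n2, p2)
    da2t = np.empty((B, cfg.n2, p2, 2), dtype=a2.dtype)
    da2t[..., 0] = np.where(idx2, 0.0, dv2)
    da2t[..., 1] = np.where(idx2, dv2, 0.0)
    da2 = np.zeros_like(a2)
    da2[:, :, : 2 * p2] = da2t.reshape(B, cfg.n2, 2 * p2)
    dz2 = da2 * a2 * (1.0 - a2)  # (B, n2, L2)

    win2_flat = cache["win2_flat"]  # (B*L2, n1*k2)
    L2 = dz2.shape[2]
    dz2_flat = np.ascontiguousarray(dz2.transpose(0, 2, 1)).reshape(B * L2, cfg.n2)
    gW2 = (dz2_flat.T @ win2_flat).reshape(cfg.n2, cfg.n1, cfg.k2)
    gb2 = dz2.sum(axis=(0, 2))

    v1 = cache["v1"]
    dv1 = np.zeros_like(v1)  # (B, n1, P1)
    for u in range(cfg.k2):
        # (B, L2, n2) @ (n2, n1) -> contribution to v1 positions u..u+L2
        dv1[:, :, u : u + L2] += (
            dz2_flat @ model.W2[:, :, u]
        ).reshape(B, L2, cfg.n1).transpose(0, 2, 1)

    a1, idx1 = cache["a1"], cache["idx1"]
    p1 = a1.shape[2] // 2
    da1t = np.empty((B, cfg.n1, p1, 2), dtype=a1.dtype)
    da1t[..., 0] = np.where(idx1, 0.0, dv1)
    da1t[..., 1] = np.where(idx1, dv1, 0.0)
    da1 = np.zeros_like(a1)
    da1[:, :, : 2 * p1] = da1t.reshape(B, cfg.n1, 2 * p1)
    dz1 = da1 * a1 * (1.0 - a1)  # (B, n1, L1)

    win1 = cache["win1"]  # (B, L1, k1)
    L1 = dz1.shape[2]
    dz1_flat = np.ascontiguousarray(dz1.transpose(0, 2, 1)).reshape(B * L1, cfg.n1)
    gW1 = dz1_flat.T @ win1.reshape(B * L1, cfg.k1)
    gb1 = dz1.sum(axis=(0, 2))

    grads = {
        "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
        "M1": gM1, "c1": gc1, "M2": gM2, "c2": gc2,
    }
    return loss, grads


def _init_model(
    config: CnnConfig,
    class_labels: Sequence[str],
    fragment_codes: Sequence[str],
    rng: np.random.Generator,
) -> TrainedModel:
    dims = config.dims()

    dt = np.dtype(config.dtype)

    def uniform(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape).astype(dt)

    return TrainedModel(
        config=config,
        W1=uniform((config.n1, config.k1), config.k1),
        b1=np.zeros(config.n1, dtype=dt),
        W2=uniform((config.n2, config.n1, config.k2), config.n1 * config.k2),
        b2=np.zeros(config.n2, dtype=dt),
        M1=uniform((dims["flat"], config.hidden), dims["flat"]),
        c1=np.zeros(config.hidden, dtype=dt),
        M2=uniform((config.hidden, config.n_classes), config.hidden),
        c2=np.zeros(config.n_classes, dtype=dt),
        class_labels=tuple(class_labels),
        fragment_codes=tuple(fragment_codes),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def forward(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Class probability vector for one boolean feature vector."""
    x = np.asarray(x, dtype=model.W1.dtype)
    L = model.config.input_length
    if x.shape != (L,):
        raise ValueError(f"expected input of length {L}, got shape {x.shape}")
    return _forward_batch(model, x[None, :])[0]


def train(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    config: CnnConfig | None = None,
    class_order: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the CNN by seeded mini-batch SGD on categorical cross-entropy."""
    X = np.asarray(matrix.values, dtype=float)
    if X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("feature matrix values must be boolean (0/1)")
    if len(labels) != X.shape[0]:
        raise ValueError(
            f"got {len(labels)} labels for {X.shape[0]} matrix rows"
        )
    if class_order is None:
        class_order = sorted(set(labels))
    class_index = {c: i for i, c in enumerate(class_order)}
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    counts = {c: 0 for c in class_order}
    for lab in labels:
        counts[lab] += 1
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"classes with zero examples: {empty}")
    targets = np.asarray([class_index[lab] for lab in labels])

    if config is None:
        config = CnnConfig()
    config = config.resolved(X.shape[1], len(class_order))
    X = X.astype(config.dtype)

    rng = np.random.default_rng(config.seed)
    model = _init_model(config, class_order, matrix.fragment_codes, rng)
    n = X.shape[0]
    lr = config.learning_rate
    params = ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2")
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = perm[start : start + config.batch_size]
            _loss, grads = _loss_and_grads(model, X[batch], targets[batch])
            for name in params:
                getattr(model, name).__isub__(lr * grads[name])
    return model


def predict(
    model: TrainedModel, matrix: FeatureMatrix
) -> tuple[list[str], np.ndarray]:
    """Argmax class per row plus full probability rows.

    Ties go to the lowest class index.  The matrix column order must match
    the model's frozen feature space exactly.
    """
    if matrix.fragment_codes != model.fragment_codes:
        raise ValueError(
            f"feature space mismatch: model expects {len(model.fragment_codes)} "
            f"fragments, matrix has {len(matrix.fragment_codes)} "
            f"(or the column order differs)"
        )
    X = np.asarray(matrix.values, dtype=model.W1.dtype)
    if X.shape[0] == 0:
        return [], np.zeros((0, model.config.n_classes))
    probs = _forward_batch(model, X)
    pred = [model.class_labels[i] for i in probs.argmax(axis=1)]
    return pred, probs


# ---------------------------------------------------------------------------
# serialization (plain JSON, bit-exact round trip via float repr)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format": "ncstruct model v1",
        "config": {
            k: getattr(model.config, k)
            for k in (
                "input_length", "n_classes", "k1", "n1", "k2", "n2", "pool",
                "hidden", "learning_rate", "batch_size", "epochs", "seed", "dtype",
            )
        },
        "class_labels": list(model.class_labels),
        "fragment_codes": list(model.fragment_codes),
        "weights": {
            name: getattr(model, name).tolist()
            for name in ("W1", "b1", "W2", "b2", "M1", "c1", "M2", "c2")
        },
    }
    with open(path, "w") as handle:
        json.dump(payload, handle)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("format") != "ncstruct model v1":
        raise ValueError(f"{path}: not an ncstruct model file")
    cfg = CnnConfig(**payload["config"])
    w = payload["weights"]
    dt = np.dtype(cfg.dtype)
    return TrainedModel(
        config=cfg,
        W1=np.asarray(w["W1"], dtype=dt), b1=np.asarray(w["b1"], dtype=dt),
        W2=np.asarray(w["W2"], dtype=dt), b2=np.asarray(w["b2"], dtype=dt),
        M1=np.asarray(w["M1"], dtype=dt), c1=np.asarray(w["c1"], dtype=dt),
        M2=np.asarray(w["M2"], dtype=dt), c2=np.asarray(w["c2"], dtype=dt),
        class_labels=tuple(payload["class_labels"]),
        fragment_codes=tuple(payload["fragment_codes"]),
    )
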