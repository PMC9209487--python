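"""Mirrored dense autoencoder over scaled heavy-atom coordinates.

The encoder maps a flattened conformation (3N coordinates scaled into [0, 1])
through dense layers of 300 and 50 rectified-linear units to an n-dimensional
latent vector, itself rectified-linear; the decoder mirrors the encoder
(n -> 50 -> 300 -> 3N) and ends in a sigmoid so outputs stay in (0, 1).
Training minimises the per-coordinate binary cross-entropy

    H = (1/3N) sum_i [ -y_i ln y_i' - (1 - y_i) ln(1 - y_i') ]

(mean squared error is available as an alternative) with the Adam optimizer,
by default for 100 epochs at batch size 40.  Everything is implemented in
NumPy with explicit backpropagation; given a seed, training is bit-for-bit
reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "AutoencoderModel",
    "latent_dim_rule",
    "bce_loss",
    "mse_loss",
    "train",
    "encode",
    "decode",
    "save_model",
    "load_model",
]

_EPS = 1e-7  # clamp for sigmoid outputs entering the logarithm


def latent_dim_rule(n_res: int) -> int:
    """Latent-space dimension for a chain of ``n_res`` residues.

    Uses n = 0.75 * n_res rounded to the nearest integer, half-values up:
    17 residues -> 13, 40 -> 30, 64 -> 48.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    return int(np.floor(0.75 * n_res + 0.5))


@dataclass(frozen=True)
class NetworkSpec:
    """Layer dimensions of the mirrored autoencoder."""

    input_dim: int
    latent_dim: int
    hidden_dims: tuple[int, ...] = (300, 50)

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.input_dim % 3 != 0:
            raise ValueError("input_dim must be divisible by 3 (x, y, z per atom)")
        object.__setattr__(self, "hidden_dims", tuple(int(h) for h in self.hidden_dims))

    @property
    def encoder_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_dims, self.latent_dim)

    @property
    def decoder_dims(self) -> tuple[int, ...]:
        return (self.latent_dim, *reversed(self.hidden_dims), self.input_dim)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 40
    loss: str = "binary_cross_entropy"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("binary_cross_entropy", "mean_squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class AutoencoderModel:
    """Trained (or freshly initialised) autoencoder.

    ``weights``/``biases`` run encoder-first then decoder; layer k computes
    ``a_k = act(a_{k-1} @ W_k + b_k)`` with rectified-linear activations on
    every layer except the final sigmoid output.
    """

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_history: list[float] = field(default_factory=list)
    config: TrainingConfig | None = None

    @property
    def n_encoder_layers(self) -> int:
        return len(self.spec.encoder_dims) - 1

    def __eq__(self, other):  # weight-level equality, used by round-trip tests
        if not isinstance(other, AutoencoderModel):
            return NotImplemented
        return (
            self.spec == other.spec
            and all(np.array_equal(a, b) for a, b in zip(self.weights, other.weights))
            and all(np.array_equal(a, b) for a, b in zip(self.biases, other.biases))
        )


def initialize_model(spec: NetworkSpec, rng: np.random.Generator) -> AutoencoderModel:
    """Glorot-uniform initialisation of all layers, zero biases."""
    dims = list(spec.encoder_dims) + list(spec.decoder_dims[1:])
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return AutoencoderModel(spec=spec, weights=weights, biases=biases)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_loss(y: np.ndarray, y_prime: np.ndarray) -> float:
    """Per-coordinate binary cross-entropy between targets in [0, 1] and
    outputs in (0, 1), averaged over the 3N coordinates (and over rows for
    2-D input)."""
    y = np.asarray(y, dtype=float)
    y_prime = np.asarray(y_prime, dtype=float)
    if y.shape != y_prime.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_prime.shape}")
    yp = np.clip(y_prime, _EPS, 1.0 - _EPS)
    h = -y * np.log(yp) - (1.0 - y) * np.log(1.0 - yp)
    return float(h.mean())


def mse_loss(y: np.ndarray, y_prime: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_prime = np.asarray(y_prime, dtype=float)
    if y.shape != y_prime.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_prime.shape}")
    return float(((y - y_prime) ** 2).mean())


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _forward(model: AutoencoderModel, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer; last layer is sigmoid, the rest ReLU."""
    acts = [x]
    n_layers = len(model.weights)
    a = x
    for k, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        if k == n_layers - 1:
            a = 1.0 / (1.0 + np.exp(-z))
        else:
            a = np.maximum(z, 0.0)
        acts.append(a)
    return acts


def encode(model: AutoencoderModel, scaled_coords: np.ndarray) -> np.ndarray:
    """Latent vectors (K x n) for scaled conformations (K x 3N).

    The latent layer is rectified-linear, so entries are non-negative;
    dimensions whose units never fire stay at exactly zero.
    """
    x = np.atleast_2d(np.asarray(scaled_coords, dtype=float))
    if x.shape[1] != model.spec.input_dim:
        raise ValueError(f"expected input dim {model.spec.input_dim}, got {x.shape[1]}")
    a = x
    for w, b in zip(
        model.weights[: model.n_encoder_layers], model.biases[: model.n_encoder_layers]
    ):
        a = np.maximum(a @ w + b, 0.0)
    return a


def decode(model: AutoencoderModel, latent_vectors: np.ndarray) -> np.ndarray:
    """Scaled coordinates (K x 3N) decoded from latent vectors (K x n)."""
    z = np.atleast_2d(np.asarray(latent_vectors, dtype=float))
    if z.shape[1] != model.spec.latent_dim:
        raise ValueError(f"expected latent dim {model.spec.latent_dim}, got {z.shape[1]}")
    a = z
    ws = model.weights[model.n_encoder_layers :]
    bs = model.biases[model.n_encoder_layers :]
    for k, (w, b) in enumerate(zip(ws, bs)):
        zlin = a @ w + b
        a = 1.0 / (1.0 + np.exp(-zlin)) if k == len(ws) - 1 else np.maximum(zlin, 0.0)
    return a


def reconstruct(model: AutoencoderModel, scaled_coords: np.ndarray) -> np.ndarray:
    return decode(model, encode(model, scaled_coords))


def _backward(
    model: AutoencoderModel, acts: list[np.ndarray], y: np.ndarray, loss: str
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the mean loss w.r.t. every weight and bias."""
    batch, dim = y.shape
    out = acts[-1]
    # delta at the output pre-activation (sigmoid)
    if loss == "binary_cross_entropy":
        delta = (out - y) / (batch * dim)
    else:  # mean squared error
        delta = 2.0 * (out - y) * out * (1.0 - out) / (batch * dim)
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    for k in range(len(model.weights) - 1, -1, -1):
        grads_w[k] = acts[k].T @ delta
        grads_b[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ model.weights[k].T) * (acts[k] > 0)
    return grads_w, grads_b


def train(
    train_data: np.ndarray,
    spec: NetworkSpec,
    config: TrainingConfig | None = None,
) -> AutoencoderModel:
    """Train the autoencoder on scaled coordinates (rows in [0, 1]^{3N}).

    Rows are shuffled every epoch with the seeded generator; the final
    partial batch is included.  Returns the model with its per-epoch mean
    training loss in ``training_history``.
    """
    config = config or TrainingConfig()
    x = np.asarray(train_data, dtype=float)
    if x.ndim != 2 or x.shape[1] != spec.input_dim:
        raise ValueError(f"training data must be (K, {spec.input_dim})")
    rng = np.random.default_rng(config.seed)
    model = initialize_model(spec, rng)
    model.config = config

    # Adam state
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    t = 0
    lr, b1, b2, eps = config.learning_rate, config.beta1, config.beta2, 1e-8
    loss_fn = bce_loss if config.loss == "binary_cross_entropy" else mse_loss

    n = x.shape[0]
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = x[order[start : start + config.batch_size]]
            acts = _forward(model, batch)
            loss_val = loss_fn(batch, acts[-1])
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}, step offset {start}; "
                    "training aborted"
                )
            epoch_loss += loss_val * batch.shape[0]
            grads_w, grads_b = _backward(model, acts, batch, config.loss)
            t += 1
            corr1 = 1.0 - b1**t
            corr2 = 1.0 - b2**t
            for k in range(len(model.weights)):
                m_w[k] = b1 * m_w[k] + (1 - b1) * grads_w[k]
                v_w[k] = b2 * v_w[k] + (1 - b2) * grads_w[k] ** 2
                model.weights[k] -= lr * (m_w[k] / corr1) / (np.sqrt(v_w[k] / corr2) + eps)
                m_b[k] = b1 * m_b[k] + (1 - b1) * grads_b[k]
                v_b[k] = b2 * v_b[k] + (1 - b2) * grads_b[k] ** 2
                model.biases[k] -= lr * (m_b[k] / corr1) / (np.sqrt(v_b[k] / corr2) + eps)
        history.append(epoch_loss / n)
    model.training_history = history
    return model


# ---------------------------------------------------------------------------
# Serialization: encoder file + decoder file + JSON manifest
# ---------------------------------------------------------------------------

def save_model(model: AutoencoderModel, directory) -> None:
    """Save as ``encoder.npz``/``decoder.npz`` plus ``manifest.json``."""
    os.makedirs(directory, exist_ok=True)
    ne = model.n_encoder_layers
    np.savez(
        os.path.join(directory, "encoder.npz"),
        **{f"W{k}": model.weights[k] for k in range(ne)},
        **{f"b{k}": model.biases[k] for k in range(ne)},
    )
    nd = len(model.weights) - ne
    np.savez(
        os.path.join(directory, "decoder.npz"),
        **{f"W{k}": model.weights[ne + k] for k in range(nd)},
        **{f"b{k}": model.biases[ne + k] for k in range(nd)},
    )
    manifest = {
        "input_dim": model.spec.input_dim,
        "latent_dim": model.spec.latent_dim,
        "hidden_dims": list(model.spec.hidden_dims),
        "training_history": list(map(float, model.training_history)),
        "config": None
        if model.config is None
        else {
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "loss": model.config.loss,
            "learning_rate": model.config.learning_rate,
            "beta1": model.config.beta1,
            "beta2": model.config.beta2,
            "seed": model.config.seed,
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(directory) -> AutoencoderModel:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    spec = NetworkSpec(
        input_dim=manifest["input_dim"],
        latent_dim=manifest["latent_dim"],
        hidden_dims=tuple(manifest["hidden_dims"]),
    )
    weights, biases = [], []
    for fname, n_layers in (
        ("encoder.npz", len(spec.encoder_dims) - 1),
        ("decoder.npz", len(spec.decoder_dims) - 1),
    ):
        with np.load(os.path.join(directory, fname)) as data:
            for k in range(n_layers):
                weights.append(data[f"W{k}"])
                biases.append(data[f"b{k}"])
    model = AutoencoderModel(spec=spec, weights=weights, biases=biases)
    # validate shapes against the manifest dimensions
    dims = list(spec.encoder_dims) + list(spec.decoder_dims[1:])
    for k, w in enumerate(model.weights):
        if w.shape != (dims[k], dims[k + 1]):
            raise ValueError(
                f"layer {k} weight shape {w.shape} inconsistent with dims {dims}"
            )
    model.training_history = manifest.get("training_history", [])
    cfg = manifest.get("config")
    if cfg is not None:
        model.config = TrainingConfig(**cfg)
    return model
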