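"""Noise-prediction MLP trained with the denoising loss.

A three-layer perceptron ``s(x, theta_t; W)`` learns to predict the noise
``delta`` injected into a stored pattern, from the corrupted state
``x = theta_t y + sqrt(1 - theta_t^2) delta``.  Minimizing

    L(W) = E_{theta_t ~ U(a,b), delta ~ N(0,I)} sum_n || delta - s(...) ||^2

drives the network output toward ``-std_t * score``, i.e. toward the exact
mixture score of the stored patterns: the associative dynamics gets encoded
in the synaptic weights rather than in an explicit pattern table.

Architecture: two ReLU hidden layers of ``hidden_units`` each, linear
output of dimension d.  The noise level ``theta_t`` is embedded by
appending it as an extra coordinate to the input of *every* affine layer,
so each weight matrix acts on an (n+1)-dimensional feature space.

The network and its Adam optimizer are implemented directly on numpy
arrays; at these problem sizes (d <= 10, 750 hidden units, batches of a few
dozen patterns) dense matmuls are all that is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import as_rng, as_matrix
from .schedule import DiffusionSchedule

__all__ = ["DenoiserConfig", "DenoiserModel", "init_model", "forward",
           "train", "save_model", "load_model", "denoiser_noise_predictor"]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture and training hyperparameters.

    ``theta_range`` is the sampling interval for the signal fraction during
    training (uniform); ``n_iterations`` counts full-batch Adam steps, one
    fresh (theta, delta) draw per pattern per step.
    """

    hidden_units: int = 750
    n_hidden: int = 2
    theta_range: tuple[float, float] = (0.6, 1.0)
    n_iterations: int = 5000
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1 or self.n_hidden < 1:
            raise ValueError("network must have at least one hidden unit/layer")
        lo, hi = self.theta_range
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("theta_range must satisfy 0 < lo < hi <= 1")


@dataclass
class DenoiserModel:
    """MLP weights plus config; layer l maps (width_l + 1) -> width_{l+1}."""

    weights: list[np.ndarray]   # each (fan_in + 1, fan_out)
    biases: list[np.ndarray]
    d: int
    config: DenoiserConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)


def init_model(d: int, config: DenoiserConfig | None = None) -> DenoiserModel:
    """Seeded He-style initialization of the [d+1 -> h, h+1 -> h, h+1 -> d] stack."""
    if d < 1:
        raise ValueError("d must be at least 1")
    config = config or DenoiserConfig()
    rng = as_rng(config.seed)
    widths = [d] + [config.hidden_units] * config.n_hidden + [d]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / (fan_in + 1))
        weights.append(rng.standard_normal((fan_in + 1, fan_out)) * scale)
        biases.append(np.zeros(fan_out))
    return DenoiserModel(weights=weights, biases=biases, d=d, config=config)


def _append_theta(a, theta):
    theta_col = np.broadcast_to(np.asarray(theta, dtype=float)[..., None],
                                a.shape[:-1] + (1,))
    return np.concatenate([a, theta_col], axis=-1)


def _forward_cached(model, x, theta):
    """Forward pass keeping the augmented activations for backprop."""
    cache = []
    a = np.asarray(x, dtype=float)
    n_layers = len(model.weights)
    for l, (W, b) in enumerate(zip(model.weights, model.biases)):
        aug = _append_theta(a, theta)
        z = aug @ W + b
        a = np.maximum(z, 0.0) if l < n_layers - 1 else z
        cache.append((aug, z))
    return a, cache


def forward(model: DenoiserModel, x, theta_t) -> np.ndarray:
    """Noise prediction for state ``x`` at signal fraction ``theta_t``.

    ``x`` may be ``(d,)`` or ``(batch, d)``; ``theta_t`` is a scalar or a
    per-row array in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.d:
        raise ValueError(f"state dimension {x.shape[-1]} != model d={model.d}")
    th = np.asarray(theta_t, dtype=float)
    if np.any(th <= 0.0) or np.any(th > 1.0):
        raise ValueError("theta_t must lie in (0, 1]")
    out, _ = _forward_cached(model, x, th)
    return out


def _backward(model, cache, grad_out):
    """Gradients of the summed squared-error loss w.r.t. weights and biases."""
    gW = [None] * len(model.weights)
    gb = [None] * len(model.biases)
    g = grad_out
    for l in range(len(model.weights) - 1, -1, -1):
        aug, z = cache[l]
        if l < len(model.weights) - 1:
            g = g * (z > 0.0)
        gW[l] = aug.reshape(-1, aug.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        gb[l] = g.reshape(-1, g.shape[-1]).sum(axis=0)
        if l > 0:
            g = (g @ model.weights[l].T)[..., :-1]  # drop the theta column
    return gW, gb


def train(model: DenoiserModel, Y, config: DenoiserConfig | None = None,
          ) -> DenoiserModel:
    """Train with the denoising loss; returns a new model, input unchanged.

    Each iteration uses the full pattern batch: per pattern a fresh
    ``theta ~ U(theta_range)`` and ``delta ~ N(0, I)`` are drawn, the input
    ``theta y + sqrt(1-theta^2) delta`` formed, and the squared error of the
    noise prediction against ``delta`` (summed over patterns and
    coordinates) is minimized by Adam.  Loss history is recorded per step.
    """
    config = config or model.config
    Y = as_matrix(Y)
    if Y.shape[1] != model.d:
        raise ValueError("pattern dimension does not match model")
    rng = as_rng(config.seed + 1)  # decorrelated from the init stream

    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    out = DenoiserModel(weights=weights, biases=biases, d=model.d,
                        config=config, loss_history=[])
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    lo, hi = config.theta_range
    lr, b1, b2, eps = (config.learning_rate, config.beta1, config.beta2,
                       config.eps)

    for it in range(1, config.n_iterations + 1):
        theta = rng.uniform(lo, hi, size=Y.shape[0])
        delta = rng.standard_normal(Y.shape)
        x = theta[:, None] * Y + np.sqrt(1.0 - theta[:, None] ** 2) * delta
        pred, cache = _forward_cached(out, x, theta)
        resid = pred - delta
        out.loss_history.append(float(np.sum(resid**2)))
        gW, gb = _backward(out, cache, 2.0 * resid)
        corr1 = 1.0 - b1**it
        corr2 = 1.0 - b2**it
        for l in range(len(weights)):
            for g, m, v, p in ((gW[l], mW[l], vW[l], weights[l]),
                               (gb[l], mb[l], vb[l], biases[l])):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g**2
                p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)
    return out


def denoiser_noise_predictor(model: DenoiserModel, schedule: DiffusionSchedule):
    """Adapt a trained model to the samplers' ``f(x, t)`` interface."""

    def predictor(x, t):
        return forward(model, x, schedule.theta(t))

    return predictor


def save_model(path, model: DenoiserModel) -> None:
    """Serialize weights + config to a JSON-with-arrays text file."""
    payload = {
        "d": model.d,
        "config": {
            **{k: getattr(model.config, k)
               for k in ("hidden_units", "n_hidden", "n_iterations",
                         "learning_rate", "beta1", "beta2", "eps", "seed")},
            "theta_range": list(model.config.theta_range),
        },
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "loss_history": model.loss_history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> DenoiserModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    cfg["theta_range"] = tuple(cfg["theta_range"])
    config = DenoiserConfig(**cfg)
    return DenoiserModel(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        d=int(payload["d"]),
        config=config,
        loss_history=[float(v) for v in payload.get("loss_history", [])],
    )
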