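"""Closed-form scores of Gaussian-mixture marginals over a finite pattern set.

When the data distribution is N equiprobable stored patterns, the marginal
density of the noise-injection process is an isotropic Gaussian mixture and
its score (gradient of the log density) is available in closed form:

* VE process (reversed time, data at ``T``): components centred at the
  patterns ``y_n`` with variance ``(T - t)*sigma^2``.
* VP process (forward time, clean at 0): components centred at
  ``theta_t * y_n`` with variance ``sigma^2 (1 - theta_t^2) / (2 alpha)``.

Both scores are softmax-weighted pulls toward the component means, computed
with log-sum-exp stabilization (naive mixture sums underflow at small noise
variance, exactly the retrieval-relevant regime).

All functions broadcast over leading axes: ``x`` may be ``(d,)`` or
``(batch, d)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, softmax

from ._utils import as_matrix
from .schedule import DiffusionSchedule

__all__ = [
    "ve_log_marginal", "ve_score", "vp_log_marginal", "vp_score",
    "score_to_noise_prediction", "noise_prediction_to_score",
    "exact_noise_predictor", "mixture_weights",
]


def _log_weights(x, means, variance):
    """Unnormalized log mixture responsibilities -||x - mu_n||^2 / (2 v)."""
    diff = x[..., None, :] - means          # (..., N, d)
    sq = np.einsum("...nd,...nd->...n", diff, diff)
    return -sq / (2.0 * variance)


def mixture_weights(x, means, variance) -> np.ndarray:
    """Softmax responsibilities of each mixture component at ``x``.

    A probability vector over the N components (nonnegative, sums to 1).
    """
    x = np.asarray(x, dtype=float)
    return softmax(_log_weights(x, as_matrix(means), variance), axis=-1)


def _mixture_log_density(x, means, variance):
    d = means.shape[1]
    lw = _log_weights(x, means, variance)
    norm = 0.5 * d * np.log(2.0 * np.pi * variance)
    return logsumexp(lw, axis=-1) - np.log(means.shape[0]) - norm


def _mixture_score(x, means, variance):
    w = softmax(_log_weights(x, means, variance), axis=-1)
    pull = np.einsum("...n,...nd->...d", w, means - x[..., None, :])
    return pull / variance


def ve_log_marginal(x, t, Y, schedule: DiffusionSchedule) -> np.ndarray:
    """Log marginal density of the VE process at reversed time ``t < T``.

    ``log (1/N) sum_n N(x; y_n, (T-t) sigma^2 I)`` via log-sum-exp.
    """
    x = np.asarray(x, dtype=float)
    v = schedule.ve_variance(t)
    return _mixture_log_density(x, as_matrix(Y), v)


def ve_score(x, t, Y, schedule: DiffusionSchedule) -> np.ndarray:
    """Gradient of ``ve_log_marginal`` in ``x``.

    ``sum_n w_n(x,t) (y_n - x) / ((T-t) sigma^2)`` with softmax weights
    ``w_n`` of ``-||x - y_n||^2 / (2 (T-t) sigma^2)``.
    """
    x = np.asarray(x, dtype=float)
    v = schedule.ve_variance(t)
    return _mixture_score(x, as_matrix(Y), v)


def _vp_variance_checked(t, schedule):
    th = schedule.theta(t)
    if np.any(th >= 1.0):
        raise ValueError("VP score undefined at t=0 (theta_t = 1, zero noise)")
    if np.any(th <= 0.0):
        raise ValueError("theta_t must be positive")
    return schedule.vp_variance(t), th


def vp_log_marginal(x, t, Y, schedule: DiffusionSchedule) -> np.ndarray:
    """Log marginal of the VP process at forward time ``t > 0``.

    Mixture of ``N(theta_t y_n, v_t I)`` with
    ``v_t = sigma^2 (1 - theta_t^2) / (2 alpha)``.
    """
    x = np.asarray(x, dtype=float)
    v, th = _vp_variance_checked(t, schedule)
    return _mixture_log_density(x, th * as_matrix(Y), v)


def vp_score(x, t, Y, schedule: DiffusionSchedule) -> np.ndarray:
    """Gradient of ``vp_log_marginal`` in ``x``."""
    x = np.asarray(x, dtype=float)
    v, th = _vp_variance_checked(t, schedule)
    return _mixture_score(x, th * as_matrix(Y), v)


def score_to_noise_prediction(score, t, schedule: DiffusionSchedule):
    """Convert a VP score into the denoiser's noise-prediction target.

    For ``x = theta_t y + std_t * delta`` the optimal noise prediction is
    ``delta_hat = -std_t * score``; this makes the exact score a drop-in
    replacement for a trained denoiser inside the samplers.
    """
    v, _ = _vp_variance_checked(t, schedule)
    return -np.sqrt(v) * np.asarray(score, dtype=float)


def noise_prediction_to_score(noise_prediction, t, schedule: DiffusionSchedule):
    """Inverse of :func:`score_to_noise_prediction`."""
    v, _ = _vp_variance_checked(t, schedule)
    return -np.asarray(noise_prediction, dtype=float) / np.sqrt(v)


def exact_noise_predictor(Y, schedule: DiffusionSchedule):
    """Return ``f(x, t)`` giving the exact-score noise prediction for ``Y``.

    The returned callable has the same signature the samplers expect from a
    trained denoiser.
    """
    Y = as_matrix(Y)

    def predictor(x, t):
        return score_to_noise_prediction(vp_score(x, t, Y, schedule), t,
                                         schedule)

    return predictor
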