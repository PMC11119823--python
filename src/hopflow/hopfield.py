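"""Classical and modern Hopfield networks.

Classical networks store patterns in a symmetric zero-diagonal coupling
matrix via the Hebb rule and retrieve with sign-threshold dynamics; their
Lyapunov energy is the quadratic form -x^T W x (stored patterns are minima).

Modern Hopfield networks replace the quadratic energy with a log-sum-exp
over pattern inner products,

    u_MH(x, beta) = -(1/beta) log sum_n exp(beta x.y_n) + ||x||^2 / 2,

and retrieve with the softmax update ``x <- Y^T softmax(beta Y x)``, which
never increases u_MH and converges onto stored patterns when
``beta * separation`` is large.  Capacity is exponential in dimension,
versus ~ D / (4 log D) for the classical network.

Vectorized: state arguments may be ``(d,)`` or ``(batch, d)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, softmax

from ._utils import as_matrix
from .patterns import binarize

__all__ = [
    "hebb_weights", "classic_update", "classic_energy", "classic_retrieve",
    "modern_update", "modern_energy", "modern_retrieve",
]


def hebb_weights(Y, zero_diagonal: bool = True) -> np.ndarray:
    """Hebbian coupling matrix ``W_jk = sum_n y_nj y_nk``.

    Symmetric by construction; invariant under ``Y -> -Y``.  The diagonal
    is zeroed by default (the textbook convention, which removes the
    self-coupling that otherwise pins each unit to its input).  With
    ``zero_diagonal=False`` the full Gram form ``W = Y^T Y`` is returned,
    making the synchronous update the linear-kernel analogue
    ``x <- sign(Y^T (Y x))`` of the modern softmax update.
    """
    Y = as_matrix(Y)
    W = Y.T @ Y
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    return W


def _check_coupling(W):
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("coupling matrix must be square")
    return W


def _check_binary(x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isin(x, (-1.0, 1.0))):
        raise ValueError("classical Hopfield states must have ±1 entries")
    return x


def classic_update(x, W, mode: str = "synchronous") -> np.ndarray:
    """One classical update of a ±1 state under couplings ``W``.

    synchronous: ``sign(W x)`` for all coordinates at once (can 2-cycle).
    asynchronous: one full sweep of single-coordinate updates in index
    order (energy-monotone, always terminates at a fixed point).
    """
    x = _check_binary(x)
    W = _check_coupling(W)
    if mode == "synchronous":
        return binarize(x @ W.T)
    if mode == "asynchronous":
        out = np.atleast_2d(x.copy())
        for j in range(W.shape[0]):
            out[:, j] = binarize(out @ W[j])
        return out[0] if x.ndim == 1 else out
    raise ValueError(f"unknown update mode {mode!r}")


def classic_energy(x, W) -> np.ndarray | float:
    """Lyapunov energy ``-x^T W x`` of the classical network.

    Non-increasing along asynchronous updates; Hebbian-stored patterns are
    its minima.  Symmetric under ``x -> -x``.
    """
    x = np.asarray(x, dtype=float)
    W = _check_coupling(W)
    e = -np.einsum("...i,ij,...j->...", x, W, x)
    return float(e) if e.ndim == 0 else e


def classic_retrieve(x, W, mode: str = "synchronous",
                     max_sweeps: int = 100) -> np.ndarray:
    """Iterate classical updates until a fixed point, 2-cycle, or cap.

    On a synchronous 2-cycle the current state is returned.
    """
    prev = None
    cur = _check_binary(x)
    for _ in range(max_sweeps):
        new = classic_update(cur, W, mode=mode)
        if np.array_equal(new, cur):
            return new
        if prev is not None and np.array_equal(new, prev):
            return new  # synchronous 2-cycle
        prev, cur = cur, new
    return cur


def modern_update(x, Y, beta: float) -> np.ndarray:
    """Softmax retrieval update ``x <- Y^T softmax(beta Y x)``.

    Returns a convex combination of the stored patterns; with a single
    stored pattern the output is that pattern for any input.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    Y = as_matrix(Y)
    x = np.asarray(x, dtype=float)
    p = softmax(beta * (x @ Y.T), axis=-1)
    return p @ Y


def modern_energy(x, Y, beta: float) -> np.ndarray | float:
    """Log-sum-exp energy of the modern Hopfield network.

    ``-(1/beta) log sum_n exp(beta x.y_n) + ||x||^2 / 2``, stabilized.
    Approaches the max-inner-product energy within ``log(N)/beta`` as
    ``beta -> inf``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    Y = as_matrix(Y)
    x = np.asarray(x, dtype=float)
    lse = logsumexp(beta * (x @ Y.T), axis=-1)
    e = -lse / beta + 0.5 * np.einsum("...d,...d->...", x, x)
    return float(e) if e.ndim == 0 else e


def modern_retrieve(x, Y, beta: float, n_updates: int = 1) -> np.ndarray:
    """Apply ``n_updates`` softmax retrieval updates."""
    if n_updates < 1:
        raise ValueError("n_updates must be at least 1")
    out = np.asarray(x, dtype=float)
    for _ in range(n_updates):
        out = modern_update(out, Y, beta)
    return out
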