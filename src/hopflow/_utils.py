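"""Shared helpers: RNG normalization and array coercion."""

from __future__ import annotations

import numpy as np


def as_rng(seed_or_rng) -> np.random.Generator:
    """Return a numpy Generator from a seed, a Generator, or None."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def as_matrix(Y) -> np.ndarray:
    """Coerce a pattern collection to a float 2-D array (N, D)."""
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D pattern matrix, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("pattern matrix must be non-empty")
    return arr
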