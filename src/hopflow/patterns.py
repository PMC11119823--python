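"""Binary pattern sets, corruption operators, and retrieval error metrics.

An associative memory stores N binary patterns ``y_n`` in {-1,+1}^D and is
queried with corrupted versions of them.  Two corruption channels are used
throughout the package:

* Gaussian mixing — ``y_tilde = theta*y + sqrt(1-theta^2)*eps`` with
  ``eps ~ N(0, I)``; ``theta`` in [0, 1] is the retained signal fraction
  (the denoising task).
* Bernoulli zero-masking — each coordinate is independently set to 0 with
  probability ``mask_prob`` (the completion task).

Retrieval quality is measured by the Hamming error: the fraction of
disagreeing coordinates between two ±1 vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import as_rng, as_matrix

__all__ = [
    "PatternSet",
    "generate_patterns",
    "corrupt_gaussian",
    "corrupt_mask",
    "binarize",
    "hamming_error",
    "save_vectors",
    "load_vectors",
]


def generate_patterns(n: int, d: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform ±1 patterns of dimension ``d``.

    Parameters
    ----------
    n, d : int
        Number of patterns and state dimensionality, both >= 1.
    seed : int, Generator or None
        Source of randomness; the same seed reproduces the same matrix.

    Returns
    -------
    ndarray of shape (n, d) with entries in {-1.0, +1.0}.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not (isinstance(d, (int, np.integer)) and d >= 1):
        raise ValueError(f"d must be a positive integer, got {d!r}")
    rng = as_rng(seed)
    return rng.integers(0, 2, size=(n, d)).astype(float) * 2.0 - 1.0


@dataclass(frozen=True)
class PatternSet:
    """Container for N stored ±1 memory vectors in dimension D.

    Thin validated wrapper around an (N, D) array; most of the package
    accepts plain arrays, and ``np.asarray(pattern_set)`` unwraps it.
    Duplicate rows are legal (patterns are sampled i.i.d.) but warned about,
    since duplicated memories share a basin.
    """

    patterns: np.ndarray
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self):
        arr = as_matrix(self.patterns)
        if not np.all(np.isin(arr, (-1.0, 1.0))):
            raise ValueError("pattern entries must be exactly -1 or +1")
        uniq = np.unique(arr, axis=0)
        if uniq.shape[0] < arr.shape[0]:
            warnings.warn(
                "pattern set contains duplicate patterns", stacklevel=2
            )
        object.__setattr__(self, "patterns", arr)

    @classmethod
    def random(cls, n: int, d: int, seed=None) -> "PatternSet":
        stored_seed = seed if isinstance(seed, (int, np.integer)) else None
        return cls(generate_patterns(n, d, seed=seed), seed=stored_seed)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.patterns, dtype=dtype)


def corrupt_gaussian(y, theta: float, seed=None) -> np.ndarray:
    """Mix a state with white noise: ``theta*y + sqrt(1-theta^2)*eps``.

    ``theta=1`` returns ``y`` unchanged; ``theta=0`` returns pure standard
    normal noise.  Operates elementwise on arrays of any shape.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    y = np.asarray(y, dtype=float)
    eps = as_rng(seed).standard_normal(y.shape)
    return theta * y + np.sqrt(1.0 - theta**2) * eps


def corrupt_mask(y, mask_prob: float, seed=None) -> np.ndarray:
    """Zero each coordinate independently with probability ``mask_prob``."""
    if not 0.0 <= mask_prob <= 1.0:
        raise ValueError(f"mask_prob must lie in [0, 1], got {mask_prob}")
    y = np.asarray(y, dtype=float)
    keep = as_rng(seed).random(y.shape) >= mask_prob
    return y * keep


def binarize(x) -> np.ndarray:
    """Elementwise sign with the tie-break sign(0) := +1.

    Zero-masked coordinates are mapped to +1; the choice is arbitrary but
    fixed so that binarization is a deterministic idempotent map onto
    {-1,+1}^D.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0.0, 1.0, -1.0)


def hamming_error(a, b) -> np.ndarray | float:
    """Fraction of disagreeing coordinates between two ±1 arrays.

    Computed along the last axis; returns a scalar for vector inputs.
    A scaled metric on {-1,+1}^D with values in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for arr in (a, b):
        if not np.all(np.isin(arr, (-1.0, 1.0))):
            raise ValueError("hamming_error requires entries in {-1,+1}")
    err = np.mean(a != b, axis=-1)
    return float(err) if err.ndim == 0 else err


def save_vectors(path, X, delimiter: str = " ") -> None:
    """Write vectors to a plain text file, one vector per row."""
    np.savetxt(path, np.atleast_2d(np.asarray(X, dtype=float)),
               delimiter=delimiter)


def load_vectors(path, delimiter: str | None = None) -> np.ndarray:
    """Read vectors from a whitespace/comma-delimited text file."""
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))
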