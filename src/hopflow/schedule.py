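"""Noise-process schedules and time grids for the diffusion dynamics.

Two time conventions coexist in the package and are documented per
function:

* VP (variance-preserving) forward time — ``t = 0`` is clean data and noise
  grows with ``t``; the signal fraction is ``theta_t = exp(-alpha*t)`` and
  the marginal variance is ``sigma^2 * (1 - theta_t^2) / (2*alpha)``
  (equal to ``1 - theta_t^2`` at the default ``alpha=0.5, sigma=1``).
  Samplers and ``vp_*`` score functions use this convention.
* VE (variance-exploding) reversed time — clean data sits at the terminal
  time ``T`` and the marginal variance at ``t < T`` is ``(T - t)*sigma^2``.
  The ``ve_*`` score functions use this convention.

``ve_time_from_noise_scale`` / ``noise_level_to_time`` convert between the
conventions and the physical noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionSchedule", "noise_level_to_time", "time_grid",
           "ve_time_from_noise_scale"]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Parameters of the noise-injection process.

    Attributes
    ----------
    alpha : float
        State-decay rate of the VP process (default 0.5, giving
        ``theta_t = exp(-t/2)``).
    sigma : float
        Diffusion coefficient of the injected noise (default 1).
    t_start : float
        Smallest time on the reverse-integration grid (default 1e-3); the
        retrieval output is the state at ``t_start``.
    n_steps : int
        Number of grid points for reverse integration (default 300).
    T : float
        Terminal (clean-data) time of the VE convention (default 1).
    """

    alpha: float = 0.5
    sigma: float = 1.0
    t_start: float = 1e-3
    n_steps: int = 300
    T: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.t_start <= 0:
            raise ValueError("t_start must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")

    def theta(self, t):
        """Signal fraction ``theta_t = exp(-alpha*t)`` (VP forward time)."""
        return np.exp(-self.alpha * np.asarray(t, dtype=float))

    def vp_variance(self, t):
        """Marginal noise variance of the VP process at forward time t."""
        th = self.theta(t)
        return self.sigma**2 * (1.0 - th**2) / (2.0 * self.alpha)

    def vp_std(self, t):
        return np.sqrt(self.vp_variance(t))

    def ve_variance(self, t):
        """Marginal variance ``(T - t)*sigma^2`` of the VE process (t < T)."""
        t = np.asarray(t, dtype=float)
        if np.any(t >= self.T):
            raise ValueError("VE convention requires t < T (data sits at T)")
        return (self.T - t) * self.sigma**2

    def noise_level_to_time(self, theta):
        """Invert ``theta_t = exp(-alpha*t)``: ``t = -ln(theta)/alpha``."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0.0) or np.any(theta > 1.0):
            raise ValueError("theta must lie in (0, 1]")
        return -np.log(theta) / self.alpha


def noise_level_to_time(theta, schedule: DiffusionSchedule):
    """Map a signal fraction theta to the VP forward time t with theta_t = theta."""
    return schedule.noise_level_to_time(theta)


def ve_time_from_noise_scale(variance, schedule: DiffusionSchedule):
    """VE time whose marginal variance ``(T-t)*sigma^2`` equals ``variance``."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be positive")
    return schedule.T - variance / schedule.sigma**2


def time_grid(t_noise: float, schedule: DiffusionSchedule,
              n_steps: int | None = None) -> np.ndarray:
    """Linear grid of times from ``t_noise`` down to ``schedule.t_start``.

    Reverse integration walks this grid in order (high noise to low noise).
    """
    n = schedule.n_steps if n_steps is None else int(n_steps)
    if n < 2:
        raise ValueError("n_steps must be at least 2")
    if t_noise <= schedule.t_start:
        raise ValueError(
            f"t_noise ({t_noise}) must exceed t_start ({schedule.t_start})"
        )
    return np.linspace(float(t_noise), schedule.t_start, n)
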