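"""Reverse-time integrators for the variance-preserving process.

The forward (noising) dynamics is the Ornstein-Uhlenbeck SDE
``dx = -alpha x dt + sigma dW`` (forward time, clean data at t=0).  Driving
it backwards with a score estimate gives two retrieval integrators:

* probability-flow ODE (deterministic Euler):
  ``x <- x + [alpha x + (sigma^2/2) score] dt``
* reverse SDE (Euler-Maruyama):
  ``x <- x + [alpha x + sigma^2 score] dt + sigma sqrt(dt) delta``

where ``dt > 0`` is the (decreasing-time) grid spacing and the score is
recovered from a noise predictor via ``score = -prediction / std_t``.  Both
walk a linear time grid from the query's noise time down to ``t_start`` and
return the full trajectory; the final state is the retrieval output (no
binarization inside the sampler).

States may be batched: ``x0`` of shape ``(d,)`` or ``(batch, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_rng
from .schedule import DiffusionSchedule

__all__ = ["Trajectory", "sample_ode", "sample_sde", "export_trajectory"]


@dataclass(frozen=True)
class Trajectory:
    """Integration record: one state per grid time."""

    times: np.ndarray    # (n_steps,)
    states: np.ndarray   # (n_steps, ...) matching x0's shape

    def __post_init__(self):
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states and times lengths differ")

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def _check_grid(grid):
    grid = np.asarray(grid, dtype=float)
    dts = np.diff(grid)
    if grid.ndim != 1 or grid.size < 2 or not np.all(dts < 0):
        raise ValueError("time grid must be strictly decreasing (noise -> t_start)")
    return grid


def _score_from_prediction(noise_predictor, x, t, schedule):
    return -np.asarray(noise_predictor(x, t), dtype=float) / schedule.vp_std(t)


def sample_ode(x0, noise_predictor, grid, schedule: DiffusionSchedule) -> Trajectory:
    """Euler integration of the probability-flow ODE along ``grid``.

    Deterministic: identical inputs give bit-identical trajectories.
    """
    grid = _check_grid(grid)
    x = np.asarray(x0, dtype=float).copy()
    states = np.empty((grid.size,) + x.shape)
    states[0] = x
    a, s2 = schedule.alpha, schedule.sigma**2
    for i in range(grid.size - 1):
        t = grid[i]
        dt = grid[i] - grid[i + 1]
        score = _score_from_prediction(noise_predictor, x, t, schedule)
        x = x + dt * (a * x + 0.5 * s2 * score)
        states[i + 1] = x
    return Trajectory(times=grid, states=states)


def sample_sde(x0, noise_predictor, grid, schedule: DiffusionSchedule,
               seed=None, noise_scale: float = 1.0) -> Trajectory:
    """Euler-Maruyama integration of the reverse SDE along ``grid``.

    Deterministic given ``seed``.  ``noise_scale`` multiplies the diffusion
    term only (0 gives the drift-only reverse SDE, used in tests).
    """
    grid = _check_grid(grid)
    rng = as_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    states = np.empty((grid.size,) + x.shape)
    states[0] = x
    a, s, s2 = schedule.alpha, schedule.sigma, schedule.sigma**2
    for i in range(grid.size - 1):
        t = grid[i]
        dt = grid[i] - grid[i + 1]
        score = _score_from_prediction(noise_predictor, x, t, schedule)
        delta = rng.standard_normal(x.shape)
        x = (x + dt * (a * x + s2 * score)
             + noise_scale * s * np.sqrt(dt) * delta)
        states[i + 1] = x
    return Trajectory(times=grid, states=states)


def export_trajectory(path, trajectory: Trajectory, delimiter: str = " ") -> None:
    """Write a (possibly batched) trajectory as text: time, then state coords."""
    states = trajectory.states
    flat = states.reshape(states.shape[0], -1)
    out = np.column_stack([trajectory.times, flat])
    np.savetxt(path, out, delimiter=delimiter)
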