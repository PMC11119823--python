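"""Experiment drivers: correlation study, capacity study, trajectory demo.

The correlation study measures, on random ±1 patterns in dimension d, how
closely the sign-binarized outputs of the exact-score diffusion sampler, a
classical Hebbian Hopfield network, and the ground-truth patterns track the
modern Hopfield iteration, on two tasks:

* denoising — queries are Gaussian-mixed, ``theta y + sqrt(1-theta^2) eps``;
* completion — queries are Bernoulli zero-masked.

Per cell (task, pattern count), all retrieved coordinates are pooled over
patterns and repetitions into one long paired sample, and a single Pearson
r is computed per method pair.

The capacity study sweeps the number of stored patterns N upward and
defines capacity as the largest N in the sweep for which the mean recovery
rate (fraction of queries with Hamming error below the threshold) is at
least ``recovery_rate``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hopfield
from .denoiser import (DenoiserConfig, denoiser_noise_predictor, init_model,
                       train)
from .patterns import (binarize, corrupt_gaussian, corrupt_mask,
                       generate_patterns, hamming_error)
from .sampler import Trajectory, sample_ode, sample_sde
from .schedule import DiffusionSchedule, time_grid
from .score_exact import exact_noise_predictor

__all__ = [
    "CorrelationStudyConfig", "run_correlation_study",
    "CapacityStudyConfig", "run_capacity_study",
    "run_trajectory_demo", "fixed_point_agreement",
]

DEFAULT_PATTERN_SWEEP = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 18, 22, 27, 33, 40)


@dataclass(frozen=True)
class CorrelationStudyConfig:
    """Study conditions for the pooled Pearson correlation table."""

    d: int = 10
    pattern_counts: tuple[int, ...] = (10, 20, 30)
    tasks: tuple[str, ...] = ("denoising", "completion")
    theta: float = 0.68
    mask_prob: float = 0.5
    n_reps: int = 100
    mhn_updates: int = 150
    mhn_beta: float = 5.0
    classic_max_sweeps: int = 100
    classic_zero_diagonal: bool = False
    classic_binarize_input: bool = False
    sampler: str = "ode"
    n_steps: int = 300
    alpha: float = 0.5
    sigma: float = 1.0
    t_start: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")


def _diffusion_retrieve(queries, Y, schedule, theta_start, sampler, n_steps,
                        rng):
    t_noise = float(schedule.noise_level_to_time(theta_start))
    if t_noise <= schedule.t_start:
        return queries.copy()
    grid = time_grid(t_noise, schedule, n_steps=n_steps)
    predictor = exact_noise_predictor(Y, schedule)
    if sampler == "ode":
        return sample_ode(queries, predictor, grid, schedule).final
    if sampler == "sde":
        return sample_sde(queries, predictor, grid, schedule, seed=rng).final
    raise ValueError(f"unknown sampler {sampler!r}")


def _distinct_patterns(n, d, rng):
    """Draw n pairwise-distinct ±1 patterns (redraws on duplicates).

    A duplicated memory is a degenerate instance — two identical
    attractors — so the demo problems presuppose distinct patterns; at
    small d random draws collide often enough to matter.
    """
    Y = generate_patterns(n, d, seed=rng)
    while np.unique(Y, axis=0).shape[0] < n:
        Y = generate_patterns(n, d, seed=rng)
    return Y


def _classic_arm(queries, Y, config):
    """Classical Hopfield retrieval as run in the correlation/capacity arms.

    The first sign-threshold update consumes the raw (continuous or
    zero-masked) query directly — zero coordinates contribute nothing —
    after which the ±1 dynamics iterates to convergence.
    """
    W = hopfield.hebb_weights(Y, zero_diagonal=config.classic_zero_diagonal)
    x0 = (binarize(queries) if config.classic_binarize_input
          else binarize(queries @ W.T))
    return hopfield.classic_retrieve(x0, W,
                                     max_sweeps=config.classic_max_sweeps)


def _pearson(a, b) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


def run_correlation_study(config: CorrelationStudyConfig) -> pd.DataFrame:
    """Run the correlation study; rows are (task, n_patterns, pair, r).

    Pairs reported: diffusion/mhn, classic/mhn, truth/mhn.  Reproducible
    bit-for-bit under a fixed ``config.seed``.
    """
    schedule = DiffusionSchedule(alpha=config.alpha, sigma=config.sigma,
                                 t_start=config.t_start,
                                 n_steps=config.n_steps)
    rows = []
    for task in config.tasks:
        for n_pat in config.pattern_counts:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    (config.seed, zlib.crc32(task.encode()), n_pat)))
            pooled = {"diffusion": [], "classic": [], "mhn": [], "truth": []}
            for _ in range(config.n_reps):
                Y = generate_patterns(n_pat, config.d, seed=rng)
                if task == "denoising":
                    queries = corrupt_gaussian(Y, config.theta, seed=rng)
                elif task == "completion":
                    queries = corrupt_mask(Y, config.mask_prob, seed=rng)
                else:
                    raise ValueError(f"unknown task {task!r}")
                diff_out = _diffusion_retrieve(
                    queries, Y, schedule, config.theta, config.sampler,
                    config.n_steps, rng)
                mhn_out = hopfield.modern_retrieve(
                    queries, Y, config.mhn_beta, n_updates=config.mhn_updates)
                classic_out = _classic_arm(queries, Y, config)
                pooled["diffusion"].append(binarize(diff_out))
                pooled["classic"].append(binarize(classic_out))
                pooled["mhn"].append(binarize(mhn_out))
                pooled["truth"].append(Y)
            flat = {k: np.concatenate(v).ravel() for k, v in pooled.items()}
            for other in ("diffusion", "classic", "truth"):
                rows.append({
                    "task": task,
                    "n_patterns": n_pat,
                    "pair": f"{other}_vs_mhn",
                    "r": _pearson(flat[other], flat["mhn"]),
                    "n_pooled": flat["mhn"].size,
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CapacityStudyConfig:
    """Study conditions for the error/capacity sweep."""

    dims: tuple[int, ...] = (10, 15, 20)
    pattern_sweep: tuple[int, ...] = DEFAULT_PATTERN_SWEEP
    theta: float = 0.68
    error_threshold: float = 0.03
    recovery_rate: float = 0.5
    n_reps: int = 10
    methods: tuple[str, ...] = ("exact_diffusion", "modern_hopfield",
                                "classic_hopfield")
    mhn_beta: float = 5.0
    mhn_updates: int = 150
    classic_max_sweeps: int = 100
    classic_zero_diagonal: bool = False
    classic_binarize_input: bool = False
    sampler: str = "ode"
    n_steps: int = 300
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.error_threshold < 1.0:
            raise ValueError("error_threshold must lie in (0, 1)")


def _retrieve_by_method(method, queries, Y, config, schedule, rng,
                        trained_model=None):
    if method == "exact_diffusion":
        return _diffusion_retrieve(queries, Y, schedule, config.theta,
                                   config.sampler, config.n_steps, rng)
    if method == "modern_hopfield":
        return hopfield.modern_retrieve(queries, Y, config.mhn_beta,
                                        n_updates=config.mhn_updates)
    if method == "classic_hopfield":
        return _classic_arm(queries, Y, config)
    if method == "trained_diffusion":
        predictor = denoiser_noise_predictor(trained_model, schedule)
        t_noise = float(schedule.noise_level_to_time(config.theta))
        grid = time_grid(t_noise, schedule, n_steps=config.n_steps)
        return sample_ode(queries, predictor, grid, schedule).final
    raise ValueError(f"unknown method {method!r}")


def run_capacity_study(config: CapacityStudyConfig,
                       denoiser_config: DenoiserConfig | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep pattern counts and estimate recovery errors and capacity.

    Returns ``(errors, capacities)``: per-(method, d, N) median Hamming
    error and mean recovery rate; and per-(method, d) capacity, the
    largest swept N whose mean recovery rate reaches
    ``config.recovery_rate``  (0 if none does).

    ``trained_diffusion`` retrains the denoiser per (d, N) cell; pass a
    reduced sweep/config when including it, since training dominates cost.
    """
    schedule = DiffusionSchedule(n_steps=config.n_steps)
    err_rows, cap_rows = [], []
    for method in config.methods:
        for d in config.dims:
            capacity = 0
            for n_pat in sorted(config.pattern_sweep):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (config.seed, zlib.crc32(method.encode()), d, n_pat)))
                errors, recoveries = [], []
                for _ in range(config.n_reps):
                    Y = generate_patterns(n_pat, d, seed=rng)
                    queries = corrupt_gaussian(Y, config.theta, seed=rng)
                    trained = None
                    if method == "trained_diffusion":
                        cfg = denoiser_config or DenoiserConfig()
                        trained = train(init_model(d, cfg), Y, cfg)
                    out = _retrieve_by_method(method, queries, Y, config,
                                              schedule, rng, trained)
                    err = hamming_error(binarize(out), Y)
                    errors.extend(np.atleast_1d(err))
                    recoveries.extend(
                        np.atleast_1d(err) < config.error_threshold)
                mean_recovery = float(np.mean(recoveries))
                err_rows.append({
                    "method": method, "d": d, "n_patterns": n_pat,
                    "median_error": float(np.median(errors)),
                    "mean_recovery": mean_recovery,
                })
                if mean_recovery >= config.recovery_rate:
                    capacity = n_pat
            cap_rows.append({"method": method, "d": d, "capacity": capacity})
    return pd.DataFrame(err_rows), pd.DataFrame(cap_rows)


def run_trajectory_demo(seed: int = 0, n_steps: int = 2000, theta: float = 0.68,
                  beta: float = 5.0, n_mhn_updates: int = 4,
                  include_trained: bool = True,
                  denoiser_config: DenoiserConfig | None = None) -> dict:
    """Qualitative trajectory comparison on d=5, N=4 random patterns.

    Produces exact-score ODE and SDE trajectories, the modern Hopfield
    iterates, and (optionally) the trained denoiser's ODE trajectories,
    all from the same corrupted queries (one per stored pattern).
    """
    rng = np.random.default_rng(seed)
    Y = _distinct_patterns(4, 5, rng)
    queries = corrupt_gaussian(Y, theta, seed=rng)
    schedule = DiffusionSchedule()
    t_noise = float(schedule.noise_level_to_time(theta))
    grid = time_grid(t_noise, schedule, n_steps=n_steps)
    predictor = exact_noise_predictor(Y, schedule)
    ode = sample_ode(queries, predictor, grid, schedule)
    sde = sample_sde(queries, predictor, grid, schedule, seed=rng)
    mhn_states = [queries.copy()]
    for _ in range(n_mhn_updates):
        mhn_states.append(hopfield.modern_update(mhn_states[-1], Y, beta))
    out = {
        "patterns": Y,
        "queries": queries,
        "ode": ode,
        "sde": sde,
        "mhn_states": np.asarray(mhn_states),
    }
    if include_trained:
        cfg = denoiser_config or DenoiserConfig(seed=seed)
        model = train(init_model(5, cfg), Y, cfg)
        out["model"] = model
        out["trained_ode"] = sample_ode(
            queries, denoiser_noise_predictor(model, schedule), grid,
            schedule)
    return out


def fixed_point_agreement(seed: int = 0, n_trials: int = 200, d: int = 5,
                          n_patterns: int = 4, theta: float = 0.68,
                          beta: float = 5.0, n_mhn_updates: int = 4,
                          n_steps: int = 300,
                          include_trained: bool = True,
                          denoiser_config: DenoiserConfig | None = None,
                          ) -> dict:
    """Fraction of trials where all retrieval routes share a fixed point.

    One pattern set is drawn; each trial corrupts a randomly chosen stored
    pattern and retrieves it with the exact-score ODE and SDE samplers,
    the trained denoiser's ODE sampler (optional), and the modern Hopfield
    iteration.  A trial agrees when every binarized endpoint matches the
    binarized modern Hopfield output.  Also reports how often the modern
    Hopfield binarized state changes after its first update.
    """
    rng = np.random.default_rng(seed)
    Y = _distinct_patterns(n_patterns, d, rng)
    schedule = DiffusionSchedule(n_steps=n_steps)
    t_noise = float(schedule.noise_level_to_time(theta))
    grid = time_grid(t_noise, schedule, n_steps=n_steps)
    predictor = exact_noise_predictor(Y, schedule)

    model = None
    if include_trained:
        cfg = denoiser_config or DenoiserConfig(seed=seed)
        model = train(init_model(d, cfg), Y, cfg)
        trained_predictor = denoiser_noise_predictor(model, schedule)

    idx = rng.integers(0, n_patterns, size=n_trials)
    queries = corrupt_gaussian(Y[idx], theta, seed=rng)

    ode_out = binarize(sample_ode(queries, predictor, grid, schedule).final)
    sde_out = binarize(
        sample_sde(queries, predictor, grid, schedule, seed=rng).final)
    mhn_iter = queries.copy()
    mhn_after_first = None
    for k in range(n_mhn_updates):
        mhn_iter = hopfield.modern_update(mhn_iter, Y, beta)
        if k == 0:
            mhn_after_first = binarize(mhn_iter)
    mhn_out = binarize(mhn_iter)

    ode_agree = np.all(ode_out == mhn_out, axis=1)
    sde_agree = np.all(sde_out == mhn_out, axis=1)
    agree = ode_agree & sde_agree
    result = {
        "ode_agreement_rate": float(np.mean(ode_agree)),
        "sde_agreement_rate": float(np.mean(sde_agree)),
        "n_trials": int(n_trials),
        "patterns": Y,
        "model": model,
    }
    deterministic = ode_agree.copy()
    if include_trained:
        trained_out = binarize(
            sample_ode(queries, trained_predictor, grid, schedule).final)
        trained_agree = np.all(trained_out == mhn_out, axis=1)
        agree &= trained_agree
        deterministic &= trained_agree
        result["trained_agreement_rate"] = float(np.mean(trained_agree))
    mhn_stable = np.all(mhn_after_first == mhn_out, axis=1)
    result["agreement_rate"] = float(np.mean(agree))
    result["deterministic_agreement_rate"] = float(np.mean(deterministic))
    result["mhn_first_update_stable_rate"] = float(np.mean(mhn_stable))
    return result
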