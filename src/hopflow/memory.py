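"""Scikit-learn-style associative memory estimators.

Each estimator follows the transformer contract: ``fit(X)`` stores the
pattern matrix (rows are the ±1 memories), and ``transform(X)`` maps
corrupted query states to retrieved states.  All estimators compose with
sklearn pipelines, ``clone`` and ``get_params``/``set_params``; fitted
state lives in trailing-underscore attributes.

* :class:`ClassicalHopfieldMemory` — Hebbian couplings, sign-threshold
  dynamics iterated to convergence.
* :class:`ModernHopfieldMemory` — softmax retrieval at inverse
  temperature beta.
* :class:`ExactDiffusionMemory` — reverse-time integration of the
  variance-preserving process driven by the exact mixture score.
* :class:`TrainedDiffusionMemory` — the same sampler driven by an MLP
  denoiser trained on the stored patterns at fit time.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import hopfield
from .denoiser import (DenoiserConfig, denoiser_noise_predictor, init_model,
                       train)
from .patterns import binarize
from .sampler import sample_ode, sample_sde
from .schedule import DiffusionSchedule, time_grid
from .score_exact import exact_noise_predictor

__all__ = ["ClassicalHopfieldMemory", "ModernHopfieldMemory",
           "ExactDiffusionMemory", "TrainedDiffusionMemory"]


class _BaseMemory(TransformerMixin, BaseEstimator):
    """Shared fit/validation logic for associative memories."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if not np.all(np.isin(X, (-1.0, 1.0))):
            raise ValueError("stored patterns must have ±1 entries")
        self.patterns_ = X
        self.n_patterns_, self.n_features_in_ = X.shape
        self._post_fit()
        return self

    def _post_fit(self):
        pass

    def _check_queries(self, X):
        check_is_fitted(self, "patterns_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query dimension {X.shape[1]} != stored dimension "
                f"{self.n_features_in_}")
        return X

    def recall(self, X):
        """Alias of :meth:`transform`: retrieve memories for queries."""
        return self.transform(X)


class ModernHopfieldMemory(_BaseMemory):
    """Modern Hopfield network retrieval ``x <- Y^T softmax(beta Y x)``.

    Parameters
    ----------
    beta : float, default 5.0
        Inverse temperature; large beta gives hard nearest-pattern recall.
    n_updates : int, default 1
        Softmax updates per query (the iteration typically converges in
        one).
    binarize_output : bool, default False
        If True, apply elementwise sign to the retrieved states.
    """

    def __init__(self, beta: float = 5.0, n_updates: int = 1,
                 binarize_output: bool = False):
        self.beta = beta
        self.n_updates = n_updates
        self.binarize_output = binarize_output

    def transform(self, X):
        X = self._check_queries(X)
        out = hopfield.modern_retrieve(X, self.patterns_, self.beta,
                                       n_updates=self.n_updates)
        return binarize(out) if self.binarize_output else out

    def energy(self, X):
        """Modern Hopfield energy of states under the stored patterns."""
        self._check_queries(np.atleast_2d(X))
        return hopfield.modern_energy(np.asarray(X, dtype=float),
                                      self.patterns_, self.beta)


class ClassicalHopfieldMemory(_BaseMemory):
    """Classical Hopfield network with Hebbian storage.

    With ``binarize_input=True`` queries are sign-binarized before
    iterating; with the default False the first sign-threshold update
    consumes the raw query directly (zero-masked coordinates then
    contribute nothing).  Iteration stops at a fixed point, on a
    synchronous 2-cycle, or after ``max_sweeps``.
    """

    def __init__(self, mode: str = "synchronous", max_sweeps: int = 100,
                 zero_diagonal: bool = True, binarize_input: bool = False,
                 binarize_output: bool = False):
        self.mode = mode
        self.max_sweeps = max_sweeps
        self.zero_diagonal = zero_diagonal
        self.binarize_input = binarize_input
        self.binarize_output = binarize_output

    def _post_fit(self):
        self.coupling_ = hopfield.hebb_weights(
            self.patterns_, zero_diagonal=self.zero_diagonal)

    def transform(self, X):
        X = self._check_queries(X)
        x0 = binarize(X) if self.binarize_input else binarize(X @ self.coupling_.T)
        out = hopfield.classic_retrieve(x0, self.coupling_,
                                        mode=self.mode,
                                        max_sweeps=self.max_sweeps)
        return out  # already ±1

    def energy(self, X):
        """Lyapunov energy -x^T W x under the learned couplings."""
        check_is_fitted(self, "coupling_")
        return hopfield.classic_energy(np.asarray(X, dtype=float),
                                       self.coupling_)


class _BaseDiffusionMemory(_BaseMemory):
    """Reverse-diffusion retrieval shared by exact and trained scores."""

    def __init__(self, query_noise_level: float = 0.68, alpha: float = 0.5,
                 sigma: float = 1.0, t_start: float = 1e-3,
                 n_steps: int = 300, sampler: str = "ode",
                 binarize_output: bool = False, random_state=None):
        self.query_noise_level = query_noise_level
        self.alpha = alpha
        self.sigma = sigma
        self.t_start = t_start
        self.n_steps = n_steps
        self.sampler = sampler
        self.binarize_output = binarize_output
        self.random_state = random_state

    def _schedule(self) -> DiffusionSchedule:
        return DiffusionSchedule(alpha=self.alpha, sigma=self.sigma,
                                 t_start=self.t_start, n_steps=self.n_steps)

    def _predictor(self, schedule):
        raise NotImplementedError

    def transform(self, X):
        X = self._check_queries(X)
        schedule = self._schedule()
        t_noise = float(schedule.noise_level_to_time(self.query_noise_level))
        if t_noise <= schedule.t_start:
            # a noiseless query leaves no integration interval
            out = X.copy()
        else:
            grid = time_grid(t_noise, schedule)
            predictor = self._predictor(schedule)
            if self.sampler == "ode":
                out = sample_ode(X, predictor, grid, schedule).final
            elif self.sampler == "sde":
                out = sample_sde(X, predictor, grid, schedule,
                                 seed=self.random_state).final
            else:
                raise ValueError(f"unknown sampler {self.sampler!r}")
        return binarize(out) if self.binarize_output else out


class ExactDiffusionMemory(_BaseDiffusionMemory):
    """Diffusion associative memory driven by the exact mixture score.

    Retrieval integrates the probability-flow ODE (or reverse SDE, with
    ``sampler='sde'``) from the time matching ``query_noise_level`` down to
    ``t_start``, using the closed-form score of the Gaussian mixture over
    the stored patterns.
    """

    def _predictor(self, schedule):
        return exact_noise_predictor(self.patterns_, schedule)


class TrainedDiffusionMemory(_BaseDiffusionMemory):
    """Diffusion associative memory with a denoiser MLP trained at fit time.

    ``fit`` runs the full denoising-loss training loop (Adam, fresh noise
    per pattern per iteration); fitted attributes include the trained
    ``model_`` and its ``loss_history_``.
    """

    def __init__(self, query_noise_level: float = 0.68, alpha: float = 0.5,
                 sigma: float = 1.0, t_start: float = 1e-3,
                 n_steps: int = 300, sampler: str = "ode",
                 binarize_output: bool = False, random_state=None,
                 hidden_units: int = 750, n_hidden: int = 2,
                 theta_min: float = 0.6, theta_max: float = 1.0,
                 n_iterations: int = 5000, learning_rate: float = 1e-3):
        super().__init__(query_noise_level=query_noise_level, alpha=alpha,
                         sigma=sigma, t_start=t_start, n_steps=n_steps,
                         sampler=sampler, binarize_output=binarize_output,
                         random_state=random_state)
        self.hidden_units = hidden_units
        self.n_hidden = n_hidden
        self.theta_min = theta_min
        self.theta_max = theta_max
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate

    def _post_fit(self):
        seed = 0 if self.random_state is None else int(self.random_state)
        config = DenoiserConfig(hidden_units=self.hidden_units,
                                n_hidden=self.n_hidden,
                                theta_range=(self.theta_min, self.theta_max),
                                n_iterations=self.n_iterations,
                                learning_rate=self.learning_rate, seed=seed)
        model = init_model(self.n_features_in_, config)
        self.model_ = train(model, self.patterns_, config)
        self.loss_history_ = list(self.model_.loss_history)

    def _predictor(self, schedule):
        check_is_fitted(self, "model_")
        return denoiser_noise_predictor(self.model_, schedule)
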