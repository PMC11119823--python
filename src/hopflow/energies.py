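"""Energy functions unifying diffusion denoising and Hopfield retrieval.

The diffusion (VE) energy over a finite pattern set,

    u_DM(x, t) = -sigma^2 log (1/N) sum_n exp(-||x - y_n||^2 / (2 (T-t) sigma^2)),

is, for unit-norm patterns and beta(t)^-1 = (T-t) sigma^2, identical up to
an x-independent constant to the modern Hopfield energy u_MH(x, beta(t)).
``equivalence_gap`` checks this identity numerically: it evaluates the
difference at random probes and returns its standard deviation, which must
vanish if the two energies differ only by a constant.

Beyond point memories, the same log-sum-exp construction extends to
memories with internal degrees of freedom:

* extended memories — each memory is a subspace S_n, integrated uniformly;
* semantic memories — the pattern sum becomes an integral over a density
  phi(y) (e.g. a manifold), estimated by Monte Carlo over samples;
* reconstructive memories — a mixture of low-dimensional stored "cores"
  (via projections f_n with W < D) and a semantic term, so some features
  are recalled faithfully while the rest are reconstructed.

As printed, these generalized energies are log-sum-exp expressions whose
memories are *maxima*; ``landscape_energy`` negates them (and optionally
adds the ||x||^2/2 stabilizer of the modern Hopfield energy) so that flows
descend into memory basins, matching the rendered landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._utils import as_matrix, as_rng
from .hopfield import modern_energy
from .schedule import DiffusionSchedule
from .score_exact import ve_log_marginal, ve_score

__all__ = [
    "MemoryGeometry", "diffusion_energy", "diffusion_energy_grad",
    "equivalence_gap", "extended_memory_energy", "semantic_energy",
    "reconstructive_energy", "landscape_energy", "numerical_gradient",
    "gradient_flow", "render_landscape", "LandscapeField",
]


def diffusion_energy(x, t, Y, schedule: DiffusionSchedule):
    """VE diffusion energy ``-sigma^2 log p_t(x)`` up to a constant.

    A single pattern gives a quadratic bowl centred at it; small ``(T-t)``
    gives sharp wells at every stored pattern.
    """
    return -schedule.sigma**2 * ve_log_marginal(x, t, Y, schedule)


def diffusion_energy_grad(x, t, Y, schedule: DiffusionSchedule):
    """Analytic gradient ``-sigma^2 * ve_score``; the negative drift."""
    return -schedule.sigma**2 * ve_score(x, t, Y, schedule)


def equivalence_gap(Y, t, schedule: DiffusionSchedule, n_probes: int = 100,
                    seed=None) -> float:
    """Probe-wise spread of ``beta(t)^-1 u_DM / sigma^2 - u_MH(., beta(t))``.

    For unit-norm patterns the two energies differ only by an
    x-independent constant, so the standard deviation across random
    standard-normal probes is zero up to floating point.
    """
    Y = as_matrix(Y)
    beta_inv = schedule.ve_variance(t)
    x = as_rng(seed).standard_normal((n_probes, Y.shape[1]))
    g = (beta_inv * diffusion_energy(x, t, Y, schedule) / schedule.sigma**2
         - modern_energy(x, Y, 1.0 / beta_inv))
    return float(np.std(g))


@dataclass(frozen=True)
class MemoryGeometry:
    """Memory support for the generalized energies.

    kind 'points': ``samples`` is the (N, D) pattern matrix.
    kind 'extended_subspaces': ``subspaces`` is a list of per-memory sample
    matrices discretizing each S_n.
    kind 'semantic_density': ``samples`` is an (M, D) draw from phi(y).
    kind 'reconstructive': ``projections`` (each (W, D) with W < D) and
    ``cores`` (each length W) define the stored low-dimensional cores;
    ``samples`` is the semantic sample set.
    """

    kind: str
    samples: np.ndarray | None = None
    subspaces: tuple[np.ndarray, ...] = ()
    projections: tuple[np.ndarray, ...] = ()
    cores: tuple[np.ndarray, ...] = ()

    @classmethod
    def points(cls, Y):
        return cls(kind="points", samples=as_matrix(Y))

    @classmethod
    def extended(cls, subspaces):
        subs = tuple(as_matrix(S) for S in subspaces)
        if not subs:
            raise ValueError("need at least one subspace")
        return cls(kind="extended_subspaces", subspaces=subs)

    @classmethod
    def semantic(cls, samples):
        return cls(kind="semantic_density", samples=as_matrix(samples))

    @classmethod
    def reconstructive(cls, projections, cores, semantic_samples):
        projs = tuple(np.atleast_2d(np.asarray(P, dtype=float))
                      for P in projections)
        cores_t = tuple(np.atleast_1d(np.asarray(c, dtype=float))
                        for c in cores)
        samples = as_matrix(semantic_samples)
        D = samples.shape[1]
        for P, c in zip(projs, cores_t):
            if P.shape != (c.size, D):
                raise ValueError("projection shape must be (W, D) matching core")
            if c.size >= D:
                raise ValueError("core dimension W must satisfy W < D")
        return cls(kind="reconstructive", samples=samples,
                   projections=projs, cores=cores_t)


def _log_mean_exp(logits, axis=-1):
    return logsumexp(logits, axis=axis) - np.log(logits.shape[axis])


def extended_memory_energy(x, geometry: MemoryGeometry, beta: float):
    """``log sum_n (1/|S_n|) sum_{y in S_n} exp(beta x.y)`` (printed form).

    Uniform quadrature over each discretized subspace; a single-point
    subspace reduces to the point-memory log-sum-exp term.
    """
    if geometry.kind != "extended_subspaces":
        raise ValueError("geometry must be of kind 'extended_subspaces'")
    x = np.asarray(x, dtype=float)
    per_memory = [
        _log_mean_exp(beta * (x @ S.T), axis=-1) for S in geometry.subspaces
    ]
    return logsumexp(np.stack(per_memory, axis=-1), axis=-1)


def semantic_energy(x, geometry: MemoryGeometry, beta: float,
                    sigma: float = 1.0):
    """Monte-Carlo ``sigma^2 log integral exp(beta x.y) phi(y) dy``."""
    if geometry.kind != "semantic_density":
        raise ValueError("geometry must be of kind 'semantic_density'")
    x = np.asarray(x, dtype=float)
    return sigma**2 * _log_mean_exp(beta * (x @ geometry.samples.T), axis=-1)


def reconstructive_energy(x, geometry: MemoryGeometry, beta: float):
    """Mixture of stored low-dimensional cores and a semantic term.

    ``log [ sum_n exp(beta f_n(x).xi_n) + (1/M) sum_m exp(beta x.y_m) ]``.
    The core term's gradient lies in the row space of f_n: only the W
    projected features are constrained, the rest evolve semantically.
    """
    if geometry.kind != "reconstructive":
        raise ValueError("geometry must be of kind 'reconstructive'")
    x = np.asarray(x, dtype=float)
    core_logits = [beta * ((x @ P.T) @ c)
                   for P, c in zip(geometry.projections, geometry.cores)]
    sem = beta * (x @ geometry.samples.T)
    sem_logit = _log_mean_exp(sem, axis=-1)
    logits = np.stack(core_logits + [sem_logit], axis=-1)
    return logsumexp(logits, axis=-1)


def landscape_energy(x, geometry: MemoryGeometry, beta: float,
                     sigma: float = 1.0, regularize: bool = True):
    """Descent-oriented energy for flows and rendering.

    The negated printed log-sum-exp expression, plus (optionally) the
    ``||x||^2/2`` stabilizer, so memories are minima/attractors instead of
    unbounded ascent directions.
    """
    x = np.asarray(x, dtype=float)
    if geometry.kind == "points":
        raw = logsumexp(beta * (x @ geometry.samples.T), axis=-1)
    elif geometry.kind == "extended_subspaces":
        raw = extended_memory_energy(x, geometry, beta)
    elif geometry.kind == "semantic_density":
        raw = semantic_energy(x, geometry, beta, sigma=sigma)
    elif geometry.kind == "reconstructive":
        raw = reconstructive_energy(x, geometry, beta)
    else:
        raise ValueError(f"unknown geometry kind {geometry.kind!r}")
    e = -raw / beta
    if regularize:
        e = e + 0.5 * np.einsum("...d,...d->...", x, x)
    return e


def numerical_gradient(f, x, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar field."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for idx in np.ndindex(x.shape):
        e = np.zeros_like(x)
        e[idx] = h
        g[idx] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def gradient_flow(f, x0, step: float = 0.05, n_steps: int = 200,
                  h: float = 1e-5) -> np.ndarray:
    """Gradient-descent trajectory on a scalar energy; rows are iterates."""
    x = np.asarray(x0, dtype=float).copy()
    path = [x.copy()]
    for _ in range(n_steps):
        x = x - step * numerical_gradient(f, x, h=h)
        path.append(x.copy())
    return np.asarray(path)


@dataclass
class LandscapeField:
    """2-D energy landscape with its gradient field and flow trajectories."""

    xs: np.ndarray
    ys: np.ndarray
    energy: np.ndarray       # (res, res)
    grad_x: np.ndarray
    grad_y: np.ndarray
    trajectories: list[np.ndarray] = field(default_factory=list)

    def to_text(self, path, delimiter: str = " ") -> None:
        """Rows: x, y, energy, grad_x, grad_y."""
        X, Y = np.meshgrid(self.xs, self.ys, indexing="ij")
        rows = np.column_stack([X.ravel(), Y.ravel(), self.energy.ravel(),
                                self.grad_x.ravel(), self.grad_y.ravel()])
        np.savetxt(path, rows, delimiter=delimiter)

    def plot(self, path=None):
        """Render heatmap + vector field + trajectories; save if path given."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        X, Y = np.meshgrid(self.xs, self.ys, indexing="ij")
        pc = ax.pcolormesh(X, Y, self.energy, shading="auto", cmap="viridis")
        skip = max(1, len(self.xs) // 20)
        ax.quiver(X[::skip, ::skip], Y[::skip, ::skip],
                  -self.grad_x[::skip, ::skip], -self.grad_y[::skip, ::skip],
                  color="white", alpha=0.7)
        for traj in self.trajectories:
            ax.plot(traj[:, 0], traj[:, 1], color="crimson", lw=1)
        fig.colorbar(pc, ax=ax, label="energy")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def render_landscape(energy, bounds=((-2.0, 2.0), (-2.0, 2.0)),
                     resolution: int = 60, starts=None,
                     flow_steps: int = 200, flow_step: float = 0.05,
                     ) -> LandscapeField:
    """Evaluate a 2-D energy on a grid with its numerical gradient field.

    ``energy`` maps a length-2 state to a scalar.  Optional ``starts`` seed
    gradient-descent trajectories overlaid on the field.
    """
    (x0, x1), (y0, y1) = bounds
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    E = np.empty((resolution, resolution))
    Gx = np.empty_like(E)
    Gy = np.empty_like(E)
    for i, xv in enumerate(xs):
        for j, yv in enumerate(ys):
            p = np.array([xv, yv])
            E[i, j] = energy(p)
            g = numerical_gradient(energy, p)
            Gx[i, j], Gy[i, j] = g
    trajectories = []
    if starts is not None:
        for s in np.atleast_2d(np.asarray(starts, dtype=float)):
            if s.size != 2:
                raise ValueError("landscape rendering requires 2-D states")
            trajectories.append(
                gradient_flow(energy, s, step=flow_step, n_steps=flow_steps))
    return LandscapeField(xs=xs, ys=ys, energy=E, grad_x=Gx, grad_y=Gy,
                          trajectories=trajectories)
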