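# Methods

## Model

The package treats associative memory retrieval as reverse-time diffusion.
A variance-preserving (VP) Ornstein–Uhlenbeck process
`dx = −αx dt + σ dW` destroys a stored pattern `y`; at forward time `t`
(clean data at `t = 0`) the state is distributed as
`N(θ_t y, v_t I)` with signal fraction `θ_t = e^{−αt}` and noise variance
`v_t = σ²(1 − θ_t²)/(2α)`. With N equiprobable stored patterns the marginal
is an isotropic Gaussian mixture, and its score — the gradient of the log
marginal density — is available in closed form as a softmax-weighted pull
toward the scaled patterns. Retrieval integrates the probability-flow ODE

```
x ← x + [αx + (σ²/2)·score] dt        (deterministic)
```

or the reverse SDE

```
x ← x + [αx + σ²·score] dt + σ√dt·δ   (stochastic)
```

on a linear time grid from the query's noise time down to `t_start`.
The printed update formulas in the source literature for these samplers
carry ambiguous drift groupings; we implement the standard reverse-time
probability-flow ODE and reverse SDE for this forward process, for which
the shared-fixed-point property below is the operative contract (and is
what the tests enforce).

A variance-exploding (VE) Brownian variant (marginal variance
`(T − t)σ²`, clean data at the terminal time `T`) is provided for the
energy analysis. The central identity is that the VE diffusion energy
`u_DM(x,t) = −σ² log p_t(x)` over unit-norm patterns satisfies

```
β(t)⁻¹ · u_DM(x,t)/σ² = u_MH(x, β(t)) + const,    β(t)⁻¹ = (T−t)σ²,
```

where `u_MH` is the modern Hopfield log-sum-exp energy. `equivalence_gap`
checks this by evaluating the difference at random standard-normal probes
and returning its standard deviation, which is zero up to floating point
(~1e-15 observed, asserted < 1e-8). For un-normalized ±1 patterns the
identity holds up to pattern-norm terms that become an irrelevant constant
shift as `β(t) → ∞`; this is checked as argmin agreement on a grid.

### Time conventions

VP functions and both samplers use forward time (`t = 0` clean, θ
decreasing); VE functions use the reversed convention with clean data at
`T` (so variance `(T − t)σ²`, pre-condition `t < T`). `DiffusionSchedule`
holds both parameter sets and the conversion helpers
(`noise_level_to_time`, `ve_time_from_noise_scale`). A query corrupted at
signal fraction θ enters the sampler at `t = −ln θ / α`; a noiseless query
(θ = 1) maps to `t = 0 ≤ t_start`, leaving no integration interval, and is
returned unchanged.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | VP decay rate; `θ_t = e^{−t/2}` |
| `sigma` | 1.0 | diffusion coefficient; with `alpha=0.5` the stationary variance is 1 and `v_t = 1 − θ_t²` |
| `t_start` | 1e-3 | end of reverse integration; retrieval output is the state here |
| `n_steps` | 300 | linear grid size (2000 in the trajectory demo) |
| `beta` | 5.0 | softmax inverse temperature (150 updates in the studies, 4 in the demo; one update suffices for the binarized output) |
| `theta` | 0.68 | retained signal fraction of the Gaussian corruption |
| `mask_prob` | 0.5 | Bernoulli zero-masking probability (completion task) |
| recovery threshold | 0.03 | Hamming-error cutoff defining successful recovery |

Denoiser: a 3-layer perceptron `[d+1 → 750, 751 → 750, 751 → d]`, ReLU on
both hidden layers, the noise level θ appended to the input of every
affine layer. Trained for 5000 full-batch Adam steps (step size 1e-3,
moments 0.9/0.999 — conventional values, exposed in `DenoiserConfig`) on
the denoising loss with `θ ~ U(0.6, 1)` and a fresh standard-normal noise
draw per pattern per iteration (the loss expectation binds θ and the noise
outside the pattern sum; per-pattern resampling is our reading and is
documented here). No learning-rate schedule, no early stopping. The
network, backpropagation and Adam are implemented directly on numpy
arrays; at these sizes (d ≤ 10, 750 hidden units, batches of ≤ 40
patterns) dense matmuls complete training in under a minute on one core.

## Design choices

* **Classical energy sign.** The Lyapunov quantity is implemented as
  `−xᵀWx` so that Hebbian-stored patterns are minima; the convention in
  which the quadratic form itself decreases conflicts with retrieval
  minima and is not used.
* **Classical experiment arm.** The correlation and capacity studies run
  the classical network as `x ← sign(Yᵀ(Yx))` — the Gram coupling with
  the Hebbian self-coupling retained, the exact linear-kernel analogue of
  the softmax update `Yᵀ softmax(βYx)` — and feed the raw query into the
  first update (so zero-masked coordinates contribute nothing) before
  iterating the ±1 dynamics to convergence (≤ 100 sweeps, with 2-cycle
  detection). Both choices are exposed as config flags
  (`classic_zero_diagonal`, `classic_binarize_input`); the textbook
  zero-diagonal convention remains the `hebb_weights` default. The
  retained-diagonal, raw-query arm is the variant whose pooled
  correlations match the reference correlation table; the zero-diagonal arm scores
  far lower because at these loads the self-coupling dominates retrieval.
* **sign(0) := +1**, fixed tie-break: zero-masking produces exact zeros
  and binarization must be deterministic and idempotent.
* **Mixture numerics.** All mixture energies, log-densities and scores go
  through log-sum-exp; naive summation underflows at small noise variance,
  which is precisely the retrieval-relevant regime. Mixture weights are
  validated as probability vectors in tests.
* **Correlation pooling.** One Pearson r per (task, pattern count, method
  pair), computed on all retrieved coordinates concatenated over patterns
  and repetitions (100 × N × d paired samples).
* **Capacity rule.** Capacity at dimension d is the largest swept pattern
  count whose mean recovery rate (fraction of queries with Hamming error
  < 3%) is ≥ 0.5. The default sweep is geometric-ish up to 40 patterns;
  softmax-network and diffusion capacities exceed this cap at d ≥ 10
  (reported as the cap), which does not affect the ordering and
  equivalence conclusions the study draws.
* **Generalized energies.** Subspace and density integrals in the
  extended/semantic/reconstructive energies are discretized by uniform
  sampling over declared sample sets; refinement-consistency tests guard
  the discretization. For deterministic grids over a subspace, use
  midpoint-rule samples (no endpoints): the integrand `e^{βxᵀy}` is
  endpoint-dominated, so endpoint-inclusive grids self-converge only at
  O(h) while midpoint grids converge at O(h²). As printed these energies are log-sum-exp
  expressions whose memories are maxima; `landscape_energy` negates them
  and adds the `‖x‖²/2` stabilizer (flagged by the `regularize` argument)
  so flows descend into basins. Where source conventions disagree on the
  sign inside the semantic integral of the reconstructive mixture, we use
  the same `+β xᵀy` convention as the pure semantic energy.

## What the synthetic generator does and does not emulate

All inputs are i.i.d. uniform ±1 patterns with Gaussian-mixing or
Bernoulli-masking corruption — exactly the conditions of the quantitative
studies being reproduced. Duplicate patterns and near-duplicates occur
naturally at small d (a random 4-pattern set in d = 5 almost surely has a
pair within Hamming distance 2) and are kept, with a warning on exact
duplicates. The generator does not produce correlated, sparse or
structured patterns (images, sequences), so passing tests say nothing
about retrieval under correlated memories, where classical Hopfield
degradation is known to be more severe and softmax retrieval depends on
separation margins.

## Probabilistic recall and what "agreement" can reach

The deterministic routes — exact-score probability-flow ODE, the trained
denoiser's ODE, and the softmax iteration — share binarized endpoints at
~99% of corrupted queries in the d = 5, N = 4 demo and ≥ 99% against
hard (large-β) retrieval at d = 10. The stochastic sampler is different
in kind: its endpoint is a draw from the posterior over stored patterns
given the query (verified in tests against the analytic two-pattern
posterior), so its agreement with any deterministic route is bounded by
the posterior mass of the dominant pattern, roughly `E[max_n p(y_n |
query)]`. At θ = 0.68 in d = 5 this bound is well below 99% for typical
pattern draws; the corresponding all-route acceptance test documents this
in its failure message rather than weakening the stochastic sampler. This
is the same property that makes the SDE useful: ambiguous queries
co-activate several memories instead of committing to one.

## Problem sizes

The shipped studies use the reference study conditions: d = 10 with 10/20/30
patterns and 100 repetitions for the correlation table (≈ 20 s on one
core), d ∈ {10, 15, 20} with 10 repetitions per sweep point for the
capacity study (≈ 20 s), and d = 5, N = 4 with the full 5000-iteration
denoiser training for the trajectory demo (≈ 1 min). Larger grids are a
matter of configuration, not code.

## Known limitations

* Exact-score retrieval scales as O(N·d) per step per query — it is a
  reference implementation, not an approximate nearest-neighbour system.
* Only the exponential modern Hopfield energy is shipped (the quadratic
  classical form being its degenerate case); general `F`/`h` energies are
  out of scope.
* The capacity sweep reports the sweep cap when a method's capacity
  exceeds it; absolute capacities above 40 patterns are not resolved.
* The denoiser is trained per pattern set; there is no amortization
  across sets, and `θ ~ U(0.6, 1)` training leaves the network
  extrapolating below θ = 0.6 (queries noisier than the training range).
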