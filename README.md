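# hopflow

Generative diffusion models and Hopfield networks as two faces of the same
associative memory.

`hopflow` stores binary patterns `y_n ∈ {−1,+1}^D` and retrieves them from
corrupted queries with three interchangeable dynamics:

* **Classical Hopfield network** — Hebbian couplings
  `W = Σ_n y_n y_nᵀ` and sign-threshold updates `x ← sign(Wx)`, minimizing
  the quadratic energy `−xᵀWx`.
* **Modern Hopfield network** — the log-sum-exp energy
  `u_MH(x, β) = −β⁻¹ log Σ_n exp(β xᵀy_n) + ‖x‖²/2`
  with the softmax retrieval update `x ← Yᵀ softmax(β Y x)`.
* **Generative diffusion** — reverse-time integration of a
  variance-preserving noise process `dx = −αx dt + σ dW`
  (signal fraction `θ_t = e^{−αt}`), driven either by the **exact score**
  of the Gaussian mixture over the stored patterns,

  `∇ₓ log p_t(x) = Σ_n w_n(x,t) (θ_t y_n − x) / v_t`,
  `w = softmax(−‖x − θ_t y_n‖² / 2v_t)`,

  or by a small **MLP denoiser** trained to predict the injected noise.

The connection is an energy identity: for unit-norm patterns and
`β(t)⁻¹ = (T−t)σ²`, the diffusion energy `−σ² log p_t(x)` equals the modern
Hopfield energy `u_MH(x, β(t))` up to an x-independent constant, so the two
dynamics share fixed points. The package verifies this identity numerically
(to ~1e-15), shows that deterministic denoising, learned denoising and
softmax retrieval land on the same binarized attractors, and measures their
agreement and storage capacity on synthetic pattern sets. It is aimed at
researchers in computational neuroscience and energy-based machine learning
who want a compact, fully testable reference implementation of this
correspondence.

## Worked example

Estimators follow the scikit-learn transformer contract: `fit` stores the
patterns, `transform` retrieves from corrupted queries.

```python
import numpy as np
from hopflow import (ExactDiffusionMemory, ModernHopfieldMemory,
                     generate_patterns, corrupt_gaussian, binarize,
                     hamming_error)

Y = generate_patterns(10, 10, seed=0)            # 10 random ±1 patterns, D=10
queries = corrupt_gaussian(Y, theta=0.68, seed=1)  # keep 68% signal

diffusion = ExactDiffusionMemory(query_noise_level=0.68).fit(Y)
hopfield = ModernHopfieldMemory(beta=5.0, n_updates=150).fit(Y)

out_d = binarize(diffusion.transform(queries))
out_h = binarize(hopfield.transform(queries))

print("per-query Hamming error (diffusion):", hamming_error(out_d, Y))
print("diffusion vs Hopfield agreement:", np.mean(out_d == out_h))
```

Output:

```
per-query Hamming error (diffusion): [0. 0. 0. 0. 0. 0. 0. 0. 0. 0.]
diffusion vs Hopfield agreement: 1.0
```

All ten corrupted queries are recovered exactly, and the diffusion sampler
and the modern Hopfield iteration agree on every coordinate of every
query, which is the point: the two dynamics share their attractors. (On
harder instances — more stored patterns, or pattern sets with close
pairs — both methods start missing, but they keep missing *together*; the
correlation study below quantifies this.)

The experiment drivers (`hopflow.experiments`) scale this up: the
correlation study pools sign-binarized outputs over 100 repetitions and
reports Pearson correlations between method pairs; the capacity study
sweeps the number of stored patterns and reports the largest load whose
corrupted queries are still recovered (Hamming error < 3%) at least half
the time. A thin CLI exposes them:

```bash
hopflow correlate --seed 1 --out results/
hopflow capacity  --seed 1 --out results/
hopflow trajectories --seed 3 --out results/
hopflow landscape --seed 0 --out results/
```

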