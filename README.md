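# pfpca — Poisson functional PCA of neural tuning-curve variability

Neural tuning curves are not fixed: a neuron's firing-rate profile over a
stimulus variable (orientation, direction, ...) fluctuates from one moment
to the next, where a *moment* is one block of a block-randomised design in
which every stimulus is shown once.  `pfpca` decomposes that moment-to-
moment variability directly from spike counts.  It is written for systems
and computational neuroscientists who have per-neuron spike-count matrices
(blocks × stimuli) and want a generative account of how the tuning curve
itself moves — multiplicative gain, additive offsets, shifts, sharpening,
or arbitrary mixtures — rather than a descriptive split into signal and
noise correlations.

## Model

For neuron-level counts `n_t(s)` in a window `Δt`, the log tuning curve of
moment `t` is a Gaussian process over the stimulus grid:

    log μ_t(s) = f(s) + Σ_k α_{k,t} φ_k(s) + ε_t(s),
    n_t(s) | μ_t ~ Poisson(μ_t(s) Δt),

with `f` the mean log tuning curve, `φ_k` smooth unit-norm functional
principal components (fPCs), scores `α_{k,t} ~ N(0, σ_k²)` the per-moment
fluctuation amplitudes, and `ε` white residual noise with variance `σ_0²`.
Equivalently `log μ_t ~ N(f, Σ)` with `Σ = Σ_k σ_k² φ_k φ_kᵀ + σ_0² I`.

Fitting is a two-step procedure:

1. **Latent-rate recovery.**  A Monte-Carlo EM algorithm treats the
   `log μ_t` as missing data: the E-step estimates `E[log μ_t | n_t]` and
   `Cov[log μ_t | n_t]` by self-normalised importance sampling (Gaussian
   prior proposal, Poisson likelihood weights, 10,000 samples per block),
   and the M-step updates `f` and `Σ` by closed-form averages.
2. **Penalised functional PCA.**  The mean is a cubic smoothing spline
   (penalty chosen by generalized cross-validation); each fPC maximises
   `var_t(φᵀ E[log μ_t|n_t]) / (1 + λ ∫ φ''(s)² ds)` under unit norm and
   orthogonality to earlier components; scores are the projections of the
   centred posterior means.

On top of the decomposition the package computes the analyses it enables:
the power-law modulation family `μ_t(s) = μ_0(s)^{1+wα} e^{bα}` with its
regression (`φ1 = b + w f`) and *flatness index*
`Δμ(s_orth)/Δμ(s_pref)` (1 = additive, 0 = multiplicative, < 0 =
sharpening); Fisher information `I(s) = μ(s)[f'(s) + Σ_k α_k φ_k'(s)]²`
with population sums and the FI-modulation index (slope of the FI–activity
relation, exactly 1 under pure shared gain); population score-matrix
structure (correlation ordering, linear dimensionality); and
representational geometry (distance matrices, classical MDS,
characteristic states, shift augmentation).

Two baselines used for comparison are included: conventional PCA on raw
counts and μ-PCA (ordinary PCA on the exponentiated posterior means).

## Worked example

```python
import numpy as np
import pfpca

# a validation dataset: multiplicative-gain fluctuations, 50 moments on a
# 9-point grid, the structured component carrying 80 % of the variance
spec = pfpca.BenchmarkSpec(kind="gain", seed=1)
counts, truth, true_scores = pfpca.build_benchmark(spec)

fit, scores, posterior = pfpca.fit_pfpca(
    counts, K=3, em_config=pfpca.EMConfig(M=10_000, seed=1)
)
print("variance shares:", np.round(scores.variance_shares, 3))
print("first fPC:      ", np.round(fit.phis[0], 3))
sign = np.sign(fit.phis[0] @ truth.phis[0])
r = np.corrcoef(sign * scores.scores[:, 0], true_scores.scores[:, 0])[0, 1]
print("score recovery corr:", round(r, 3))
```

Output:

```
variance shares: [0.783 0.149 0.068]
first fPC:       [0.193 0.166 0.354 0.45  0.422 0.416 0.312 0.248 0.313]
score recovery corr: 0.784
```

The first component carries ~0.8 of the score variance (the generator's
structured share), its shape is roughly flat across the grid — the
signature of multiplicative gain in log-rate space, blurred by Poisson
noise at this sample size — and the per-moment scores track the true
fluctuation amplitudes.  A shell interface wraps the
same pipeline (`pfpca simulate`, `pfpca fit`, `pfpca analyze powerlaw|fi|
population`, `pfpca geometry`, `pfpca report`).

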