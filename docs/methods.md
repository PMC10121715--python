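# Methods

## The generative model

One neuron's spike counts are organised as a B × m matrix: B moments
(blocks of a block-randomised design, each sampling all m stimuli once)
by m stimulus values on a grid in degrees.  Within a moment the tuning
curve is assumed stable; across moments its logarithm fluctuates around a
mean profile:

    log μ_t(s) = f(s) + Σ_k α_{k,t} φ_k(s) + ε_t(s),      α_{k,t} ~ N(0, σ_k²),
    n_t(s) | μ_t ~ Poisson(μ_t(s) Δt),                    ε_t(s) ~ N(0, σ_0²).

The φ_k are unit-Euclidean-norm, mutually orthogonal vectors on the grid
("functional principal components"); the scores α_{k,t} carry the
moment-to-moment fluctuation; σ_0² absorbs the variance not aligned with
the K retained components.  The implied marginal law of the log-rate
vector is N(f, Σ) with Σ = Σ_k σ_k² φ_k φ_kᵀ + σ_0² I, which is exactly
how the simulator draws it.  Modelling in log-rate space makes a constant
φ_k a pure multiplicative gain, and Poisson observations make the counts
over-dispersed whenever any σ² > 0.

## Inference

**Step 1 — Monte-Carlo EM for the latent rates.**  With log μ_t as
missing data, the E-step needs E[log μ_t | n_t] and Cov[log μ_t | n_t].
These are intractable, so they are estimated by self-normalised
importance sampling: the proposal is the current Gaussian prior
N(f̂, Σ̂), the weights are the Poisson likelihoods of the block's counts,
and the Kish effective sample size (Σw)²/Σw² is reported per block as a
degeneracy diagnostic.  The M-step is closed form: f̂ is the average
posterior mean, Σ̂ the average of posterior covariance plus posterior-mean
scatter.  Defaults: M = 10,000 samples per block (configurable; the
per-sample arithmetic runs in single precision because the Monte-Carlo
standard error at typical ESS of a few hundred to a few thousand is
orders of magnitude above float32 resolution), initialisation
f̂⁰ = log((mean count + 0.5)/Δt) and Σ̂⁰ = 0.1·I, stopping when the
relative change of both f̂ and Σ̂ falls below 1e-3 (at most 100
iterations).  The underlying standard-normal draws are generated once per
fit and reused at every iteration (common random numbers); without this
the stopping rule would only measure Monte-Carlo noise.

*Boundary-variance behaviour.*  When the data carry no latent
fluctuation, the maximum-likelihood Σ is 0, but the EM map approaches
that boundary at a third-order rate (the update's deficit is O(v³) in the
variance v), verified against an exact-quadrature one-dimensional EM.  In
practice Σ̂ retains a small positive floor (diagonal ~0.03–0.12 at rates
of 2–5 spikes/s) and f̂ a matching log-normal bias of about −Σ̂_jj/2.
This is a property of the algorithm, not of its Monte-Carlo
implementation; tests and downstream analyses account for it.

**Step 2 — penalised functional PCA of the posterior means.**  The mean
curve minimises Σ_t ‖E[log μ_t|n_t] − f‖² + λ ∫ (f″)² ds; because all
blocks share the grid this is a cubic smoothing spline through the column
means, with λ selected by generalized cross-validation (scipy's
`make_smoothing_spline`) unless set explicitly.  Each fPC maximises the
penalised variance ratio var_t(φᵀ X_t) / (φᵀ(I + λP)φ) subject to
‖φ‖ = 1 and orthogonality to earlier components, where P is the
second-difference curvature matrix scaled by the grid spacing h (so
φᵀPφ ≈ ∫(φ″)² ds).  The solution is a generalized eigenproblem solved by
deflation.  Scores are α̂_{k,t} = φ_kᵀ(E[log μ_t|n_t] − f); variance
shares are var(α̂_k)/Σ var(α̂_k'); σ̂_0² is the mean squared residual of
the centred posterior means after projection on the K components.  Each
fPC's sign is fixed so its grid sum is non-negative (first nonzero entry
positive on ties).

*Quadrature convention.*  All integrals over the stimulus grid are plain
sums (unit weight per grid point).  Two properties motivated this over a
trapezoidal rule: at λ = 0 the decomposition is then *exactly* ordinary
PCA of the centred posterior means (which the tests exploit as a
brute-force oracle), and recovered fPCs live on the same unit-norm scale
as the generative model's, making estimated and true scores directly
comparable without rescaling.

*Roughness penalty default.*  λ_pc defaults to 0.01·h⁴ — h⁴ is the
natural unit of the discrete curvature functional, so the default is
invariant to the grid's units.  A leave-one-block-out reconstruction
criterion is available (`lambda_pc="cv"`) but prefers λ = 0 by
construction (reconstruction error never rewards component smoothness),
leaving the leading component measurably tilted by Poisson-noise
shrinkage on low-rate stimuli; the mild fixed penalty restores the shape
of smooth fluctuation patterns (constant/gain, additive) without
flattening genuinely curved ones (shift, sharpening).  Heavier penalties
(≥ 0.1·h⁴) visibly degrade antisymmetric components and are not used by
default.

## Baselines

Conventional PCA mean-centres the raw count rows and eigendecomposes —
counts are the only observable, so that is what "PCA on the data" means
here.  μ-PCA runs the same Step-1 EM, exponentiates the posterior means,
and applies ordinary PCA in rate space.  Both return components, scores
and variance shares in the same containers as the full estimator, and the
score-recovery comparison aligns every method's component sign to the
ground-truth direction by inner product before correlating scores.

## The synthetic-data generators

The validation protocol uses a bell-shaped tuning curve
μ(s) = 0.5 + 5·f_G(s/20)/f_G(0) (f_G the standard-normal density; baseline
0.5 spikes/s, peak 5.5 spikes/s) on the 9-point grid −90°…90° in 22.5°
steps, with B = 50 moments and Δt = 1 s.  Four fluctuation types are
defined by the normalised difference of log tuning curves at two opposite
excursions: gain (log 1.3μ₀ − log 0.9μ₀, a constant), additive
(log(μ₀+0.4) − log(μ₀−0.2)), shift (log μ₀(s+6) − log μ₀(s−6), evaluated
from the closed form, not grid interpolation), and sharpen (the ±20 %
width-scaled curves' log difference).  Score variances are σ1² = 1.25
(gain), 5.5 (additive), 1.38 (shift), 1.85 (sharpen), and the white-noise
level c solves σ1²/(σ1² + m·c) = 0.8, so the structured component carries
exactly 80 % of the log-rate variance.  Mixtures orthogonalise a second
direction against the first and reuse the printed variance for both
(exact mixture weights are exposed as configuration).  A monotonic
variant replaces the bell curve with a logistic mean log rate rising from
0.5 to ~5.5 spikes/s.

Two control generators close the loop on specific claims: a pure
multiplicative-gain control (constant log-rate fluctuation per moment,
standard deviation matched per neuron to a reference) used to show that
the estimator does not fabricate a mean-dependent first fPC, and a rank-1
population (one shared per-moment fluctuation scaled per neuron) whose
true score matrix has rank exactly 1.

What these generators deliberately do not emulate: trial-to-trial
dependence within a block, non-Poisson dispersion beyond the latent
fluctuations, stimulus-correlated noise, or neuron-to-neuron noise
correlations beyond the shared latent.  Passing tests therefore certify
the estimator under its own model class, not robustness to every failure
mode of cortical data.

## Downstream analyses

**Power law and flatness.**  Ordinary least squares of φ₁ on f gives
slope w, intercept b, an F-test p-value and the fraction index
1 − Σe(s)²/Σφ₁(s)².  Substituting the fitted line into the model yields
μ_t(s) = μ₀(s)^{1+wα} e^{bα}.  The flatness index is computed on a von
Mises tuning curve rescaled to [c, 1] with c = 0.2, width parameter 1, on
a 1° grid of the 180° orientation circle (so the preferred and orthogonal
orientations fall exactly on grid points):
Δμ(s) = μ_α(s) − μ₀(s) − (c·e^{bα} − c), flatness = Δμ(s_orth)/Δμ(s_pref).
The correction term is written in expanded form so that pure gain cancels
to exactly zero in floating point.  The evaluation score defaults to
α = 1 (one standard deviation in normalised units) and is configurable.

**Fisher information.**  I(s) = μ(s)[f′(s) + Σ_k α_k φ_k′(s)]², the
Poisson FI written through the log-rate derivative.  Derivatives come
from natural cubic splines through the fitted grid values (the model
presumes smooth curves; finite differences on a 9-point grid would be
dominated by discretisation).  Stimuli are in degrees, so FI is in
spikes/deg² per window.  Population FI assumes conditional independence
given the fluctuations and sums over neurons and the block's stimuli;
activity is the summed expected count.  The FI-modulation index is the
OLS slope after dividing both series by their across-block means — the
normalisation under which exact proportionality (pure shared gain) gives
exactly 1.

**Population scores and geometry.**  Score correlation matrices are
ordered by average-linkage clustering on 1 − r; dimensionality is the
eigen-share spectrum of the neurons × neurons score covariance, with
per-neuron z-scoring on by default (switchable) so high-variance neurons
do not dominate.  Geometry: pairwise Euclidean distances between state
response vectors, optionally after the square-root variance-stabilising
transform; classical (Torgerson) MDS by double-centring; k-means (10
restarts, seeded) over blocks for characteristic states; shift
augmentation adds 8 copies of each neuron's tuning shifted by 20° steps
around the 180° circle via periodic spline evaluation.  The
multiplicative-gain cone analysis uses raw rates by default because the
radius-proportional-to-gain statement is exact only without the
square-root transform; the fitted-model pipeline defaults to the
transform, matching how Poisson noise is stabilised in practice.

## Problem sizes and determinism

Every stochastic routine takes an integer seed and derives independent
substreams (numpy `SeedSequence`); identical seeds give bitwise-identical
counts, posteriors and fits.  The test suite runs the four-type
score-recovery benchmark at the full reference settings (B = 50,
M = 10,000, ten seeds) and scales the remaining simulation-heavy checks
to sizes where their anchors are stable (M = 1,000–2,000, populations of
8–50 neurons, B = 50–300); the methods' qualitative behaviour is
unchanged at those sizes, and each test states its own tolerance
rationale where it is not obvious.

## Known limitations

- Scores are modelled as independent across moments; no temporal
  smoothing or state dynamics.
- One neuron at a time: the population analyses consume per-neuron fits
  and do not share information across neurons during estimation.
- The EM's boundary-variance floor (above) means very weakly fluctuating
  neurons report a small spurious first-component variance; comparisons
  against controls (not absolute shares) are the reliable readout there.
- The exponential link is fixed; alternative links and non-Poisson
  observation models are out of scope.
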