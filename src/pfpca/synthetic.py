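"""Validation protocols with known ground truth.

Reproduces the simulation designs used to benchmark the estimator: four
single-type tuning-fluctuation datasets (multiplicative gain, additive
modulation, tuning shift, tuning sharpening) on a bell-shaped tuning
curve over a 9-point stimulus grid, mixtures thereof, monotonic
(sigmoidal) tuning variants, and two control generators — a
fluctuation-magnitude-matched pure multiplicative-gain model and a
rank-1 shared-gain population.

Every generator returns the spike counts together with the full ground
truth (decomposition, scores, log rates), so any estimator can be scored
without re-deriving the latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ScoreMatrix,
    SpikeCountMatrix,
    StimulusGrid,
    TuningDecomposition,
    benchmark_grid,
    benchmark_tuning_curve,
    make_fluctuation_fpc,
    make_structured_covariance,
    simulate_counts,
)

__all__ = [
    "SIGMA1_SQUARED",
    "BenchmarkSpec",
    "build_benchmark",
    "build_multiplicative_control",
    "build_rank1_population",
    "build_monotonic_benchmark",
]

# per-type structured score variances of the validation protocol
SIGMA1_SQUARED = {"gain": 1.25, "additive": 5.5, "shift": 1.38, "sharpen": 1.85}


@dataclass
class BenchmarkSpec:
    """One validation dataset: a fluctuation type (or mixture) with its
    variance, the structured share, and the block count.

    ``kind`` is one of gain/additive/shift/sharpen or a tuple of two of
    them for a mixture (orthogonalised second direction).
    """

    kind: str | tuple[str, str] = "gain"
    sigma1_2: float | None = None
    structured_share: float = 0.8
    B: int = 50
    seed: int = 0
    grid: StimulusGrid = field(default_factory=benchmark_grid)

    def __post_init__(self):
        if self.sigma1_2 is None:
            key = self.kind if isinstance(self.kind, str) else self.kind[0]
            self.sigma1_2 = SIGMA1_SQUARED[key]
        if self.sigma1_2 <= 0:
            raise ValueError("sigma1_2 must be positive")
        if not 0 < self.structured_share < 1:
            raise ValueError("structured_share must lie in (0, 1)")


def _decomposition_for(
    kinds: list[str], mu0: np.ndarray, spec: BenchmarkSpec
) -> TuningDecomposition:
    grid = spec.grid
    phis = []
    for kind in kinds:
        phi = make_fluctuation_fpc(kind, mu0, grid)
        for prev in phis:  # orthogonalise mixture directions
            phi = phi - prev * (prev @ phi)
        phi /= np.linalg.norm(phi)
        phis.append(phi)
    phis = np.array(phis)
    m = grid.m
    _, c = make_structured_covariance(phis[0], spec.sigma1_2, spec.structured_share)
    if len(kinds) == 1:
        sigma_k2 = np.array([spec.sigma1_2])
    else:
        # mixtures share the printed variance across both directions
        sigma_k2 = np.array([spec.sigma1_2, spec.sigma1_2 * 0.99999])
    sigma_k2 = np.sort(sigma_k2)[::-1]
    return TuningDecomposition(
        grid=grid, f=np.log(mu0), phis=phis, sigma_k2=sigma_k2,
        sigma0_2=c, dt=1.0,
    )


def build_benchmark(
    spec: BenchmarkSpec,
) -> tuple[SpikeCountMatrix, TuningDecomposition, ScoreMatrix]:
    """Generate one validation dataset with ground truth.

    Log-rate fluctuations are Gaussian with covariance
    sigma1^2 phi phi' + c I, c solved so the structured component carries
    ``structured_share`` (default 80 %) of the variance; counts are
    conditionally Poisson off the bell-shaped benchmark tuning curve.
    """
    mu0 = benchmark_tuning_curve(spec.grid)
    kinds = [spec.kind] if isinstance(spec.kind, str) else list(spec.kind)
    decomp = _decomposition_for(kinds, mu0, spec)
    counts, scores, _log_mu = simulate_counts(decomp, spec.B, spec.seed)
    return counts, decomp, scores


def build_multiplicative_control(
    reference_scores_sd: np.ndarray,
    mean_log_rate: np.ndarray,
    B: int,
    seed: int,
    grid: StimulusGrid | None = None,
    dt: float = 1.0,
) -> list[tuple[SpikeCountMatrix, TuningDecomposition, ScoreMatrix]]:
    """Pure multiplicative-gain control data, magnitude-matched per neuron.

    For each neuron the per-moment log tuning curve is the mean log rate
    plus a stimulus-independent fluctuation whose standard deviation
    matches ``reference_scores_sd`` for that neuron.  Downstream, the
    regression of the first fPC on the mean should produce slopes
    centred near zero for these data.
    """
    sds = np.atleast_1d(np.asarray(reference_scores_sd, float))
    if np.any(sds < 0):
        raise ValueError("score standard deviations must be non-negative")
    mean_log_rate = np.atleast_2d(np.asarray(mean_log_rate, float))
    if mean_log_rate.shape[0] == 1:
        mean_log_rate = np.repeat(mean_log_rate, sds.size, axis=0)
    m = mean_log_rate.shape[1]
    grid = grid or benchmark_grid()
    const = np.full(m, 1.0 / np.sqrt(m))  # unit-norm constant direction
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(sds.size) % (2**31)
    for i, sd in enumerate(sds):
        decomp = TuningDecomposition(
            grid=grid, f=mean_log_rate[i], phis=const[None, :],
            sigma_k2=np.array([sd**2]), sigma0_2=0.0, dt=dt,
        )
        counts, scores, _ = simulate_counts(decomp, B, int(child_seeds[i]))
        out.append((counts, decomp, scores))
    return out


def build_rank1_population(
    n_neurons: int,
    score_sds: np.ndarray,
    B: int = 50,
    seed: int = 0,
    fluct_kind: str = "multiplicative",
    grid: StimulusGrid | None = None,
) -> tuple[list[SpikeCountMatrix], list[TuningDecomposition], np.ndarray]:
    """Rank-1 population: one shared per-moment fluctuation for all neurons.

    A single standard-normal fluctuation g_t is drawn per moment and
    scaled per neuron to the target score standard deviation, so the true
    neurons x blocks score matrix is exactly rank 1.  ``fluct_kind``
    selects the shared direction: multiplicative (constant in log-rate
    space) or additive.
    """
    if n_neurons < 2:
        raise ValueError("need at least two neurons")
    grid = grid or benchmark_grid()
    mu0 = benchmark_tuning_curve(grid)
    if fluct_kind == "multiplicative":
        phi = np.full(grid.m, 1.0 / np.sqrt(grid.m))
    elif fluct_kind == "additive":
        phi = make_fluctuation_fpc("additive", mu0, grid)
    else:
        raise ValueError("fluct_kind must be 'multiplicative' or 'additive'")
    sds = np.broadcast_to(np.asarray(score_sds, float), (n_neurons,))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    g = rng.standard_normal(B)  # shared fluctuation, one per moment
    true_scores = np.outer(sds, g)  # neurons x blocks, rank 1
    counts_list, decomps = [], []
    for i in range(n_neurons):
        log_mu = np.log(mu0)[None, :] + true_scores[i][:, None] * phi[None, :]
        lam = np.exp(log_mu)
        counts = rng.poisson(lam)
        decomp = TuningDecomposition(
            grid=grid, f=np.log(mu0), phis=phi[None, :],
            sigma_k2=np.array([sds[i] ** 2]), sigma0_2=0.0, dt=1.0,
        )
        counts_list.append(SpikeCountMatrix(counts, grid, dt=1.0))
        decomps.append(decomp)
    return counts_list, decomps, true_scores


def _sigmoid_log_rate(grid: StimulusGrid) -> np.ndarray:
    """Monotone sigmoidal mean tuning: rates rise from 0.5 to ~5.5 spikes/s."""
    s = grid.values
    span = s[-1] - s[0]
    mu = 0.5 + 5.0 / (1.0 + np.exp(-(s - s.mean()) / (span / 10.0)))
    return np.log(mu)


def build_monotonic_benchmark(
    spec: BenchmarkSpec,
) -> tuple[SpikeCountMatrix, TuningDecomposition, ScoreMatrix]:
    """Validation dataset with a sigmoidal (monotone) mean tuning curve.

    Fluctuation kinds gain/additive/shift are defined analogously to the
    bell-shaped benchmark, relative to the sigmoidal curve.
    """
    grid = spec.grid
    f = _sigmoid_log_rate(grid)
    mu0 = np.exp(f)
    kinds = [spec.kind] if isinstance(spec.kind, str) else list(spec.kind)
    s = grid.values
    phis = []
    for kind in kinds:
        if kind == "gain":
            d = np.log(1.3 * mu0) - np.log(0.9 * mu0)
        elif kind == "additive":
            d = np.log(mu0 + 0.4) - np.log(mu0 - 0.2)
        elif kind == "shift":
            shifted = lambda off: 0.5 + 5.0 / (
                1.0 + np.exp(-(s + off - s.mean()) / ((s[-1] - s[0]) / 10.0))
            )
            d = np.log(shifted(6.0)) - np.log(shifted(-6.0))
        else:
            raise ValueError(f"unsupported kind {kind!r} for monotonic tuning")
        for prev in phis:
            d = d - prev * (prev @ d)
        d /= np.linalg.norm(d)
        phis.append(d)
    phis = np.array(phis)
    _, c = make_structured_covariance(phis[0], spec.sigma1_2, spec.structured_share)
    sigma_k2 = np.full(len(kinds), spec.sigma1_2)
    if len(kinds) > 1:
        sigma_k2[1:] *= 0.99999
    decomp = TuningDecomposition(
        grid=grid, f=f, phis=phis, sigma_k2=sigma_k2, sigma0_2=c, dt=1.0,
    )
    counts, scores, _ = simulate_counts(decomp, spec.B, spec.seed)
    return counts, decomp, scores
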