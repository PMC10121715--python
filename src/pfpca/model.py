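"""Generative model of moment-to-moment tuning-curve variability.

A neuron's tuning curve mu_t(s) (spikes/s as a function of a stimulus
variable s, in degrees) is allowed to fluctuate from one experimental
block ("moment") to the next.  The model places the fluctuations in
log-rate space:

    log mu_t(s) = f(s) + sum_k alpha_{k,t} phi_k(s) + eps_t(s)

where f is the mean log tuning curve, the phi_k are unit-norm functional
principal components (fPCs), the scores alpha_{k,t} ~ N(0, sigma_k^2)
are the per-moment fluctuation amplitudes, and eps_t(s) ~ N(0, sigma_0^2)
is unstructured residual variability.  Spike counts within a counting
window dt are conditionally Poisson:

    n_t(s) ~ Poisson(mu_t(s) * dt).

This module defines the containers for the model and the data, the
benchmark tuning curve and fluctuation directions used for validation,
and the forward simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StimulusGrid",
    "TuningDecomposition",
    "SpikeCountMatrix",
    "ScoreMatrix",
    "benchmark_grid",
    "benchmark_tuning_curve",
    "make_fluctuation_fpc",
    "make_structured_covariance",
    "simulate_counts",
]

_ORTH_TOL = 1e-8


@dataclass(frozen=True)
class StimulusGrid:
    """An ordered set of stimulus angles (degrees).

    ``periodic`` marks grids covering a circular variable (e.g. 0..180
    orientation); no wraparound is applied unless an operation asks for it.
    """

    values: np.ndarray
    periodic: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two stimulus values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        return float(np.diff(self.values).mean())


def benchmark_grid() -> StimulusGrid:
    """The 9-point validation grid: -90 to 90 degrees in 22.5-degree steps."""
    return StimulusGrid(np.arange(-90.0, 90.0 + 1e-9, 22.5))


@dataclass
class TuningDecomposition:
    """Mean log tuning curve plus fPCs with score variances.

    Parameters
    ----------
    grid : StimulusGrid
    f : (m,) mean log firing rate (log spikes/s) on the grid.
    phis : (K, m) unit-Euclidean-norm, mutually orthogonal fPC vectors.
    sigma_k2 : (K,) score variances, sorted non-increasing.
    sigma0_2 : residual (white-noise) log-rate variance.
    dt : counting-window length in seconds.
    """

    grid: StimulusGrid
    f: np.ndarray
    phis: np.ndarray
    sigma_k2: np.ndarray
    sigma0_2: float = 0.0
    dt: float = 1.0

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.phis = np.atleast_2d(np.asarray(self.phis, dtype=float))
        self.sigma_k2 = np.atleast_1d(np.asarray(self.sigma_k2, dtype=float))
        m = self.grid.m
        if self.f.shape != (m,):
            raise ValueError(f"f must have shape ({m},)")
        if self.phis.shape[1] != m:
            raise ValueError(f"phis must have {m} columns")
        if self.sigma_k2.shape[0] != self.phis.shape[0]:
            raise ValueError("one score variance per fPC required")
        if np.any(self.sigma_k2 < 0) or self.sigma0_2 < 0:
            raise ValueError("variances must be non-negative")
        if np.any(np.diff(self.sigma_k2) > 1e-12):
            raise ValueError("sigma_k2 must be sorted non-increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.phis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("each fPC must have unit Euclidean norm")
        gram = self.phis @ self.phis.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off), initial=0.0) > 1e-6:
            raise ValueError("fPCs must be mutually orthogonal")

    @property
    def K(self) -> int:
        return self.phis.shape[0]

    def covariance(self) -> np.ndarray:
        """Implied log-rate covariance sum_k sigma_k^2 phi_k phi_k' + sigma_0^2 I."""
        m = self.grid.m
        return (self.phis.T * self.sigma_k2) @ self.phis + self.sigma0_2 * np.eye(m)

    def replace(self, **kw) -> "TuningDecomposition":
        return dataclasses.replace(self, **kw)


@dataclass
class SpikeCountMatrix:
    """B x m spike counts for one neuron, columns aligned to the grid."""

    counts: np.ndarray
    grid: StimulusGrid
    dt: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != self.grid.m:
            raise ValueError("counts must be B x m with m matching the grid")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be integral")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.counts = c.astype(np.int64)

    @property
    def B(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]


@dataclass
class ScoreMatrix:
    """Per-moment fluctuation amplitudes alpha_{k,t} (B x K)."""

    scores: np.ndarray
    component_variances: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.component_variances is None:
            self.component_variances = self.scores.var(axis=0)
        self.component_variances = np.atleast_1d(
            np.asarray(self.component_variances, dtype=float)
        )
        if np.any(self.component_variances < 0):
            raise ValueError("component variances must be non-negative")

    @property
    def B(self) -> int:
        return self.scores.shape[0]

    @property
    def K(self) -> int:
        return self.scores.shape[1]

    @property
    def variance_shares(self) -> np.ndarray:
        tot = self.component_variances.sum()
        if tot == 0:
            return np.full_like(self.component_variances, np.nan)
        return self.component_variances / tot


def benchmark_tuning_curve(grid: StimulusGrid | np.ndarray) -> np.ndarray:
    """Bell-shaped benchmark tuning curve, in spikes/s.

    mu(s) = 0.5 + 5 * fG(s/20) / fG(0), with fG the standard normal
    density: baseline 0.5 spikes/s, peak 5.5 spikes/s at s = 0, Gaussian
    falloff with a 20-degree length scale.
    """
    s = grid.values if isinstance(grid, StimulusGrid) else np.asarray(grid, float)
    return 0.5 + 5.0 * stats.norm.pdf(s / 20.0) / stats.norm.pdf(0.0)


def _benchmark_curve_width(s: np.ndarray, width_scale: float) -> np.ndarray:
    # benchmark curve with the Gaussian component's s.d. rescaled
    return 0.5 + 5.0 * stats.norm.pdf(s / (20.0 * width_scale)) / stats.norm.pdf(0.0)


def make_fluctuation_fpc(kind: str, mu0: np.ndarray, grid: StimulusGrid) -> np.ndarray:
    """Reverse-engineer the unit-norm fPC producing a given fluctuation type.

    Each direction is the difference between the log tuning curves at two
    opposite excursions of that fluctuation, normalised to unit Euclidean
    norm on the grid:

    - ``gain``: log(1.3 mu0) - log(0.9 mu0) (constant; pure multiplicative)
    - ``additive``: log(mu0 + 0.4) - log(mu0 - 0.2)
    - ``shift``: log(mu0(s+6)) - log(mu0(s-6)), using the closed-form
      benchmark curve evaluated off-grid
    - ``sharpen``: log of the +/-20 %-width benchmark curves' difference
    """
    s = grid.values
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(mu0 <= 0):
        bad = s[mu0 <= 0]
        raise ValueError(f"mu0 must be positive; non-positive at s={bad}")
    if kind == "gain":
        d = np.log(1.3 * mu0) - np.log(0.9 * mu0)
    elif kind == "additive":
        lo = mu0 - 0.2
        if np.any(lo <= 0):
            bad = s[lo <= 0]
            raise ValueError(f"mu0 - 0.2 must stay positive; violated at s={bad}")
        d = np.log(mu0 + 0.4) - np.log(lo)
    elif kind == "shift":
        d = np.log(benchmark_tuning_curve(s + 6.0)) - np.log(
            benchmark_tuning_curve(s - 6.0)
        )
    elif kind == "sharpen":
        d = np.log(_benchmark_curve_width(s, 0.8)) - np.log(
            _benchmark_curve_width(s, 1.2)
        )
    else:
        raise ValueError(f"unknown fluctuation kind {kind!r}")
    return d / np.linalg.norm(d)


def make_structured_covariance(
    phi: np.ndarray, sigma1_2: float, structured_share: float
) -> tuple[np.ndarray, float]:
    """Covariance Sigma = sigma1^2 phi phi' + c I with a fixed structured share.

    c is solved so that sigma1^2 / (sigma1^2 + m c) equals
    ``structured_share`` (the structured component's share of the total
    log-rate variance, by the trace decomposition).  Returns (Sigma, c).
    """
    phi = np.asarray(phi, dtype=float)
    if not np.isclose(np.linalg.norm(phi), 1.0):
        raise ValueError("phi must have unit norm")
    if sigma1_2 <= 0:
        raise ValueError("sigma1_2 must be positive")
    if not 0 < structured_share < 1:
        raise ValueError("structured_share must lie in (0, 1)")
    m = phi.size
    c = sigma1_2 * (1.0 - structured_share) / (structured_share * m)
    sigma = sigma1_2 * np.outer(phi, phi) + c * np.eye(m)
    return sigma, c


def simulate_counts(
    decomp: TuningDecomposition, B: int, seed: int
) -> tuple[SpikeCountMatrix, ScoreMatrix, np.ndarray]:
    """Draw B moments of Poisson spike counts from the generative model.

    Per moment t: alpha_{k,t} ~ N(0, sigma_k^2), eps_t(s) ~ N(0, sigma_0^2)
    i.i.d. over s, log mu_t = f + sum_k alpha_{k,t} phi_k + eps_t, and
    counts ~ Poisson(mu_t dt).  Returns the counts together with the true
    scores and the true B x m log-rate matrix for recovery testing.
    Identical seeds give identical output.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    K, m = decomp.phis.shape
    alpha = rng.standard_normal((B, K)) * np.sqrt(decomp.sigma_k2)
    eps = rng.standard_normal((B, m)) * np.sqrt(decomp.sigma0_2)
    log_mu = decomp.f[None, :] + alpha @ decomp.phis + eps
    lam = np.exp(log_mu) * decomp.dt
    if not np.all(np.isfinite(lam)):
        t, j = np.argwhere(~np.isfinite(lam))[0]
        raise FloatingPointError(
            f"rate overflow at block {t}, stimulus {decomp.grid.values[j]}"
        )
    counts = rng.poisson(lam)
    scm = SpikeCountMatrix(counts, decomp.grid, dt=decomp.dt)
    return scm, ScoreMatrix(alpha, decomp.sigma_k2.copy()), log_mu
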