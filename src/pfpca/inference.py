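"""Two-step Poisson functional PCA estimator.

Step 1 treats the per-moment log firing-rate vectors log mu_t as missing
data and recovers their posterior moments E[log mu_t | n_t] and
Cov[log mu_t | n_t] with a Monte-Carlo EM algorithm: the log rates are
a-priori Gaussian, log mu_t ~ N(f, Sigma), counts are conditionally
Poisson, and the intractable posterior expectations are estimated by
self-normalised importance sampling with the current Gaussian prior as
proposal.  The M-step updates are closed-form averages:

    f_hat     = (1/B) sum_t E[log mu_t | n_t]
    Sigma_hat = (1/B) sum_t ( Cov[log mu_t | n_t]
                              + (E[..] - f_hat)(E[..] - f_hat)' )

Step 2 runs functional PCA on the recovered posterior means: the mean
component f(s) is a cubic smoothing spline (roughness penalty chosen by
generalized cross-validation), and the fPCs maximise the penalised
variance ratio

    max_phi  var_t( phi' E[log mu_t|n_t] ) / (1 + lambda * phi' P phi),
    ||phi|| = 1,

with P the discretised second-derivative (curvature) penalty; higher
components satisfy the same criterion orthogonally to those already
found.  Scores are alpha_{k,t} = phi_k' (E[log mu_t|n_t] - f).

Numerical conventions: integrals over the stimulus grid are plain sums
(unit quadrature weight per grid point), so the lambda = 0 case is
exactly ordinary PCA of the centred posterior means and recovered fPCs
share the unit-Euclidean-norm scale of the generative model.  The
Monte-Carlo E-step reuses the same underlying normal draws at every EM
iteration (common random numbers), which makes the relative-change
stopping rule meaningful despite Monte-Carlo noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.interpolate import make_smoothing_spline

from .model import ScoreMatrix, SpikeCountMatrix, StimulusGrid, TuningDecomposition

__all__ = [
    "EMConfig",
    "FPCAConfig",
    "PosteriorLogRate",
    "DegenerateWeightsError",
    "e_step",
    "m_step",
    "recover_latent_rates",
    "smooth_mean",
    "penalized_fpca",
    "fit_pfpca",
]

logger = logging.getLogger("pfpca")


class DegenerateWeightsError(RuntimeError):
    """All importance weights vanished; increase M or improve the initialisation."""


@dataclass
class EMConfig:
    """Monte-Carlo EM settings.

    M is the number of Monte-Carlo samples per block and E-step (the
    reference analyses use M = 10,000); tol is the relative-change
    stopping threshold applied to both f_hat and Sigma_hat.
    """

    M: int = 10_000
    max_iter: int = 100
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.M < 100:
            raise ValueError("M must be at least 100")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FPCAConfig:
    """Functional-PCA settings.

    lambda_mean = None selects the mean-spline penalty by generalized
    cross-validation.  lambda_pc = None uses the scale-aware default
    0.01 * spacing^4 (a mild curvature penalty; spacing^4 is the natural
    unit of the discrete int (phi'')^2 ds functional, so the default is
    grid-invariant); lambda_pc = "cv" selects it by leave-one-block-out
    reconstruction error on a log-spaced grid; lambda_pc = 0 disables fPC
    smoothing and reduces the decomposition to ordinary PCA.
    """

    K: int = 3
    lambda_mean: float | None = None
    lambda_pc: float | str | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if isinstance(self.lambda_pc, str) and self.lambda_pc != "cv":
            raise ValueError("lambda_pc must be a number, None, or 'cv'")


@dataclass
class PosteriorLogRate:
    """Posterior moments of the latent log rates, one set per block."""

    post_mean: np.ndarray  # (B, m)
    post_cov: np.ndarray  # (B, m, m)
    ess: np.ndarray  # (B,) effective sample sizes

    @property
    def B(self) -> int:
        return self.post_mean.shape[0]


# ---------------------------------------------------------------------------
# Step 1: Monte-Carlo EM
# ---------------------------------------------------------------------------


def _gaussian_sqrt(Sigma: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix, clipping tiny negative modes."""
    w, V = np.linalg.eigh(Sigma)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def _e_step_batch(
    counts: np.ndarray,
    f_hat: np.ndarray,
    Sigma_hat: np.ndarray,
    dt: float,
    Z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Importance-sampled posterior moments for all blocks at once.

    counts: (B, m) ints; Z: (B, M, m) standard-normal draws (fixed across
    EM iterations).  Proposal = prior N(f_hat, Sigma_hat); weights are the
    Poisson likelihoods of each block's counts.
    """
    B, M, m = Z.shape
    A = _gaussian_sqrt(Sigma_hat)
    # single precision: Monte-Carlo error (ESS ~ 1e2-1e4) dominates the
    # arithmetic error by orders of magnitude, and the exp/matmul over
    # B*M*m samples is the hot path of the whole estimator
    Z2 = np.ascontiguousarray(Z, dtype=np.float32).reshape(B * M, m)
    L = (Z2 @ A.T.astype(np.float32)).reshape(B, M, m)
    L += f_hat.astype(np.float32)
    # log Poisson likelihood up to count-only constants
    logw = np.einsum("bj,bMj->bM", counts.astype(np.float32), L)
    logw -= np.float32(dt) * np.exp(L).sum(axis=2)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    wsum = w.sum(axis=1, dtype=np.float64)
    if np.any(~np.isfinite(wsum)) or np.any(wsum <= 0):
        bad = int(np.argwhere(~np.isfinite(wsum) | (wsum <= 0))[0])
        raise DegenerateWeightsError(
            f"importance weights degenerate for block {bad}; "
            "increase M or improve the initialisation"
        )
    w /= wsum[:, None].astype(np.float32)
    ess = 1.0 / np.einsum("bM,bM->b", w, w, dtype=np.float64)
    mean = np.einsum("bM,bMj->bj", w, L, dtype=np.float64)
    Lc = L - mean.astype(np.float32)[:, None, :]
    cov = np.matmul(np.swapaxes(Lc, 1, 2), w[:, :, None] * Lc).astype(np.float64)
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    return mean, cov, ess


def e_step(
    counts_block: np.ndarray,
    f_hat: np.ndarray,
    Sigma_hat: np.ndarray,
    config: EMConfig,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior mean, covariance and ESS of log mu for one block of counts."""
    counts_block = np.asarray(counts_block, dtype=np.int64)
    m = counts_block.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((1, config.M, m))
    mean, cov, ess = _e_step_batch(
        counts_block[None, :], np.asarray(f_hat, float), np.asarray(Sigma_hat, float),
        dt, Z,
    )
    return mean[0], cov[0], float(ess[0])


def m_step(posteriors: PosteriorLogRate) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form EM parameter updates from the posterior moments."""
    if posteriors.B < 2:
        raise ValueError("m_step needs at least two blocks")
    f_hat = posteriors.post_mean.mean(axis=0)
    dev = posteriors.post_mean - f_hat
    Sigma_hat = posteriors.post_cov.mean(axis=0) + (dev.T @ dev) / posteriors.B
    return f_hat, 0.5 * (Sigma_hat + Sigma_hat.T)


def recover_latent_rates(
    counts: SpikeCountMatrix, config: EMConfig
) -> tuple[PosteriorLogRate, np.ndarray, np.ndarray, list[dict]]:
    """Run the Monte-Carlo EM until the parameters stabilise.

    Returns the final posterior moments, f_hat, Sigma_hat and a per-
    iteration trajectory log.  Deterministic for a fixed config.seed.
    """
    C = counts.counts
    B, m = C.shape
    if np.any(C.sum(axis=0) == 0):
        warnings.warn(
            "some stimulus columns have no spikes; their log rates are weakly "
            "identified",
            RuntimeWarning,
        )
    # initialisation: additive 0.5 avoids log 0 at silent stimuli
    f_hat = np.log((C.mean(axis=0) + 0.5) / counts.dt)
    Sigma_hat = 0.1 * np.eye(m)

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    # common random numbers: fixed across EM iterations
    Z = rng.standard_normal((B, config.M, m)).astype(np.float32)

    trajectory: list[dict] = []
    for it in range(config.max_iter):
        try:
            mean, cov, ess = _e_step_batch(C, f_hat, Sigma_hat, counts.dt, Z)
        except DegenerateWeightsError as err:
            raise DegenerateWeightsError(f"iteration {it}: {err}") from err
        post = PosteriorLogRate(mean, cov, ess)
        f_new, Sigma_new = m_step(post)
        df = np.linalg.norm(f_new - f_hat) / max(np.linalg.norm(f_hat), 1.0)
        dS = np.linalg.norm(Sigma_new - Sigma_hat) / max(
            np.linalg.norm(Sigma_hat), 1.0
        )
        trajectory.append(
            {"iter": it, "df": float(df), "dSigma": float(dS),
             "min_ess": float(ess.min())}
        )
        logger.debug(
            "EM iter %d: df=%.2e dSigma=%.2e min_ess=%.0f", it, df, dS, ess.min()
        )
        f_hat, Sigma_hat = f_new, Sigma_new
        if max(df, dS) < config.tol:
            break
    return post, f_hat, Sigma_hat, trajectory


# ---------------------------------------------------------------------------
# Step 2: smoothed mean + penalised functional PCA
# ---------------------------------------------------------------------------


def smooth_mean(
    post_mean: np.ndarray, grid: StimulusGrid, config: FPCAConfig | None = None
) -> np.ndarray:
    """Cubic-smoothing-spline estimate of the mean log tuning curve.

    Minimises sum_t ||E[log mu_t|n_t] - f||^2 + lambda * int (f'')^2 ds;
    because all blocks share the grid this is a smoothing spline through
    the column means.  lambda is chosen by generalized cross-validation
    when the config leaves it unset; with lambda = 0 the result equals the
    raw column mean.
    """
    config = config or FPCAConfig()
    post_mean = np.atleast_2d(np.asarray(post_mean, float))
    ybar = post_mean.mean(axis=0)
    m = grid.m
    if m < 4:
        warnings.warn("fewer than 4 grid points; returning the unpenalised mean",
                      RuntimeWarning)
        return ybar
    lam = config.lambda_mean
    if lam == 0:
        return ybar
    spl = make_smoothing_spline(grid.values, ybar, lam=lam)
    return spl(grid.values)


def _second_difference_penalty(grid: StimulusGrid) -> np.ndarray:
    """Discrete curvature penalty P with phi' P phi ~ int (phi'')^2 ds."""
    m, h = grid.m, grid.spacing
    D = np.zeros((m - 2, m))
    for i in range(m - 2):
        D[i, i : i + 3] = [1.0, -2.0, 1.0]
    D /= h**2
    return h * (D.T @ D)


def _penalized_components(
    S: np.ndarray, P: np.ndarray, K: int, lam: float
) -> np.ndarray:
    """Top-K penalised components by deflation.

    Component k maximises phi'S phi / (phi'(I + lam P)phi) subject to
    ||phi|| = 1 and Euclidean orthogonality to components 1..k-1.
    """
    m = S.shape[0]
    G = np.eye(m) + lam * P
    phis = np.zeros((K, m))
    basis = np.eye(m)
    for k in range(K):
        Zb = basis  # (m, m-k) orthonormal complement basis
        w, V = linalg.eigh(Zb.T @ S @ Zb, Zb.T @ G @ Zb)
        phi = Zb @ V[:, -1]
        phi /= np.linalg.norm(phi)
        phis[k] = phi
        # shrink the working basis to the orthogonal complement
        proj = np.eye(m) - phis[: k + 1].T @ phis[: k + 1]
        U, sv, _ = np.linalg.svd(proj)
        basis = U[:, sv > 1e-10]
    return phis


def _loo_lambda_pc(Xc: np.ndarray, P: np.ndarray, K: int, h: float) -> float:
    """Leave-one-block-out reconstruction error over a log-spaced grid."""
    B = Xc.shape[0]
    # curvature penalties are O(h^-4); scale candidates so the ratio's
    # denominator moves through ~1
    cands = [0.0] + list(np.array([1e-3, 1e-2, 1e-1, 1.0, 10.0]) * h**4)
    errs = []
    for lam in cands:
        err = 0.0
        for t in range(B):
            rest = np.delete(Xc, t, axis=0)
            S = (rest.T @ rest) / rest.shape[0]
            phis = _penalized_components(S, P, K, lam)
            x = Xc[t]
            err += float(np.sum((x - phis.T @ (phis @ x)) ** 2))
        errs.append(err)
    return cands[int(np.argmin(errs))]


def penalized_fpca(
    post_mean: np.ndarray,
    f: np.ndarray,
    grid: StimulusGrid,
    config: FPCAConfig,
) -> tuple[np.ndarray, ScoreMatrix, np.ndarray]:
    """Penalised functional PCA of the centred posterior mean log rates.

    Returns (phis (K, m), ScoreMatrix, variance shares).  Scores are the
    projections alpha_{k,t} = phi_k'(E[log mu_t|n_t] - f); variance shares
    are var(alpha_k) / sum_k' var(alpha_k').
    """
    post_mean = np.atleast_2d(np.asarray(post_mean, float))
    B, m = post_mean.shape
    K = config.K
    if K > m:
        raise ValueError("K cannot exceed the number of grid points")
    Xc = post_mean - np.asarray(f, float)[None, :]
    S = (Xc.T @ Xc) / B
    rank = int(np.linalg.matrix_rank(S, tol=1e-10))
    if K > rank:
        warnings.warn(
            f"sample covariance has rank {rank} < K={K}; reducing K",
            RuntimeWarning,
        )
        K = max(rank, 1)
    P = _second_difference_penalty(grid)
    lam = config.lambda_pc
    if lam is None:
        lam = 0.01 * grid.spacing**4
    elif lam == "cv":
        lam = _loo_lambda_pc(Xc, P, K, grid.spacing)
    phis = _penalized_components(S, P, K, lam)
    scores = Xc @ phis.T
    variances = scores.var(axis=0)
    order = np.argsort(variances)[::-1]
    phis, scores, variances = phis[order], scores[:, order], variances[order]
    shares = variances / variances.sum() if variances.sum() > 0 else variances
    return phis, ScoreMatrix(scores, variances), shares


def _fix_signs(phis: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix each fPC's sign: sum over the grid >= 0, ties broken by the
    first nonzero entry being positive."""
    phis = phis.copy()
    scores = scores.copy()
    for k in range(phis.shape[0]):
        s = phis[k].sum()
        if abs(s) < 1e-8:
            nz = np.nonzero(np.abs(phis[k]) > 1e-12)[0]
            s = phis[k][nz[0]] if nz.size else 1.0
        if s < 0:
            phis[k] = -phis[k]
            scores[:, k] = -scores[:, k]
    return phis, scores


def fit_pfpca(
    counts: SpikeCountMatrix,
    K: int = 3,
    em_config: EMConfig | None = None,
    fpca_config: FPCAConfig | None = None,
) -> tuple[TuningDecomposition, ScoreMatrix, PosteriorLogRate]:
    """Full two-step Pf-PCA fit of one neuron's spike-count matrix."""
    em_config = em_config or EMConfig()
    fpca_config = fpca_config or FPCAConfig(K=K)
    if fpca_config.K != K:
        fpca_config = FPCAConfig(K=K, lambda_mean=fpca_config.lambda_mean,
                                 lambda_pc=fpca_config.lambda_pc)
    post, _f_em, _Sigma_em, _log = recover_latent_rates(counts, em_config)
    f = smooth_mean(post.post_mean, counts.grid, fpca_config)
    phis, score_mat, _shares = penalized_fpca(post.post_mean, f, counts.grid,
                                              fpca_config)
    phis, scores = _fix_signs(phis, score_mat.scores)
    Xc = post.post_mean - f[None, :]
    resid = Xc - scores @ phis
    sigma0_2 = float(np.mean(resid**2))
    variances = scores.var(axis=0)
    decomp = TuningDecomposition(
        grid=counts.grid, f=f, phis=phis, sigma_k2=variances,
        sigma0_2=sigma0_2, dt=counts.dt,
    )
    return decomp, ScoreMatrix(scores, variances), post
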