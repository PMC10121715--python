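"""Power-law modulation, fPC-on-mean regression, and the flatness index.

Across many neurons the first fPC is well described as a linear function
of the mean log tuning curve, phi_1(s) = b + w f(s) + e(s).  Substituted
back into the generative model this yields a power-law family of tuning
modulations,

    mu_t(s) = mu_0(s)^(1 + w alpha_t) * exp(b alpha_t),

which contains pure multiplicative gain (w = 0) and approximately
additive modulation as special cases.  The flatness index locates a
modulation on that continuum: for a tuning curve mu_0 with baseline c,

    Delta-mu(s) = mu_alpha(s) - mu_0(s) - c (exp(b alpha) - 1),
    flatness    = Delta-mu(s_orth) / Delta-mu(s_pref),

so additive modulation scores 1, multiplicative gain scores 0, and
sharpening scores below 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PowerLawFit",
    "FlatnessConfig",
    "regress_fpc_on_mean",
    "powerlaw_tuning",
    "flatness_index",
    "flatness_map",
    "vonmises_tuning",
]


@dataclass
class PowerLawFit:
    """OLS fit of phi_1(s) = b + w f(s) + e(s)."""

    b: float
    w: float
    residuals: np.ndarray
    p_value: float
    fraction: float


@dataclass
class FlatnessConfig:
    """Von Mises construction on which flatness is evaluated.

    The baseline c and peak fix the tuning curve's range; the evaluation
    uses a 1-degree grid over the 180-degree orientation domain, so the
    preferred and orthogonal orientations fall exactly on grid points.
    """

    c: float = 0.2
    peak: float = 1.0
    vonmises_width: float = 1.0
    alpha_eval: float = 1.0
    pref: float = 90.0
    resolution: float = 1.0

    def __post_init__(self):
        if not 0 < self.c < self.peak:
            raise ValueError("need 0 < c < peak")


def regress_fpc_on_mean(phi1: np.ndarray, f: np.ndarray) -> PowerLawFit:
    """Ordinary least squares of the first fPC on the mean component.

    The F-test p-value assesses the regression; the fraction index
    1 - sum e(s)^2 / sum phi_1(s)^2 quantifies how much of the first fPC
    a linear function of the mean explains.
    """
    phi1 = np.asarray(phi1, float)
    f = np.asarray(f, float)
    if phi1.shape != f.shape or phi1.size < 3:
        raise ValueError("phi1 and f must be equal-length vectors of size >= 3")
    if np.ptp(f) < 1e-12:
        raise ValueError("mean component is constant; regression degenerate")
    res = sm.OLS(phi1, sm.add_constant(f)).fit()
    resid = np.asarray(res.resid)
    fraction = 1.0 - float(np.sum(resid**2) / np.sum(phi1**2))
    return PowerLawFit(
        b=float(res.params[0]),
        w=float(res.params[1]),
        residuals=resid,
        p_value=float(res.f_pvalue),
        fraction=fraction,
    )


def powerlaw_tuning(mu0: np.ndarray, b: float, w: float, alpha: float) -> np.ndarray:
    """Power-law modulated tuning curve mu0^(1+w*alpha) * exp(b*alpha)."""
    mu0 = np.asarray(mu0, float)
    if np.any(mu0 <= 0):
        raise ValueError("mu0 must be positive")
    return mu0 ** (1.0 + w * alpha) * np.exp(b * alpha)


def vonmises_tuning(config: FlatnessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Von Mises orientation tuning rescaled to the range [c, peak].

    Returns (orientation grid in degrees over [0, 180), mu0).  The
    orientation variable is 180-degree periodic, so the cosine runs at
    twice the angle.
    """
    s = np.arange(0.0, 180.0, config.resolution)
    kappa = config.vonmises_width
    vm = np.exp(kappa * np.cos(2.0 * np.radians(s - config.pref)))
    vm = (vm - vm.min()) / (vm.max() - vm.min())
    return s, config.c + (config.peak - config.c) * vm


def flatness_index(
    b: float,
    w: float,
    alpha: float | None = None,
    config: FlatnessConfig | None = None,
    mu_alpha: np.ndarray | None = None,
) -> float:
    """Flatness of a tuning modulation: Delta-mu(s_orth) / Delta-mu(s_pref).

    By default the modulated curve is the power-law family evaluated at
    alpha (config.alpha_eval when alpha is None).  Pass ``mu_alpha``
    explicitly for non-power-law modulations, e.g. the additive case
    mu0 + c_add * alpha.
    """
    config = config or FlatnessConfig()
    if alpha is None:
        alpha = config.alpha_eval
    s, mu0 = vonmises_tuning(config)
    if mu_alpha is None:
        mu_a = powerlaw_tuning(mu0, b, w, alpha)
    else:
        mu_a = np.asarray(mu_alpha, float)
        if mu_a.shape != mu0.shape:
            raise ValueError("explicit mu_alpha must be on the evaluation grid")
    # correction written as c*e^(b a) - c so that, at the orthogonal
    # orientation (mu0 = c exactly), pure gain cancels to exactly zero
    delta = mu_a - mu0 - (config.c * np.exp(b * alpha) - config.c)
    i_pref = int(np.argmax(mu0))
    i_orth = int(np.argmin(np.abs((s - (s[i_pref] + 90.0)) % 180.0)))
    if delta[i_pref] == 0:
        raise ZeroDivisionError("Delta-mu at the preferred orientation is zero")
    return float(delta[i_orth] / delta[i_pref])


def flatness_map(
    b_grid: np.ndarray,
    w_grid: np.ndarray,
    alpha: float | None = None,
    config: FlatnessConfig | None = None,
) -> np.ndarray:
    """Flatness evaluated on a Cartesian (b, w) grid.

    Undefined cells (Delta-mu(s_pref) = 0) come back as NaN rather than
    raising.  Rows index b, columns index w.
    """
    b_grid = np.atleast_1d(np.asarray(b_grid, float))
    w_grid = np.atleast_1d(np.asarray(w_grid, float))
    out = np.full((b_grid.size, w_grid.size), np.nan)
    for i, b in enumerate(b_grid):
        for j, w in enumerate(w_grid):
            try:
                out[i, j] = flatness_index(b, w, alpha, config)
            except ZeroDivisionError:
                pass
    return out
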