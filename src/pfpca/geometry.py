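"""Representational geometry of population codes under tuning fluctuations.

A population's expected responses to a set of states (stimulus
orientation crossed with a fluctuation condition, e.g. a gain level or a
characteristic fluctuation state) form a matrix whose pairwise Euclidean
distances — optionally after the square-root variance-stabilising
transform for Poisson noise — define a representational distance matrix.
Classical MDS embeds it in a few dimensions.  A homogeneous von Mises
population under shared multiplicative gain produces concentric
per-gain rings (a cone), with ring radius proportional to gain when raw
rates are used; fitted models are summarised by k-means characteristic
states, and a shift augmentation makes the code approximately
shift-invariant before computing distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .model import TuningDecomposition
from .population import PopulationScoreMatrix

__all__ = [
    "PopulationCode",
    "PopulationGeometry",
    "homogeneous_vonmises_population",
    "representational_distance",
    "classical_mds",
    "characteristic_states",
    "shift_augment",
    "representation_radius",
]


@dataclass
class PopulationCode:
    """Expected rates per (orientation, condition) state."""

    rates: np.ndarray  # (states, neurons)
    state_labels: list  # (orientation_deg, condition) per state
    transform: str = "none"

    def __post_init__(self):
        self.rates = np.atleast_2d(np.asarray(self.rates, float))
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.transform not in ("none", "sqrt"):
            raise ValueError("transform must be 'none' or 'sqrt'")
        if len(self.state_labels) != self.rates.shape[0]:
            raise ValueError("one label per state required")

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]


@dataclass
class PopulationGeometry:
    """State-by-state distances with their low-dimensional MDS embedding."""

    distances: np.ndarray
    embedding: np.ndarray
    eigenvalues: np.ndarray


def homogeneous_vonmises_population(
    n_neurons: int,
    width: float = 1.0,
    gains: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    n_orient: int = 180,
    peak_rate: float = 1.0,
) -> PopulationCode:
    """Homogeneous von Mises orientation code under shared gain levels.

    Preferred orientations are equispaced on the 180-degree orientation
    circle; each neuron's tuning is exp(width * (cos 2(s - pref) - 1))
    scaled to ``peak_rate``, and every gain level scales all neurons
    alike.  With the defaults this yields 180 orientations x 4 gains =
    720 states.
    """
    if n_neurons < 2:
        raise ValueError("need at least two neurons")
    prefs = np.arange(n_neurons) * 180.0 / n_neurons
    orients = np.arange(n_orient) * 180.0 / n_orient
    delta = np.radians(orients[:, None] - prefs[None, :])
    tuning = peak_rate * np.exp(width * (np.cos(2.0 * delta) - 1.0))
    rates, labels = [], []
    for g in gains:
        rates.append(g * tuning)
        labels.extend((float(o), float(g)) for o in orients)
    return PopulationCode(np.vstack(rates), labels, transform="none")


def representational_distance(code: PopulationCode) -> np.ndarray:
    """Pairwise Euclidean state distances under the configured transform."""
    X = code.rates
    if code.transform == "sqrt":
        X = np.sqrt(X)
    return squareform(pdist(X, metric="euclidean"))


def classical_mds(distances: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres -D^2/2 and eigendecomposes; returns the top-d
    coordinates (centred at the origin) and the full non-increasing
    eigenvalue spectrum.  Dimensions beyond the count of positive
    eigenvalues are zero-padded with a warning.
    """
    D = np.asarray(distances, float)
    n = D.shape[0]
    if d < 1:
        raise ValueError("d must be at least 1")
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    n_pos = int(np.sum(w > 1e-10 * max(w[0], 1.0)))
    if d > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {d - n_pos} "
            "dimensions with zeros",
            RuntimeWarning,
        )
    coords = np.zeros((n, d))
    k = min(d, n_pos)
    coords[:, :k] = V[:, :k] * np.sqrt(w[:k])
    return coords, w


def characteristic_states(
    psm: PopulationScoreMatrix, k: int = 10, seed: int = 0
) -> np.ndarray:
    """k-means summary of recurring population fluctuation patterns.

    Clusters the blocks (samples) of the neurons x blocks score matrix
    into k groups and returns the k x neurons matrix of within-cluster
    mean scores, ordered by decreasing total mean score (a proxy for the
    implied population activity).  Deterministic under seed.
    """
    if psm.n_blocks < k:
        raise ValueError("need at least k blocks")
    X = psm.scores.T  # blocks x neurons
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    centers = np.vstack([X[labels == i].mean(axis=0) for i in range(k)])
    order = np.argsort(centers.sum(axis=1))[::-1]
    return centers[order]


def _periodic_eval(grid_vals: np.ndarray, y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Evaluate y (defined on a grid over the 180-degree circle) at angles s."""
    x = np.append(grid_vals, grid_vals[0] + 180.0)
    yy = np.append(y, y[0])
    spl = CubicSpline(x, yy, bc_type="periodic")
    return spl(np.mod(s - grid_vals[0], 180.0) + grid_vals[0])


def shift_augment(
    decomps: list[TuningDecomposition],
    state_scores: np.ndarray | None = None,
    n_shifts: int = 8,
    step: float = 20.0,
    orientations: np.ndarray | None = None,
    transform: str = "sqrt",
) -> PopulationCode:
    """Shift-invariant population code from fitted per-neuron models.

    For each characteristic state (row of ``state_scores``, one first-fPC
    score per neuron; a single zero-score state when omitted) the tuning
    curve of every neuron is exp(f + alpha phi_1), evaluated at the
    requested orientations, and augmented with ``n_shifts`` copies shifted
    by multiples of ``step`` degrees around the 180-degree circle — so
    the neuron count multiplies by n_shifts + 1.  Requires a periodic
    stimulus grid.
    """
    if not decomps:
        raise ValueError("need at least one decomposition")
    grid = decomps[0].grid
    if not grid.periodic:
        raise ValueError("shift augmentation requires a circular stimulus grid")
    n = len(decomps)
    if state_scores is None:
        state_scores = np.zeros((1, n))
    state_scores = np.atleast_2d(np.asarray(state_scores, float))
    if state_scores.shape[1] != n:
        raise ValueError("one score per neuron per state required")
    if orientations is None:
        orientations = grid.values
    orientations = np.asarray(orientations, float)
    shifts = np.arange(n_shifts + 1) * step
    rates, labels = [], []
    for i_state, alphas in enumerate(state_scores):
        cols = []
        for decomp, a in zip(decomps, alphas):
            for sh in shifts:
                log_mu = _periodic_eval(
                    grid.values, decomp.f, orientations - sh
                ) + a * _periodic_eval(grid.values, decomp.phis[0], orientations - sh)
                cols.append(np.exp(log_mu))
        rates.append(np.column_stack(cols))
        labels.extend((float(o), i_state) for o in orientations)
    return PopulationCode(np.vstack(rates), labels, transform=transform)


def representation_radius(embedding: np.ndarray, state_group: np.ndarray) -> float:
    """Mean distance of a state group from its centroid (first two dims)."""
    emb = np.asarray(embedding, float)
    idx = np.asarray(state_group)
    pts = emb[idx, :2]
    if pts.shape[0] < 3:
        raise ValueError("state group needs at least 3 states")
    r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    if np.allclose(r, 0.0):
        warnings.warn("degenerate state group; radius 0", RuntimeWarning)
        return 0.0
    return float(r.mean())
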