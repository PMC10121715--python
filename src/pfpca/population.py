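"""Population structure of first-fPC scores.

Concatenating each neuron's first-fPC scores gives a neurons x blocks
matrix whose correlation structure and linear dimensionality reveal how
much of the moment-to-moment fluctuation is shared across the
population.  A rank-1 shared-gain population produces a score matrix
whose spectrum is dominated by a single component; richer fluctuation
structure spreads variance over more components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = ["PopulationScoreMatrix", "score_correlation", "score_dimensionality"]


@dataclass
class PopulationScoreMatrix:
    """Neurons x blocks matrix of first-fPC scores."""

    scores: np.ndarray
    neuron_ids: list | None = None
    block_ids: list | None = None

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, float))
        if self.scores.shape[0] < 2:
            raise ValueError("need at least two neurons")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix must have no missing entries")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(self.scores.shape[0]))

    @property
    def n_neurons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.scores.shape[1]


def score_correlation(
    psm: PopulationScoreMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-block Pearson correlations with a clustering-based ordering.

    Returns (correlation matrix, leaf ordering).  The ordering comes from
    average-linkage hierarchical clustering on the 1 - r distance, the
    standard heat-map arrangement placing correlated neurons adjacently.
    Zero-variance neurons are excluded with a warning (their correlation
    rows are NaN and they are dropped from the ordering).
    """
    X = psm.scores
    var = X.var(axis=1)
    keep = var > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance neuron(s)",
            RuntimeWarning,
        )
        X = X[keep]
    if X.shape[0] < 2:
        raise ValueError("fewer than two neurons with positive score variance")
    r = np.corrcoef(X)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return r, np.asarray(order)


def score_dimensionality(
    psm: PopulationScoreMatrix, standardize: bool = True
) -> np.ndarray:
    """Variance-share spectrum of the population score matrix.

    PCA across neurons (blocks as samples); by default each neuron's
    scores are z-scored first so high-variance neurons do not dominate
    the spectrum.  Returns eigenvalue shares summing to 1.
    """
    X = psm.scores
    if psm.n_blocks < 2:
        raise ValueError("need at least two blocks")
    if standardize:
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = (Xc @ Xc.T) / psm.n_blocks
    w = np.linalg.eigvalsh(cov)[::-1]
    w = np.clip(w, 0.0, None)
    return w / w.sum()
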