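"""Z-score normalisation and Sammon's non-linear 2-D projection.

The five vitals live on very different scales (mmHg vs °C), so every
observation is first normalised to zero mean and unit variance using
moments computed over the whole filtered cohort.  Sammon's mapping then
seeks 2-D image points whose pairwise Euclidean distances match the
input-space distances, by minimising the stress

    E = (1 / sum_{i<j} D_ij) * sum_{i<j} (D_ij - d_ij)^2 / D_ij

where D_ij are input-space and d_ij map-space distances.  Minimisation
uses Sammon's diagonal-Newton update scaled by a "magic factor" of 0.3,
with step halving whenever a step would increase the stress, so the
recorded stress sequence is non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .cohort import Cohort, VITALS


@dataclass
class NormalizationParams:
    """Per-vital mean and SD (sample convention) in natural units."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive componentwise")


def fit_normalization(cohort: Cohort) -> NormalizationParams:
    """Moments over every complete observation of every patient (both groups)."""
    X = cohort.all_observations()
    if X.shape[0] < 2:
        raise ValueError("need at least two observations to fit normalisation")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    for i, v in enumerate(VITALS):
        if sigma[i] <= 0:
            raise ValueError(f"zero variance in vital sign {v!r}")
    return NormalizationParams(mu=mu, sigma=sigma)


def normalize(x, params: NormalizationParams) -> np.ndarray:
    """(x - mu) / sigma, componentwise; works on vectors or (n, 5) matrices."""
    return (np.asarray(x, dtype=float) - params.mu) / params.sigma


def denormalize(xn, params: NormalizationParams) -> np.ndarray:
    return np.asarray(xn, dtype=float) * params.sigma + params.mu


# ---------------------------------------------------------------------------
# Sammon mapping


@dataclass
class SammonEmbedding:
    points: np.ndarray          # (n, 2) image coordinates
    stress: float
    n_iterations: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def _pair_mask(D: np.ndarray) -> np.ndarray:
    """Off-diagonal pairs with non-zero input distance (duplicates skipped)."""
    mask = D > 0
    np.fill_diagonal(mask, False)
    return mask


def sammon_stress(X, Y, input_distances: np.ndarray | None = None) -> float:
    """Evaluate the Sammon stress of map coordinates ``Y`` for inputs ``X``.

    Duplicate input points (zero input-space distance) are skipped in both
    sums, where the stress is undefined.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of points")
    if X.shape[0] < 2:
        raise ValueError("need at least two points")
    D = squareform(pdist(X)) if input_distances is None else input_distances
    if not np.any(D > 0):
        raise ValueError("all pairwise input distances are zero")
    d = cdist(Y, Y)
    mask = np.triu(_pair_mask(D))
    c = D[mask].sum()
    return float(np.sum((D[mask] - d[mask]) ** 2 / D[mask]) / c)


def sammon_embed(
    X,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    step: float = 0.3,
    init: str = "random",
) -> SammonEmbedding:
    """Project points to 2-D by minimising the Sammon stress.

    Image points start at uniform-random locations in [-1, 1]^2 (or at the
    first two principal components with ``init="pca"``) and are updated with
    the diagonal-Newton rule scaled by ``step``; any update that would raise
    the stress is halved until it does not.  Convergence is declared when
    the relative stress change drops below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three points to embed")
    D = squareform(pdist(X))
    dup = ~_pair_mask(D)
    np.fill_diagonal(dup, False)
    if dup.any():
        warnings.warn("duplicate input points: their pairs are skipped in the stress")
    mask = _pair_mask(D)
    if not mask.any():
        raise ValueError("all pairwise input distances are zero")
    c = D[np.triu(mask)].sum()

    rng = np.random.default_rng(seed)
    if init == "pca":
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Y = Xc @ vt[:2].T
    elif init == "random":
        Y = rng.uniform(-1.0, 1.0, size=(n, 2))
    else:
        raise ValueError(f"unknown init {init!r}")

    eps = 1e-12
    Dm = np.where(mask, D, 1.0)  # placeholder values never used thanks to mask

    def stress_of(Ycur: np.ndarray) -> float:
        d = cdist(Ycur, Ycur)
        tri = np.triu(mask)
        return float(np.sum((D[tri] - d[tri]) ** 2 / D[tri]) / c)

    stress = stress_of(Y)
    history = [stress]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = cdist(Y, Y)
        d = np.where(d < eps, eps, d)
        delta = D - d
        w = np.where(mask, 1.0 / (Dm * d), 0.0)

        diff = Y[:, None, :] - Y[None, :, :]              # (n, n, 2)
        grad = (-2.0 / c) * np.einsum("ij,ijk->ik", w * delta, diff)
        quad = diff ** 2 / d[:, :, None]
        hess = (-2.0 / c) * np.einsum(
            "ijk->ik",
            w[:, :, None] * (delta[:, :, None] - quad * (1.0 + delta[:, :, None] / d[:, :, None])),
        )
        denom = np.where(np.abs(hess) < eps, eps, np.abs(hess))
        direction = grad / denom

        factor = step
        accepted = False
        for _ in range(30):
            Y_new = Y - factor * direction
            new_stress = stress_of(Y_new)
            if not np.isfinite(new_stress):
                raise FloatingPointError(
                    f"Sammon stress diverged at iteration {it} (stress={new_stress})")
            if new_stress <= stress:
                accepted = True
                break
            factor *= 0.5
        if not accepted:
            # no descent direction even at a vanishing step: local optimum
            converged = True
            break
        rel = (stress - new_stress) / stress if stress > 0 else 0.0
        Y, stress = Y_new, new_stress
        history.append(stress)
        if rel < tol:
            converged = True
            break

    return SammonEmbedding(points=Y, stress=stress, n_iterations=it,
                           converged=converged, stress_history=history)
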