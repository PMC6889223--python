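"""PCA feature selection on Procrustes-aligned coordinates.

Covariance-matrix PCA (the data are never variance-standardized: after
Procrustes fitting all coordinates share a scale, and standardization
would distort the covariance structure).  Two retention rules are
offered: the broken-stick criterion, which keeps leading components
whose variance proportion exceeds the expected length of the
corresponding ordered segment of a randomly broken unit stick, and a
sequential Bartlett sphericity test on the trailing eigenvalues.
Individual components can be exported as 3D deformation fields away from
the mean configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "PCModel",
    "fit_pca",
    "broken_stick_count",
    "bartlett_count",
    "pc_deformation",
]

_RANK_TOL = 1e-10  # eigenvalue > tol * lambda_1 counts as non-zero


@dataclass
class PCModel:
    """Fitted principal components of an (n, p) coordinate matrix."""

    mean: np.ndarray  # (p,)
    eigenvalues: np.ndarray  # descending, length min(n, p)
    loadings: np.ndarray  # (p, n_components), orthonormal columns
    scores: np.ndarray  # (n, n_components)

    @property
    def proportions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_nonzero(self) -> int:
        lam = self.eigenvalues
        if lam[0] <= 0:
            return 0
        return int((lam > _RANK_TOL * lam[0]).sum())

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(data) - self.mean) @ self.loadings


def fit_pca(data: np.ndarray) -> PCModel:
    """Covariance PCA of (n, p) aligned coordinates via SVD.

    Data are mean-centered internally (never standardized); components
    are ordered by descending eigenvalue with the sign convention that
    each loading's largest-magnitude entry is positive.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or len(data) < 2:
        raise ValueError("need an (n >= 2, p) data matrix")
    if not np.isfinite(data).all():
        raise ValueError("non-finite input")
    mean = data.mean(axis=0)
    centered = data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (len(data) - 1)
    loadings = vt.T
    # deterministic sign: largest-|.| entry of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = centered @ loadings
    return PCModel(mean, eigenvalues, loadings, scores)


def broken_stick_count(eigenvalues: np.ndarray) -> int:
    """Broken-stick retention: keep leading components whose variance
    proportion exceeds b_i = (1/p) * sum_{j=i..p} 1/j, stopping at the
    first failure."""
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p == 0 or lam.sum() <= 0:
        raise ValueError("need at least one positive eigenvalue")
    proportions = lam / lam.sum()
    inv = 1.0 / np.arange(1, p + 1)
    b = np.cumsum(inv[::-1])[::-1] / p
    count = 0
    for prop, bi in zip(proportions, b):
        if prop >= bi:  # >= so a lone component (proportion exactly 1) is kept
            count += 1
        else:
            break
    return count


def bartlett_count(eigenvalues: np.ndarray, n: int, alpha: float = 0.05) -> int:
    """Sequential Bartlett sphericity test on trailing eigenvalues.

    For m = 0, 1, ... the null 'the remaining p - m eigenvalues are
    equal' is tested with the chi-square statistic

        X^2 = (n - m - (2q + 1 + 2/q) / 6) * (q * ln(mean) - sum(ln)),
        q = p - m,  df = (q + 2)(q - 1) / 2.

    The retained count is the first m at which the null is not rejected
    at level ``alpha``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p == 0 or np.any(lam < 0) or lam.sum() <= 0:
        raise ValueError("degenerate spectrum")
    for m in range(p):
        rem = lam[m:]
        q = len(rem)
        if q == 1:
            return m
        if rem.min() <= 0:
            # zero trailing eigenvalues: spectrum is rank-deficient;
            # treat as maximally non-spherical and keep going
            continue
        stat = (n - m - (2 * q + 1 + 2.0 / q) / 6.0) * (
            q * np.log(rem.mean()) - np.log(rem).sum()
        )
        df = (q + 2) * (q - 1) / 2.0
        if scipy.stats.chi2.sf(stat, df) > alpha:
            return m
    return p - 1


def pc_deformation(model: PCModel, component: int, magnitude: float) -> np.ndarray:
    """The shape at ``mean + magnitude * loading``, reshaped (k, 3).

    Exported as a field of 3D vectors away from the mean configuration;
    magnitude 0 returns the mean configuration itself.
    """
    if not 0 <= component < model.loadings.shape[1]:
        raise IndexError(f"component {component} out of range")
    flat = model.mean + magnitude * model.loadings[:, component]
    if flat.size % 3:
        raise ValueError("coordinate vector length is not a multiple of 3")
    return flat.reshape(-1, 3)
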