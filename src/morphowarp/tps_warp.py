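"""Three-dimensional thin-plate-spline interpolation and bending energy.

A TPS map ``h : R^3 -> R^3`` through control points decomposes into an
affine part and a non-affine part built from the radial kernel

    psi_w(p) = || p - s_w ||

(the 3D biharmonic spline kernel).  In homogeneous coordinates,

    h(p) = Psi(p) K + p Gamma

with ``K`` an (M, 4) non-affine coefficient matrix and ``Gamma`` a (4, 4)
homogeneous affine matrix.  The coefficients solve the bordered linear
system

    [ Psi - beta*I   S ] [ K     ]   [ T ]
    [ S^T            0 ] [ Gamma ] = [ 0 ]

where ``S``/``T`` are the homogeneous source/target control points and
``beta >= 0`` is a smoothing regularizer: ``beta = 0`` gives exact
interpolation of the control points.  (The regularizer carries a minus
sign here because ``||r||`` is conditionally negative definite; on the
negated, positive-energy kernel it is the usual ``+beta`` ridge.)

The bending energy of the map is the integral of squared second
derivatives over R^3.  For this kernel it reduces (up to a fixed positive
physical constant, dropped throughout) to the quadratic form

    E = -trace(K_xyz^T Psi K_xyz)  >= 0,

zero exactly for affine maps.  The minus sign is forced by the kernel:
``||r||`` is conditionally negative definite under the side condition
``S^T K = 0``, so the negated form is the positive-semidefinite one.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "WarpModel",
    "build_tps",
    "warp_points",
    "bending_energy",
    "bending_energy_matrix",
    "DegenerateControlPointsError",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e12


class DegenerateControlPointsError(ValueError):
    """Coplanar, coincident or otherwise rank-deficient control points."""


def _homogeneous(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return np.hstack([points, np.ones((len(points), 1))])


def _check_control_points(source: np.ndarray) -> None:
    m = len(source)
    if m < 5:
        raise DegenerateControlPointsError(f"need >= 5 control points, got {m}")
    if pdist(source).min() <= 1e-9:
        raise DegenerateControlPointsError("duplicate control points (pairwise distance <= 1e-9)")
    centered = source - source.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0]
    if scale <= 0 or svals[2] / scale < 1e-10:
        raise DegenerateControlPointsError("control points are (near-)coplanar")


@dataclass
class WarpModel:
    """A fitted TPS map from ``source_points`` to ``target_points``."""

    source_points: np.ndarray  # (M, 3)
    target_points: np.ndarray  # (M, 3)
    K: np.ndarray  # (M, 4) non-affine coefficients
    gamma: np.ndarray  # (4, 4) homogeneous affine part
    beta: float = 0.0

    def to_json(self, path) -> None:
        doc = {
            "source_points": self.source_points.tolist(),
            "target_points": self.target_points.tolist(),
            "K": self.K.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WarpModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            np.asarray(doc["source_points"], dtype=float),
            np.asarray(doc["target_points"], dtype=float),
            np.asarray(doc["K"], dtype=float),
            np.asarray(doc["gamma"], dtype=float),
            float(doc["beta"]),
        )


def build_tps(source: np.ndarray, target: np.ndarray, beta: float = 0.0) -> WarpModel:
    """Fit a 3D TPS mapping ``source`` control points onto ``target``.

    Parameters
    ----------
    source, target : (M, 3) arrays, mm.  Corresponding control points.
    beta : smoothing regularization added to the kernel diagonal;
        ``beta = 0`` (default) interpolates the control points exactly.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"source/target must both be (M, 3); got {source.shape} vs {target.shape}")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    _check_control_points(source)

    m = len(source)
    psi = cdist(source, source)
    sh = _homogeneous(source)
    th = _homogeneous(target)
    system = np.zeros((m + 4, m + 4))
    # smoothing enters on the diagonal of the positive-energy form: the
    # ||r|| kernel is conditionally negative definite, so +beta on the
    # negated kernel is -beta here; beta = 0 interpolates exactly
    system[:m, :m] = psi - beta * np.eye(m)
    system[:m, m:] = sh
    system[m:, :m] = sh.T
    rhs = np.zeros((m + 4, 4))
    rhs[:m] = th

    cond = np.linalg.cond(system)
    if cond > _COND_WARN:
        warnings.warn(
            f"TPS system condition number {cond:.3e} exceeds {_COND_WARN:.0e}; "
            "solution may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.debug("TPS solve: M=%d beta=%g cond=%.3e", m, beta, cond)
    try:
        sol = scipy.linalg.solve(system, rhs)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateControlPointsError(f"singular TPS system: {exc}") from None

    K = sol[:m]
    gamma = sol[m:]
    # Homogeneous bookkeeping: the 4th output coordinate must be exactly the
    # constant 1, i.e. K's last column 0 and gamma's last column e4.
    scale = max(np.abs(target).max(), 1.0)
    assert np.abs(K[:, 3]).max() < 1e-6 * scale
    assert np.abs(gamma[:, 3] - np.array([0, 0, 0, 1.0])).max() < 1e-6
    K[:, 3] = 0.0
    gamma[:, 3] = np.array([0, 0, 0, 1.0])
    return WarpModel(source, target, K, gamma, float(beta))


def warp_points(model: WarpModel, points: np.ndarray) -> np.ndarray:
    """Apply the fitted map to arbitrary points, returning (N, 3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    psi = cdist(points, model.source_points)
    h = psi @ model.K + _homogeneous(points) @ model.gamma
    return h[:, :3]


def bending_energy(model: WarpModel) -> float:
    """Bending energy of the fitted map (non-negative; 0 iff affine)."""
    psi = cdist(model.source_points, model.source_points)
    kxyz = model.K[:, :3]
    e = -float(np.trace(kxyz.T @ psi @ kxyz))
    return max(e, 0.0)


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """The (M, M) bending-energy quadratic form for a control-point set.

    Returns the symmetric positive-semidefinite matrix ``B`` (the negated
    upper-left block of the inverse bordered system) such that for any
    per-coordinate displacement field ``u`` of the control points the TPS
    interpolating ``source -> source + u`` has bending energy
    ``sum_c u_c^T B u_c``.  ``B`` annihilates affine functions of the
    source, so its null space has dimension 4 for generic points.
    """
    source = np.asarray(source, dtype=float)
    _check_control_points(source)
    m = len(source)
    psi = cdist(source, source)
    sh = _homogeneous(source)
    system = np.zeros((m + 4, m + 4))
    system[:m, :m] = psi
    system[:m, m:] = sh
    system[m:, :m] = sh.T
    try:
        inv = scipy.linalg.inv(system)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateControlPointsError(f"singular TPS system: {exc}") from None
    b = -inv[:m, :m]
    return 0.5 * (b + b.T)
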