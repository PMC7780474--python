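"""3D thin-plate-spline fitting, warping, and the bending-energy form.

The TPS interpolant between two k-point configurations X (source) and Y
(target) is

    f(p) = a0 + A p + sum_j w_j U(|p - x_j|),        U(r) = r  (3D kernel)

with the non-affine weights W orthogonal to the affine subspace
(P^T W = 0, P = [1 X]).  Solving the bordered system

    [K + lambda I   P] [W]   [Y]
    [P^T            0] [A] = [0]

gives exact interpolation at lambda = 0 and a smoothing fit for
lambda > 0.  The bending energy of the deformation is the quadratic form
trace(Y^T B Y) where B is the upper-left k x k block of the inverse
bordered matrix; B is symmetric, annihilates affine configurations, and
has rank <= k - 4.  Sign conventions for the 3D kernel differ across
references, so the overall sign of B is fixed at build time to make the
form positive semidefinite — the property the sliding criterion relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

log = logging.getLogger(__name__)

__all__ = ["TPSModel", "fit_tps", "warp_points", "bending_energy",
            "bending_energy_matrix"]

_COND_WARN = 1e12


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between every pair of rows of a and b."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


@dataclass
class TPSModel:
    """Fitted thin-plate spline from ``source_points`` to ``target_points``."""

    source_points: np.ndarray       # (k, 3)
    target_points: np.ndarray       # (k, 3)
    nonaffine_weights: np.ndarray   # (k, 3); columns orthogonal to [1 X]
    affine: np.ndarray              # (4, 3); row 0 translation, rows 1:4 linear
    kernel_matrix: np.ndarray       # (k, k)
    bending_energy_matrix: np.ndarray  # (k, k) symmetric PSD, rank <= k-4
    regularization: float = 0.0
    affine_only: bool = False

    def warp(self, probes: np.ndarray) -> np.ndarray:
        return warp_points(self, probes)

    def energy(self) -> float:
        """Bending energy of the fitted deformation."""
        t = self.target_points
        return float(np.trace(t.T @ self.bending_energy_matrix @ t))


def _affine_fallback(source, target):
    k = len(source)
    P = np.hstack([np.ones((k, 1)), source])
    A, *_ = np.linalg.lstsq(P, target, rcond=None)
    return TPSModel(
        source_points=source,
        target_points=target,
        nonaffine_weights=np.zeros((k, 3)),
        affine=A,
        kernel_matrix=_kernel(source, source),
        bending_energy_matrix=np.zeros((k, k)),
        affine_only=True,
    )


def fit_tps(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSModel:
    """Fit a 3D TPS mapping ``source`` onto ``target``.

    lam = 0 gives pure interpolation (the template-warping use); lam > 0
    smooths, which can rescue configurations with near-duplicate points.
    Fewer than 5 points, or a coplanar source, degrades gracefully to an
    affine-only fit.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same shape")
    k = len(source)
    if lam < 0:
        raise ValueError("regularization must be >= 0")
    if k < 5 or _is_coplanar(source):
        return _affine_fallback(source, target)
    K = _kernel(source, source)
    if lam == 0.0:
        # duplicate source points make the system singular
        iu = np.triu_indices(k, 1)
        if (K[iu] == 0).any():
            raise ValueError(
                "duplicate source points with lambda = 0; jitter the points "
                "or use lambda > 0"
            )
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    # U(r) = r is conditionally *negative* definite, so the smoothing term
    # enters with a minus sign (the penalty must oppose -w^T K w)
    L[:k, :k] = K - lam * np.eye(k)
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.vstack([target, np.zeros((4, 3))])
    cond = np.linalg.cond(L)
    if cond > _COND_WARN:
        log.warning("TPS system condition number %.3g exceeds %.1g", cond, _COND_WARN)
    try:
        lu, piv = scipy.linalg.lu_factor(L)
    except scipy.linalg.LinAlgError as e:
        raise ValueError(
            f"singular TPS system ({e}); jitter duplicate points or use "
            "lambda > 0"
        ) from e
    sol = scipy.linalg.lu_solve((lu, piv), rhs)
    W, A = sol[:k], sol[k:]
    # bending-energy matrix: upper-left block of L^-1 (at the same lam),
    # sign-fixed so the quadratic form is PSD
    inv_cols = scipy.linalg.lu_solve((lu, piv), np.eye(k + 4)[:, :k])
    B = inv_cols[:k]
    B = 0.5 * (B + B.T)
    B = _fix_sign(B)
    return TPSModel(
        source_points=source,
        target_points=target,
        nonaffine_weights=W,
        affine=A,
        kernel_matrix=K,
        bending_energy_matrix=B,
        regularization=lam,
    )


def _is_coplanar(points: np.ndarray, rtol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[-1] <= rtol * max(s[0], 1e-300)


def _fix_sign(B: np.ndarray) -> np.ndarray:
    """Orient B so x^T B x >= 0 on the non-affine subspace.

    The 3D kernel U(r) = r is conditionally definite with a sign that
    depends on convention; the dominant eigenvalue of B decides the flip.
    """
    w = np.linalg.eigvalsh(B)
    dominant = w[np.argmax(np.abs(w))]
    if dominant < 0:
        B = -B
    return B


def warp_points(model: TPSModel, probes: np.ndarray) -> np.ndarray:
    """Apply the fitted spline to arbitrary probe points."""
    probes = np.asarray(probes, dtype=float)
    single = probes.ndim == 1
    probes = probes.reshape(-1, 3)
    P = np.hstack([np.ones((len(probes), 1)), probes])
    out = P @ model.affine
    if not model.affine_only:
        out = out + _kernel(probes, model.source_points) @ model.nonaffine_weights
    return out[0] if single else out


def bending_energy_matrix(source: np.ndarray, lam: float = 0.0) -> np.ndarray:
    """The k x k bending-energy quadratic form of a source configuration."""
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    model = fit_tps(src, src, lam=lam)
    return model.bending_energy_matrix


def bending_energy(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> float:
    """Bending energy of the TPS from ``source`` to ``target``.

    Zero iff the deformation is affine; invariant to simultaneous rigid
    motion of both configurations; quadratic in the non-affine displacement.
    """
    model = fit_tps(source, target, lam=lam)
    return model.energy()
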