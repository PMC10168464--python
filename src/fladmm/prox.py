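"""Discrete gradient, isotropic TV, shrinkage and ball projections.

Gradient fields are ndarrays of shape ``(2, n_x, n_y)``: component 0 holds
backward differences along rows, component 1 along columns, with zeros on
the first row / first column (one-sided boundary).  The adjoint is the
mechanical transpose of that stencil, so ``grad`` / ``grad_adjoint`` form
an exact adjoint pair.

These closed-form operators are the building blocks of every ADMM solver
here: 2D shrinkage is the prox of the grouped l2,1 norm, the l2-ball
projection enforces the data-divergence constraint, and the l1-ball
(simplex-type) projection enforces a TV bound on a nonnegative
gradient-magnitude image.
"""

from __future__ import annotations

import numpy as np

from .projector import LinearMap

__all__ = [
    "grad",
    "grad_adjoint",
    "grad_magnitude",
    "tv_norm",
    "shrink1d",
    "shrink2d",
    "project_l2_ball",
    "project_l1_ball",
    "GradientOperator",
]


def grad(u: np.ndarray) -> np.ndarray:
    """Backward-difference gradient ``D u``, shape ``(2, n_x, n_y)``."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("expected a 2D image")
    out = np.zeros((2,) + u.shape)
    out[0, 1:, :] = u[1:, :] - u[:-1, :]
    out[1, :, 1:] = u[:, 1:] - u[:, :-1]
    return out


def grad_adjoint(f: np.ndarray) -> np.ndarray:
    """Exact adjoint ``D^T f`` of :func:`grad` (transpose of the stencil)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or f.shape[0] != 2:
        raise ValueError("expected a gradient field of shape (2, n_x, n_y)")
    out = np.zeros(f.shape[1:])
    out[1:, :] += f[0, 1:, :]
    out[:-1, :] -= f[0, 1:, :]
    out[:, 1:] += f[1, :, 1:]
    out[:, :-1] -= f[1, :, 1:]
    return out


def grad_magnitude(f: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean magnitude of a gradient field."""
    return np.sqrt(f[0] ** 2 + f[1] ** 2)


def tv_norm(u: np.ndarray) -> float:
    """Isotropic total variation: sum over pixels of |(D u)_i|_2."""
    return float(grad_magnitude(grad(u)).sum())


def shrink1d(a: np.ndarray, lam: float) -> np.ndarray:
    """Soft thresholding, the prox of ``lam * |x|_1``."""
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    a = np.asarray(a, dtype=float)
    return np.maximum(np.abs(a) - lam, 0.0) * np.sign(a)


def shrink2d(f: np.ndarray, lam: float) -> np.ndarray:
    """Grouped (2D-vector) soft thresholding, the prox of ``lam * |x|_{2,1}``.

    Pixels with zero magnitude map to zero (the unique minimizer there).
    """
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    f = np.asarray(f, dtype=float)
    mag = grad_magnitude(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > 0, np.maximum(mag - lam, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
    return f * scale[None]


def project_l2_ball(a: np.ndarray, r: float) -> np.ndarray:
    """Euclidean projection of ``a`` onto the l2 ball of radius ``r``.

    Uses the Frobenius norm of the whole array; ``r = 0`` returns zeros
    (the 0/0 quotient is defined as 0).
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    a = np.asarray(a, dtype=float)
    norm = float(np.linalg.norm(a))
    if norm <= r:
        return a.copy()
    if r == 0:
        return np.zeros_like(a)
    return a * (r / norm)


def project_l1_ball(a: np.ndarray, r: float) -> np.ndarray:
    """Projection of a nonnegative vector onto ``{x >= 0 : |x|_1 <= r}``.

    Inside the ball the input is returned unchanged; outside, the result is
    the simplex projection ``max(a - theta, 0)`` with the water-filling
    level ``theta`` found by the O(n log n) sort-and-cumulative-sum rule.
    The only consumer projects gradient-magnitude images, which are
    nonnegative by construction; the signed general case is out of scope.
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("input must be nonnegative")
    shape = a.shape
    a = a.ravel()
    if a.sum() <= r:
        return a.reshape(shape).copy()
    if r == 0:
        return np.zeros(shape)
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    k = np.arange(1, a.size + 1)
    rho = np.nonzero(u - (css - r) / k > 0)[0][-1]
    theta = (css[rho] - r) / (rho + 1)
    return np.maximum(a - theta, 0.0).reshape(shape)


class GradientOperator(LinearMap):
    """The gradient transform ``D`` as a LinearMap (for spectral estimates)."""

    def __init__(self, shape: tuple[int, int]):
        self.in_shape = tuple(shape)
        self.out_shape = (2,) + self.in_shape

    def apply(self, u: np.ndarray) -> np.ndarray:
        return grad(u)

    def apply_adjoint(self, f: np.ndarray) -> np.ndarray:
        return grad_adjoint(f)
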