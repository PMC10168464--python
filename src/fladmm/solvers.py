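"""Fully linearized ADMM solvers for three total-variation CT models.

All three models reconstruct an image ``u`` from sinogram data ``g = A u``:

* ucTV   — unconstrained:  min 1/2 |Au - g|^2 + alpha * TV(u)
* DDcTV  — data-divergence-constrained:  min TV(u)  s.t. |Au - g|_2 <= eps
* TVcDM  — TV-constrained:  min 1/2 |Au - g|^2  s.t. TV(u) <= t

Each is split with auxiliary variables (``y = Du`` and, for DDcTV,
``z = Au - g``) and solved by ADMM in which *every* quadratic term of the
hard image sub-problem is linearized at the current iterate.  The image
update then collapses to a gradient step with the fixed step ``1/(s1+s2)``,
where the linearization constants ``s1, s2`` must dominate the spectral
norms of the corresponding quadratics (``s >= beta * lambda_max(B^T B)``).
No line search and no structural assumptions on ``A`` or ``D`` are needed —
only matrix-vector products, shrinkage, and ball projections.

The plain scheme performs one gradient step per outer iteration
("A" variant); repeating only that image step ``n_inner`` times per outer
iteration, with the splits and multipliers frozen, accelerates convergence
substantially ("B" variant; ``n_inner = 1`` reproduces "A" bit-for-bit).

A Chambolle–Pock primal–dual baseline for the DDcTV model is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projector import LinearMap, spectral_norm_sq
from .prox import (
    GradientOperator,
    grad,
    grad_adjoint,
    grad_magnitude,
    project_l1_ball,
    project_l2_ball,
    shrink2d,
    tv_norm,
)

__all__ = [
    "MODELS",
    "StepSizes",
    "SolverConfig",
    "SolverState",
    "CPConfig",
    "ConvergenceRecord",
    "DivergenceError",
    "step_size_policy",
    "solve",
    "solve_uctv",
    "solve_ddctv",
    "solve_tvcdm",
    "cp_ddctv",
]

MODELS = ("uctv", "ddctv", "tvcdm")


class DivergenceError(RuntimeError):
    """Raised when iterates blow up or turn non-finite."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"solver diverged at outer iteration {iteration}")


@dataclass(frozen=True)
class StepSizes:
    """Linearization constants; ``1/(s1 + s2)`` is the image-update step."""

    s1: float
    s2: float

    @property
    def step(self) -> float:
        return 1.0 / (self.s1 + self.s2)


@dataclass
class SolverConfig:
    """Parameters of one FL-ADMM reconstruction.

    ``beta`` is the augmented-Lagrangian penalty (for DDcTV, ``beta1`` /
    ``beta2`` for the TV and data splits default to ``beta``).  ``alpha``
    is the ucTV regularization weight, ``epsilon`` the DDcTV data-ball
    radius (0 = exact data equality), ``t`` the TVcDM TV bound.
    ``n_inner = 1`` is the plain algorithm.  ``early_stop_tol`` (off by
    default) stops once the RMSE against a supplied truth image drops below
    it, else once the relative image change does.
    """

    model: str
    n_outer: int
    n_inner: int = 1
    beta: float = 1.0
    beta1: float | None = None
    beta2: float | None = None
    alpha: float | None = None
    epsilon: float | None = None
    t: float | None = None
    safety_factor: float = 1.05
    seed: int = 0
    early_stop_tol: float | None = None
    log_every: int = 1

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("n_outer and n_inner must be >= 1")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.model == "ddctv":
            if self.beta1 is None:
                self.beta1 = self.beta
            if self.beta2 is None:
                self.beta2 = self.beta
            if not (self.beta1 > 0 and self.beta2 > 0):
                raise ValueError("beta1 and beta2 must be positive")
            if self.epsilon is None or self.epsilon < 0:
                raise ValueError("ddctv requires epsilon >= 0")
        elif self.model == "uctv":
            if self.alpha is None or not self.alpha > 0:
                raise ValueError("uctv requires alpha > 0")
        elif self.model == "tvcdm":
            if self.t is None or self.t < 0:
                raise ValueError("tvcdm requires t >= 0")
        if not self.safety_factor > 0:
            raise ValueError("safety_factor must be positive")
        if self.log_every < 1:
            raise ValueError("log_every must be >= 1")


@dataclass
class CPConfig:
    """Chambolle–Pock baseline parameters for the DDcTV model.

    ``L`` overrides the power-method estimate of the stacked operator norm
    |(A; D)|_2; ``lam`` sets the primal/dual step ratio (sigma = lam/L,
    tau = 1/(lam*L)), ``theta`` the over-relaxation.
    """

    n_iter: int
    epsilon: float = 0.0
    L: float | None = None
    lam: float = 1.0
    theta: float = 1.0
    seed: int = 0
    log_every: int = 1

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.lam > 0:
            raise ValueError("lam must be positive")


@dataclass
class SolverState:
    """Iterates after one outer iteration (passed to solver callbacks).

    ``z`` and ``lam2`` are the data-space split and multiplier (DDcTV only,
    ``None`` elsewhere).
    """

    iteration: int
    u: np.ndarray
    y: np.ndarray
    lam: np.ndarray
    z: np.ndarray | None = None
    lam2: np.ndarray | None = None


class ConvergenceRecord:
    """Per-outer-iteration log of RMSE, data residual |Au-g|_2 and TV(u)."""

    def __init__(self) -> None:
        self.iters: list[int] = []
        self.rmse: list[float] = []
        self.data_err: list[float] = []
        self.tv: list[float] = []

    def append(self, iteration: int, rmse: float, data_err: float, tv: float) -> None:
        self.iters.append(iteration)
        self.rmse.append(rmse)
        self.data_err.append(data_err)
        self.tv.append(tv)

    def __len__(self) -> int:
        return len(self.iters)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iter": self.iters, "rmse": self.rmse, "data_err": self.data_err, "tv": self.tv}
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def first_iter_below(self, threshold: float) -> int | None:
        """First logged outer iteration with RMSE <= threshold (None if never)."""
        for it, r in zip(self.iters, self.rmse):
            if np.isfinite(r) and r <= threshold:
                return it
        return None


def _rmse(u: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((u - truth) ** 2)))


def step_size_policy(
    A: LinearMap,
    cfg: SolverConfig,
    power_max_iter: int = 1000,
    power_tol: float = 1e-6,
) -> StepSizes:
    """Linearization constants from power-method spectral norms.

    ucTV / TVcDM:  s1 >= lambda_max(A^T A),        s2 >= beta * lambda_max(D^T D)
    DDcTV:         s1 >= beta1 * lambda_max(D^T D), s2 >= beta2 * lambda_max(A^T A)

    Each bound is multiplied by ``cfg.safety_factor`` (power iteration
    approaches the true eigenvalue from below, so a margin keeps the step
    valid).  Deterministic given ``cfg.seed``.
    """
    norm_AtA, _ = spectral_norm_sq(A, max_iter=power_max_iter, tol=power_tol, seed=cfg.seed)
    D = GradientOperator(A.in_shape)
    norm_DtD, _ = spectral_norm_sq(D, max_iter=power_max_iter, tol=power_tol, seed=cfg.seed)
    sf = cfg.safety_factor
    if cfg.model == "ddctv":
        return StepSizes(s1=sf * cfg.beta1 * norm_DtD, s2=sf * cfg.beta2 * norm_AtA)
    return StepSizes(s1=sf * norm_AtA, s2=sf * cfg.beta * norm_DtD)


def _guard(u: np.ndarray, iteration: int, scale: float) -> None:
    if not np.all(np.isfinite(u)):
        raise DivergenceError(iteration, f"non-finite image at outer iteration {iteration}")
    if np.max(np.abs(u)) > 1e6 * scale:
        raise DivergenceError(iteration)


def _log(record, A, u, g, truth, iteration) -> float:
    r = _rmse(u, truth) if truth is not None else float("nan")
    record.append(iteration, r, float(np.linalg.norm(A.apply(u) - g)), tv_norm(u))
    return r


def solve_uctv(
    g: np.ndarray,
    A: LinearMap,
    cfg: SolverConfig,
    truth: np.ndarray | None = None,
    steps: StepSizes | None = None,
    callback=None,
) -> tuple[np.ndarray, ConvergenceRecord]:
    """FL-ADMM for the unconstrained TV model.

    Outer iteration: ``n_inner`` linearized gradient steps on the image
    (splits frozen), then 2D shrinkage of ``Du - lam/beta`` with threshold
    ``alpha/beta``, then the multiplier update ``lam -= beta*(Du - y)``.
    """
    if cfg.model != "uctv":
        raise ValueError("config model must be 'uctv'")
    g = np.asarray(g, dtype=float)
    if steps is None:
        steps = step_size_policy(A, cfg)
    beta, alpha = cfg.beta, cfg.alpha
    tau = steps.step
    u = np.zeros(A.in_shape)
    y = np.zeros((2,) + A.in_shape)
    lam = np.zeros_like(y)
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    record = ConvergenceRecord()
    u_prev = u
    for k in range(1, cfg.n_outer + 1):
        c = y + lam / beta
        for _ in range(cfg.n_inner):
            u = u - tau * (A.apply_adjoint(A.apply(u) - g) + beta * grad_adjoint(grad(u) - c))
        _guard(u, k, scale)
        Du = grad(u)
        y = shrink2d(Du - lam / beta, alpha / beta)
        lam = lam - beta * (Du - y)
        if callback is not None:
            callback(SolverState(k, u.copy(), y.copy(), lam.copy()))
        if k % cfg.log_every == 0 or k == cfg.n_outer:
            r = _log(record, A, u, g, truth, k)
            if _should_stop(cfg, r, u, u_prev, truth):
                break
        u_prev = u
    return u, record


def solve_ddctv(
    g: np.ndarray,
    A: LinearMap,
    cfg: SolverConfig,
    truth: np.ndarray | None = None,
    steps: StepSizes | None = None,
    callback=None,
) -> tuple[np.ndarray, ConvergenceRecord]:
    """FL-ADMM for the data-divergence-constrained TV model.

    Splits ``y = Du`` and ``z = Au - g``.  Outer iteration: ``n_inner``
    linearized image steps, 2D shrinkage with threshold ``1/beta1``,
    l2-ball projection of ``Au - g - lam2/beta2`` onto radius ``epsilon``
    (``epsilon = 0`` forces the data equality ``Au = g``), then both
    multiplier updates.
    """
    if cfg.model != "ddctv":
        raise ValueError("config model must be 'ddctv'")
    g = np.asarray(g, dtype=float)
    if steps is None:
        steps = step_size_policy(A, cfg)
    b1, b2, eps = cfg.beta1, cfg.beta2, cfg.epsilon
    tau = steps.step
    u = np.zeros(A.in_shape)
    y = np.zeros((2,) + A.in_shape)
    lam1 = np.zeros_like(y)
    z = np.zeros(A.out_shape)
    lam2 = np.zeros_like(z)
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    record = ConvergenceRecord()
    u_prev = u
    for k in range(1, cfg.n_outer + 1):
        c1 = y + lam1 / b1
        c2 = z + g + lam2 / b2
        for _ in range(cfg.n_inner):
            u = u - tau * (
                b1 * grad_adjoint(grad(u) - c1) + b2 * A.apply_adjoint(A.apply(u) - c2)
            )
        _guard(u, k, scale)
        Du = grad(u)
        Au = A.apply(u)
        y = shrink2d(Du - lam1 / b1, 1.0 / b1)
        z = project_l2_ball(Au - g - lam2 / b2, eps)
        lam1 = lam1 - b1 * (Du - y)
        lam2 = lam2 - b2 * (Au - z - g)
        if callback is not None:
            callback(SolverState(k, u.copy(), y.copy(), lam1.copy(), z=z.copy(), lam2=lam2.copy()))
        if k % cfg.log_every == 0 or k == cfg.n_outer:
            r = _log(record, A, u, g, truth, k)
            if _should_stop(cfg, r, u, u_prev, truth):
                break
        u_prev = u
    return u, record


def solve_tvcdm(
    g: np.ndarray,
    A: LinearMap,
    cfg: SolverConfig,
    truth: np.ndarray | None = None,
    steps: StepSizes | None = None,
    callback=None,
) -> tuple[np.ndarray, ConvergenceRecord]:
    """FL-ADMM for the TV-constrained data-divergence model.

    Outer iteration: ``n_inner`` linearized image steps (identical in form
    to ucTV), then the split update: project the per-pixel magnitudes of
    ``w = Du - lam/beta`` onto the l1 ball of radius ``t`` and rescale each
    pixel's 2-vector to the projected magnitude (zero-magnitude pixels stay
    zero), then ``lam -= beta*(Du - y)``.
    """
    if cfg.model != "tvcdm":
        raise ValueError("config model must be 'tvcdm'")
    g = np.asarray(g, dtype=float)
    if steps is None:
        steps = step_size_policy(A, cfg)
    beta, t = cfg.beta, cfg.t
    tau = steps.step
    u = np.zeros(A.in_shape)
    y = np.zeros((2,) + A.in_shape)
    lam = np.zeros_like(y)
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    record = ConvergenceRecord()
    u_prev = u
    for k in range(1, cfg.n_outer + 1):
        c = y + lam / beta
        for _ in range(cfg.n_inner):
            u = u - tau * (A.apply_adjoint(A.apply(u) - g) + beta * grad_adjoint(grad(u) - c))
        _guard(u, k, scale)
        Du = grad(u)
        w = Du - lam / beta
        mag = grad_magnitude(w)
        m = project_l1_ball(mag, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mag > 0, m / np.where(mag > 0, mag, 1.0), 0.0)
        y = w * ratio[None]
        lam = lam - beta * (Du - y)
        if callback is not None:
            callback(SolverState(k, u.copy(), y.copy(), lam.copy()))
        if k % cfg.log_every == 0 or k == cfg.n_outer:
            r = _log(record, A, u, g, truth, k)
            if _should_stop(cfg, r, u, u_prev, truth):
                break
        u_prev = u
    return u, record


def _should_stop(cfg, rmse_val, u, u_prev, truth) -> bool:
    if cfg.early_stop_tol is None:
        return False
    if truth is not None:
        return np.isfinite(rmse_val) and rmse_val <= cfg.early_stop_tol
    du = float(np.linalg.norm(u - u_prev)) / max(float(np.linalg.norm(u)), 1e-30)
    return du <= cfg.early_stop_tol


_SOLVERS = {"uctv": solve_uctv, "ddctv": solve_ddctv, "tvcdm": solve_tvcdm}


def solve(
    g: np.ndarray,
    A: LinearMap,
    cfg: SolverConfig,
    truth: np.ndarray | None = None,
    steps: StepSizes | None = None,
    callback=None,
) -> tuple[np.ndarray, ConvergenceRecord]:
    """Dispatch to the FL-ADMM instance selected by ``cfg.model``."""
    return _SOLVERS[cfg.model](g, A, cfg, truth=truth, steps=steps, callback=callback)


class _StackedOp(LinearMap):
    """K = (A; D), the combined operator of the primal-dual formulation."""

    def __init__(self, A: LinearMap):
        self.A = A
        self.D = GradientOperator(A.in_shape)
        self.in_shape = A.in_shape

    def apply(self, u):
        return np.concatenate([self.A.apply(u).ravel(), self.D.apply(u).ravel()])

    def apply_adjoint(self, v):
        m = int(np.prod(self.A.out_shape))
        s = v[:m].reshape(self.A.out_shape)
        f = v[m:].reshape(self.D.out_shape)
        return self.A.apply_adjoint(s) + self.D.apply_adjoint(f)


def cp_ddctv(
    g: np.ndarray,
    A: LinearMap,
    cp_cfg: CPConfig,
    truth: np.ndarray | None = None,
) -> tuple[np.ndarray, ConvergenceRecord]:
    """Chambolle–Pock primal–dual baseline for the DDcTV model.

    Standard first-order primal-dual iteration for
    min TV(u) s.t. |Au - g|_2 <= epsilon, with dual variables for the data
    term (conjugate of the shifted l2-ball indicator: a global l2 shrink of
    ``p + sigma*(A u_bar - g)`` by ``sigma*epsilon``) and for the TV term
    (per-pixel clamp of the gradient dual onto the unit disk).  Steps are
    sigma = lam/L, tau = 1/(lam*L) with ``L`` the power-method estimate of
    the stacked operator norm |(A; D)|_2 unless overridden.
    """
    g = np.asarray(g, dtype=float)
    L = cp_cfg.L
    if L is None:
        K = _StackedOp(A)
        norm_sq, _ = spectral_norm_sq(K, seed=cp_cfg.seed)
        L = float(np.sqrt(norm_sq))
    sigma = cp_cfg.lam / L
    tau = 1.0 / (cp_cfg.lam * L)
    eps = cp_cfg.epsilon

    u = np.zeros(A.in_shape)
    u_bar = u.copy()
    p = np.zeros(A.out_shape)
    q = np.zeros((2,) + A.in_shape)
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    record = ConvergenceRecord()
    for k in range(1, cp_cfg.n_iter + 1):
        v = p + sigma * (A.apply(u_bar) - g)
        nv = float(np.linalg.norm(v))
        p = v * (max(nv - sigma * eps, 0.0) / nv) if nv > 0 else np.zeros_like(v)
        w = q + sigma * grad(u_bar)
        mag = grad_magnitude(w)
        q = w / np.maximum(1.0, mag)[None]
        u_new = u - tau * (A.apply_adjoint(p) + grad_adjoint(q))
        u_bar = u_new + cp_cfg.theta * (u_new - u)
        u = u_new
        _guard(u, k, scale)
        if k % cp_cfg.log_every == 0 or k == cp_cfg.n_iter:
            _log(record, A, u, g, truth, k)
    return u, record
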