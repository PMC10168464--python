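"""FL-ADMM solver instances: fixed points, exact update identities,
oracle agreement, divergence guard, and the Chambolle-Pock baseline."""

import numpy as np
import pytest

from fladmm import (
    CPConfig,
    DivergenceError,
    GradientOperator,
    ImageGrid,
    MatrixOperator,
    PhantomSpec,
    RadonTransform,
    ScanGeometry,
    SolverConfig,
    StepSizes,
    cp_ddctv,
    grad,
    grad_adjoint,
    grad_magnitude,
    make_phantom,
    project_l1_ball,
    project_l2_ball,
    rmse,
    shrink2d,
    solve,
    solve_ddctv,
    solve_tvcdm,
    solve_uctv,
    spectral_norm_sq,
    step_size_policy,
    tv_norm,
)
from conftest import dense_gradient_matrix


def well_conditioned_operator(rng, n_side=4):
    """An invertible, well-conditioned system on an n_side x n_side image."""
    n = n_side * n_side
    M = np.eye(n) + 0.1 * rng.standard_normal((n, n))
    return MatrixOperator(M, in_shape=(n_side, n_side), out_shape=(n,)), M


class TestStepSizePolicy:
    def test_identity_operator(self):
        A = MatrixOperator(np.eye(9), in_shape=(3, 3), out_shape=(9,))
        cfg = SolverConfig(model="uctv", n_outer=1, alpha=1.0, beta=1.0, safety_factor=1.0)
        steps = step_size_policy(A, cfg, power_tol=1e-13)
        assert np.isclose(steps.s1, 1.0, rtol=1e-6)

    def test_gradient_term_matches_dense_eigendecomposition(self):
        A = MatrixOperator(np.eye(16), in_shape=(4, 4), out_shape=(16,))
        D = dense_gradient_matrix(4, 4)
        lam_dense = np.linalg.eigvalsh(D.T @ D).max()
        cfg = SolverConfig(model="uctv", n_outer=1, alpha=1.0, beta=2.0, safety_factor=1.0)
        steps = step_size_policy(A, cfg, power_max_iter=100000, power_tol=1e-14)
        assert np.isclose(steps.s2, 2.0 * lam_dense, rtol=1e-7)

    def test_linear_in_beta(self):
        A = MatrixOperator(np.eye(16), in_shape=(4, 4), out_shape=(16,))
        s_b1 = step_size_policy(A, SolverConfig(model="uctv", n_outer=1, alpha=1.0, beta=1.0))
        s_b2 = step_size_policy(A, SolverConfig(model="uctv", n_outer=1, alpha=1.0, beta=2.0))
        assert np.isclose(s_b2.s2, 2.0 * s_b1.s2)

    def test_ddctv_symbol_assignment(self):
        """For DDcTV, s1 bounds the TV quadratic and s2 the data quadratic."""
        A = MatrixOperator(3.0 * np.eye(16), in_shape=(4, 4), out_shape=(16,))
        cfg = SolverConfig(
            model="ddctv", n_outer=1, epsilon=0.0, beta1=2.0, beta2=5.0, safety_factor=1.0
        )
        steps = step_size_policy(A, cfg, power_max_iter=100000, power_tol=1e-14)
        lam_D = np.linalg.eigvalsh(
            dense_gradient_matrix(4, 4).T @ dense_gradient_matrix(4, 4)
        ).max()
        assert np.isclose(steps.s1, 2.0 * lam_D, rtol=1e-7)
        assert np.isclose(steps.s2, 5.0 * 9.0, rtol=1e-7)


class TestFixedPoints:
    @pytest.mark.parametrize(
        "cfg",
        [
            SolverConfig(model="uctv", n_outer=20, n_inner=3, alpha=0.5),
            SolverConfig(model="ddctv", n_outer=20, n_inner=3, epsilon=0.0),
            SolverConfig(model="tvcdm", n_outer=20, n_inner=3, t=1.0),
        ],
        ids=["uctv", "ddctv", "tvcdm"],
    )
    def test_zero_data_keeps_zero_image(self, cfg, tiny_system):
        _, geom, A = tiny_system
        u, record = solve(np.zeros(geom.shape), A, cfg)
        assert np.all(u == 0)
        assert record.tv[-1] == 0

    def test_cp_zero_data(self, tiny_system):
        _, geom, A = tiny_system
        u, _ = cp_ddctv(np.zeros(geom.shape), A, CPConfig(n_iter=30, epsilon=0.0))
        assert np.all(u == 0)


class TestMultiplierConsistency:
    def test_ddctv_multiplier_updates_exact(self, tiny_system, rng):
        """lam - lam_prev == -beta*(residual) holds bitwise every outer iteration."""
        grid, geom, A = tiny_system
        truth = rng.uniform(size=grid.shape)
        g = A.apply(truth)
        states = []
        cfg = SolverConfig(model="ddctv", n_outer=15, n_inner=4, beta1=2.0, beta2=3.0, epsilon=0.1)
        solve_ddctv(g, A, cfg, callback=states.append)
        assert len(states) == 15
        for prev, cur in zip(states, states[1:]):
            du = grad(cur.u)
            au = A.apply(cur.u)
            # recompute the update expressions: must match bit-for-bit
            assert np.array_equal(cur.lam, prev.lam - 2.0 * (du - cur.y))
            assert np.array_equal(cur.lam2, prev.lam2 - 3.0 * (au - cur.z - g))
            assert np.array_equal(cur.y, shrink2d(du - prev.lam / 2.0, 1.0 / 2.0))
            assert np.array_equal(cur.z, project_l2_ball(au - g - prev.lam2 / 3.0, 0.1))

    def test_uctv_multiplier_updates_exact(self, tiny_system, rng):
        grid, geom, A = tiny_system
        g = A.apply(rng.uniform(size=grid.shape))
        states = []
        cfg = SolverConfig(model="uctv", n_outer=10, n_inner=2, beta=1.5, alpha=0.7)
        solve_uctv(g, A, cfg, callback=states.append)
        for prev, cur in zip(states, states[1:]):
            assert np.array_equal(cur.lam, prev.lam - 1.5 * (grad(cur.u) - cur.y))


def _plain_a_variant_ddctv(g, A, cfg, steps, n_outer):
    """Independent transcription of the plain (no-inner-loop) DDcTV scheme."""
    b1, b2, eps = cfg.beta1, cfg.beta2, cfg.epsilon
    tau = steps.step
    u = np.zeros(A.in_shape)
    y = np.zeros((2,) + A.in_shape)
    lam1 = np.zeros_like(y)
    z = np.zeros(A.out_shape)
    lam2 = np.zeros_like(z)
    for _ in range(n_outer):
        c1 = y + lam1 / b1
        c2 = z + g + lam2 / b2
        u = u - tau * (b1 * grad_adjoint(grad(u) - c1) + b2 * A.apply_adjoint(A.apply(u) - c2))
        Du = grad(u)
        Au = A.apply(u)
        y = shrink2d(Du - lam1 / b1, 1.0 / b1)
        z = project_l2_ball(Au - g - lam2 / b2, eps)
        lam1 = lam1 - b1 * (Du - y)
        lam2 = lam2 - b2 * (Au - z - g)
    return u


def _plain_a_variant_tv_split(g, A, cfg, steps, n_outer, model):
    """Independent transcription of the plain ucTV / TVcDM schemes."""
    beta = cfg.beta
    tau = steps.step
    u = np.zeros(A.in_shape)
    y = np.zeros((2,) + A.in_shape)
    lam = np.zeros_like(y)
    for _ in range(n_outer):
        c = y + lam / beta
        u = u - tau * (A.apply_adjoint(A.apply(u) - g) + beta * grad_adjoint(grad(u) - c))
        Du = grad(u)
        if model == "uctv":
            y = shrink2d(Du - lam / beta, cfg.alpha / beta)
        else:
            w = Du - lam / beta
            mag = grad_magnitude(w)
            m = project_l1_ball(mag, cfg.t)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(mag > 0, m / np.where(mag > 0, mag, 1.0), 0.0)
            y = w * ratio[None]
        lam = lam - beta * (Du - y)
    return u


class TestInnerLoopEquivalence:
    """n_inner = 1 must reproduce the plain scheme bit-for-bit."""

    def test_ddctv(self, tiny_system, rng):
        grid, geom, A = tiny_system
        g = A.apply(rng.uniform(size=grid.shape))
        cfg = SolverConfig(model="ddctv", n_outer=25, n_inner=1, beta1=1.5, beta2=0.8, epsilon=0.05)
        steps = step_size_policy(A, cfg)
        u_b, _ = solve_ddctv(g, A, cfg, steps=steps)
        u_a = _plain_a_variant_ddctv(g, A, cfg, steps, 25)
        assert np.array_equal(u_b, u_a)

    @pytest.mark.parametrize("model", ["uctv", "tvcdm"])
    def test_tv_split_models(self, model, tiny_system, rng):
        grid, geom, A = tiny_system
        g = A.apply(rng.uniform(size=grid.shape))
        kwargs = {"alpha": 0.3} if model == "uctv" else {"t": 5.0}
        cfg = SolverConfig(model=model, n_outer=25, n_inner=1, beta=1.2, **kwargs)
        steps = step_size_policy(A, cfg)
        u_b, _ = solve(g, A, cfg, steps=steps)
        u_a = _plain_a_variant_tv_split(g, A, cfg, steps, 25, model)
        assert np.array_equal(u_b, u_a)


class TestObjectiveOracles:
    def test_uctv_matches_smoothed_lbfgs_oracle(self, rng):
        """Final ucTV objective within 1e-4 of a generic smooth-TV minimizer."""
        from scipy.optimize import minimize

        A, M = well_conditioned_operator(rng)
        truth = rng.uniform(size=(4, 4))
        g = A.apply(truth) + 0.05 * rng.standard_normal(16)
        alpha = 0.3

        def objective(u):
            return 0.5 * np.sum((A.apply(u) - g) ** 2) + alpha * tv_norm(u)

        cfg = SolverConfig(model="uctv", n_outer=4000, n_inner=5, alpha=alpha, beta=1.0)
        u_admm, _ = solve_uctv(g, A, cfg)

        delta = 1e-6

        def smooth_obj_grad(x):
            u = x.reshape(4, 4)
            f = grad(u)
            mag = np.sqrt(f[0] ** 2 + f[1] ** 2 + delta**2)
            val = 0.5 * np.sum((M @ x - g) ** 2) + alpha * np.sum(mag)
            jac = M.T @ (M @ x - g) + alpha * grad_adjoint(f / mag[None]).ravel()
            return val, jac

        res = minimize(smooth_obj_grad, np.zeros(16), jac=True, method="L-BFGS-B",
                       options={"maxiter": 100000, "ftol": 1e-18, "gtol": 1e-14})
        f_oracle = objective(res.x.reshape(4, 4))
        f_admm = objective(u_admm)
        assert abs(f_admm - f_oracle) <= 1e-4

    def test_tvcdm_inactive_constraint_gives_least_squares(self, rng):
        """With t above TV of the exact solution, TVcDM solves Au = g."""
        A, M = well_conditioned_operator(rng)
        truth = rng.uniform(size=(4, 4))
        g = A.apply(truth)
        u_ls = np.linalg.solve(M, g).reshape(4, 4)  # == truth
        t = 1.1 * tv_norm(u_ls)
        cfg = SolverConfig(model="tvcdm", n_outer=3000, n_inner=5, t=t, beta=1.0)
        u, _ = solve_tvcdm(g, A, cfg)
        assert rmse(u, u_ls) <= 1e-4
        assert tv_norm(u) <= t + 1e-3

    def test_tvcdm_zero_bound_forces_zero_split(self, tiny_system, rng):
        grid, geom, A = tiny_system
        g = A.apply(rng.uniform(size=grid.shape))
        states = []
        cfg = SolverConfig(model="tvcdm", n_outer=30, n_inner=2, t=0.0)
        u, _ = solve_tvcdm(g, A, cfg, callback=states.append)
        for s in states:
            assert np.all(s.y == 0)

    def test_ddctv_and_cp_agree_with_direct_solve_oracle(self, rng):
        """eps = 0 with invertible A: the unique feasible point is A^{-1} g,
        so both solvers' objectives must match TV(A^{-1} g) to 1e-4."""
        A, M = well_conditioned_operator(rng)
        truth = rng.uniform(size=(4, 4))
        g = A.apply(truth)
        u_star = np.linalg.solve(M, g).reshape(4, 4)
        cfg = SolverConfig(model="ddctv", n_outer=3000, n_inner=5, beta=1.0, epsilon=0.0)
        u_fl, _ = solve_ddctv(g, A, cfg)
        u_cp, _ = cp_ddctv(g, A, CPConfig(n_iter=20000, epsilon=0.0))
        for u in (u_fl, u_cp):
            assert np.linalg.norm(A.apply(u) - g) <= 1e-3
            assert abs(tv_norm(u) - tv_norm(u_star)) <= 1e-4


class TestConvergenceBehaviour:
    def test_mini_inverse_crime(self):
        """16x16 disk, exact-data DDcTV: recover the phantom to RMSE 1e-3."""
        n = 16
        grid, geom = ImageGrid(n, n), ScanGeometry(n, 24)
        truth = make_phantom(PhantomSpec("disk", (n, n)))
        A = RadonTransform(grid, geom)
        g = A.apply(truth)
        cfg = SolverConfig(
            model="ddctv", n_outer=2000, n_inner=10, beta=1.0, epsilon=0.0,
            early_stop_tol=1e-3, log_every=10,
        )
        u, record = solve_ddctv(g, A, cfg, truth=truth)
        assert record.rmse[-1] <= 1e-3

    def test_rmse_descent_trend(self):
        """Exact-data DDcTV RMSE at iteration 10k is below that at k."""
        n = 32
        grid, geom = ImageGrid(n, n), ScanGeometry(n, 32)
        truth = make_phantom(PhantomSpec("shepp_logan", (n, n)))
        A = RadonTransform(grid, geom)
        g = A.apply(truth)
        cfg = SolverConfig(model="ddctv", n_outer=1000, n_inner=10, beta=1.0, epsilon=0.0)
        _, record = solve_ddctv(g, A, cfg, truth=truth)
        r = dict(zip(record.iters, record.rmse))
        for k in (10, 50, 100):
            assert r[10 * k] < r[k]

    def test_divergence_guard_fires(self, tiny_system, rng):
        """Steps far below the spectral bound must abort, not emit NaNs."""
        grid, geom, A = tiny_system
        g = A.apply(rng.uniform(size=grid.shape))
        cfg = SolverConfig(model="ddctv", n_outer=500, n_inner=5, beta=1.0, epsilon=0.0)
        bad = step_size_policy(A, cfg)
        bad = StepSizes(s1=0.02 * bad.s1, s2=0.02 * bad.s2)
        with pytest.raises(DivergenceError) as exc_info:
            solve_ddctv(g, A, cfg, steps=bad)
        assert exc_info.value.iteration >= 1

    def test_early_stop_on_truth_rmse(self):
        n = 16
        grid, geom = ImageGrid(n, n), ScanGeometry(n, 16)
        truth = make_phantom(PhantomSpec("disk", (n, n)))
        A = RadonTransform(grid, geom)
        g = A.apply(truth)
        cfg = SolverConfig(model="ddctv", n_outer=5000, n_inner=10, beta=1.0,
                           epsilon=0.0, early_stop_tol=1e-2)
        _, record = solve_ddctv(g, A, cfg, truth=truth)
        assert record.iters[-1] < 5000
        assert record.rmse[-1] <= 1e-2


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"model": "nope", "n_outer": 1},
            {"model": "uctv", "n_outer": 1},  # missing alpha
            {"model": "ddctv", "n_outer": 1},  # missing epsilon
            {"model": "tvcdm", "n_outer": 1, "t": -1.0},
            {"model": "ddctv", "n_outer": 1, "epsilon": 0.0, "beta1": -1.0},
            {"model": "uctv", "n_outer": 0, "alpha": 1.0},
            {"model": "uctv", "n_outer": 1, "alpha": 1.0, "safety_factor": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)

    def test_model_mismatch_rejected(self, tiny_system):
        _, geom, A = tiny_system
        cfg = SolverConfig(model="uctv", n_outer=1, alpha=1.0)
        with pytest.raises(ValueError):
            solve_ddctv(np.zeros(geom.shape), A, cfg)
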