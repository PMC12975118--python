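import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from npmix.likelihood import LikelihoodMatrix
from npmix.ssn import (
    NewtonSystem,
    SubproblemContext,
    active_set,
    grad_phi,
    line_search,
    moreau_envelope_h,
    newton_direction,
    phi,
    prox_h,
    prox_h_jacobian_diag,
    ssn_solve,
)
from npmix.types import SolverConfig

from conftest import random_likelihood


def make_ctx(rng, n=6, m=4, sigma=2.0):
    Lmat = random_likelihood(rng, n, m)
    xk = rng.random(m)
    yk = rng.random(n) + 0.2
    return SubproblemContext(Lmat=Lmat, xk=xk, yk=yk, sigma=sigma)


class TestProx:
    def test_scalar_stationarity_at_zero(self):
        p = prox_h(np.array([0.0]), sigma=1.0, n=1)
        assert p[0] == pytest.approx(1.0)

    def test_n4_at_zero(self):
        p = prox_h(np.array([0.0]), sigma=1.0, n=4)
        assert p[0] == pytest.approx(0.5)

    def test_quadratic_formula_vs_scalar_minimization(self):
        p = prox_h(np.array([10.0]), sigma=1.0, n=1)
        assert p[0] == pytest.approx((10 + np.sqrt(104)) / 2)
        res = minimize_scalar(
            lambda t: -np.log(t) + 0.5 * (t - 10.0) ** 2,
            bounds=(1e-6, 20.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert p[0] == pytest.approx(res.x, rel=1e-6)

    def test_stationarity_identity_random(self, rng):
        # sigma (p - w) = 1/(n p), including extreme w where the naive
        # formula would lose every digit
        w = np.concatenate(
            [rng.standard_normal(50) * 5, [1e8, -1e8, 1e12, -1e12]]
        )
        for sigma, n in [(0.5, 3), (2.0, 100), (1e6, 1000)]:
            p = prox_h(w, sigma, n)
            assert np.all(p > 0)
            lhs = sigma * (p - w)
            rhs = 1.0 / (n * p)
            assert np.allclose(lhs, rhs, rtol=1e-10)


class TestProxJacobian:
    def test_half_at_zero(self):
        j = prox_h_jacobian_diag(np.zeros(3), sigma=1.0, n=4)
        assert np.allclose(j, 0.5)

    def test_monotone_limits(self):
        j = prox_h_jacobian_diag(np.array([-1e10, 1e10]), 1.0, 1)
        assert j[0] == pytest.approx(0.0, abs=1e-12)
        assert j[1] == pytest.approx(1.0, abs=1e-12)
        assert np.all((j >= 0) & (j <= 1))

    def test_matches_finite_differences(self, rng):
        w = rng.standard_normal(20)
        sigma, n = 1.7, 9
        h = 1e-6
        fd = (prox_h(w + h, sigma, n) - prox_h(w - h, sigma, n)) / (2 * h)
        assert np.allclose(prox_h_jacobian_diag(w, sigma, n), fd, atol=1e-6)


class TestMoreauEnvelope:
    def test_hand_value(self):
        assert moreau_envelope_h(np.array([0.0]), 1.0, 1) == pytest.approx(0.5)

    def test_minimality(self, rng):
        w = rng.standard_normal(5)
        sigma, n = 1.3, 5
        env = moreau_envelope_h(w, sigma, n)
        for _ in range(20):
            z = rng.random(5) * 3 + 0.01
            val = -np.log(z).sum() / n + 0.5 * sigma * ((z - w) ** 2).sum()
            assert env <= val + 1e-12

    def test_gradient_identity(self, rng):
        # d/dw M(w) = sigma (w - prox(w)), checked by central differences
        w = rng.standard_normal(4)
        sigma, n = 2.1, 4
        g = sigma * (w - prox_h(w, sigma, n))
        h = 1e-6
        for i in range(4):
            e = np.zeros(4)
            e[i] = h
            fd = (
                moreau_envelope_h(w + e, sigma, n)
                - moreau_envelope_h(w - e, sigma, n)
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, abs=1e-6)


class TestPhiAndGradient:
    def test_zero_point_value(self, rng):
        Lmat = random_likelihood(rng, 3, 2)
        ctx = SubproblemContext(
            Lmat=Lmat, xk=np.zeros(2), yk=np.zeros(3), sigma=1.5
        )
        v = np.zeros(3)
        # max(-1, 0) = 0 so only the envelope term remains
        assert phi(v, ctx) == pytest.approx(
            moreau_envelope_h(np.zeros(3), 1.5, 3)
        )

    def test_scalar_hand_gradient(self):
        Lmat = LikelihoodMatrix(L=np.array([[1.0]]), row_log_scale=np.zeros(1))
        ctx = SubproblemContext(
            Lmat=Lmat, xk=np.zeros(1), yk=np.zeros(1), sigma=1.0
        )
        g = grad_phi(np.zeros(1), ctx)
        assert g[0] == pytest.approx(-1.0)

    def test_convexity_midpoint(self, rng):
        ctx = make_ctx(rng)
        for _ in range(10):
            v1 = rng.standard_normal(6)
            v2 = rng.standard_normal(6)
            mid = phi(0.5 * (v1 + v2), ctx)
            assert mid <= 0.5 * (phi(v1, ctx) + phi(v2, ctx)) + 1e-10

    def test_gradient_descent_direction(self, rng):
        ctx = make_ctx(rng)
        v = rng.standard_normal(6)
        g = grad_phi(v, ctx)
        assert phi(v - 1e-6 * g, ctx) <= phi(v, ctx)

    def test_gradient_vs_finite_differences(self, rng):
        # 50 random points across random contexts
        for trial in range(50):
            n = int(rng.integers(2, 10))
            m = int(rng.integers(2, 10))
            sigma = float(rng.random() * 5 + 0.1)
            ctx = make_ctx(rng, n=n, m=m, sigma=sigma)
            v = rng.standard_normal(n)
            g = grad_phi(v, ctx)
            h = 1e-6
            fd = np.empty(n)
            for i in range(n):
                e = np.zeros(n)
                e[i] = h
                fd[i] = (phi(v + e, ctx) - phi(v - e, ctx)) / (2 * h)
            assert np.linalg.norm(g - fd) <= 1e-5 * (1 + np.linalg.norm(g))


class TestActiveSet:
    def _ctx_with_z(self, z, sigma=1.0):
        # L = I, v = n*(z + 1) - with xk = 0 gives the requested z
        n = m = len(z)
        Lmat = LikelihoodMatrix(L=np.eye(n), row_log_scale=np.zeros(n))
        ctx = SubproblemContext(
            Lmat=Lmat, xk=np.zeros(m), yk=np.zeros(n), sigma=sigma
        )
        v = n * (np.asarray(z, float) + 1.0)
        return ctx, v

    def test_tie_at_zero_excluded(self):
        ctx, v = self._ctx_with_z([0.2, 0.0, -0.1])
        sys = active_set(v, ctx)
        assert sys.s == 1
        assert list(sys.J) == [True, False, False]

    def test_empty_active_set(self, rng):
        ctx, v = self._ctx_with_z([-0.5, -1.0, -2.0])
        sys = active_set(v, ctx)
        assert sys.s == 0
        rhs = rng.standard_normal(3)
        d, resid = newton_direction(sys, ctx, rhs)
        assert np.allclose(d, rhs / sys.D)
        assert resid == 0.0

    def test_d_strictly_positive(self, rng):
        ctx = make_ctx(rng)
        sys = active_set(rng.standard_normal(6) * 100, ctx)
        assert np.all(sys.D > 0)

    def test_s_bounded_by_positive_x_when_dual_feasible(self, rng):
        # dual-feasible v: (1/n) L'v <= 1; then s <= #{j: x_j > 0}
        Lmat = random_likelihood(rng, 5, 4)
        xk = np.array([0.4, 0.0, 0.6, 0.0])
        ctx = SubproblemContext(Lmat=Lmat, xk=xk, yk=rng.random(5), sigma=2.0)
        for _ in range(20):
            v = rng.standard_normal(5)
            if np.any(Lmat.rmatvec(v) / 5 > 1):
                continue
            sys = active_set(v, ctx)
            assert sys.s <= int((xk > 0).sum())


class TestNewtonDirection:
    def test_two_by_two_hand_example(self):
        # system [[2,1],[1,2]] d = (1,1) -> d = (1/3, 1/3)
        Lmat = LikelihoodMatrix(L=np.ones((2, 1)), row_log_scale=np.zeros(2))
        ctx = SubproblemContext(
            Lmat=Lmat, xk=np.zeros(1), yk=np.zeros(2), sigma=4.0
        )  # sqrt(sigma)/n = 1 -> Ltilde = (1,1)'
        sys = NewtonSystem(
            J=np.array([True]), s=1, D=np.ones(2), solve_mode="smw"
        )
        d, resid = newton_direction(sys, ctx, np.ones(2))
        assert np.allclose(d, [1.0 / 3.0, 1.0 / 3.0])
        assert resid <= 1e-12

    @pytest.mark.parametrize("trial", range(5))
    def test_smw_vs_dense_agreement(self, rng, trial):
        n = int(rng.integers(10, 50))
        m = int(rng.integers(11, 30))
        ctx = make_ctx(rng, n=n, m=m, sigma=float(rng.random() * 3 + 0.5))
        s = int(rng.integers(1, 11))
        J = np.zeros(m, dtype=bool)
        J[rng.choice(m, size=s, replace=False)] = True
        D = rng.random(n) + 0.1
        rhs = rng.standard_normal(n)
        sys_smw = NewtonSystem(J=J, s=s, D=D, solve_mode="smw")
        sys_dense = NewtonSystem(J=J, s=s, D=D, solve_mode="dense_n")
        d1, r1 = newton_direction(sys_smw, ctx, rhs)
        d2, r2 = newton_direction(sys_dense, ctx, rhs)
        assert np.linalg.norm(d1 - d2) <= 1e-8 * (1 + np.linalg.norm(d1))
        assert max(r1, r2) <= 1e-8 * (1 + np.linalg.norm(rhs))


class TestLineSearch:
    def test_full_step_on_newton_direction(self, rng):
        ctx = make_ctx(rng, n=4, m=3)
        v = rng.standard_normal(4) * 0.1
        g = grad_phi(v, ctx)
        sys = active_set(v, ctx)
        d, _ = newton_direction(sys, ctx, -g)
        alpha = line_search(v, d, ctx, mu=1e-4, beta=0.5)
        # near-quadratic region: the (possibly damped) Newton step passes
        assert alpha >= 0.25

    def test_steepest_descent_near_optimum(self, rng):
        ctx = make_ctx(rng, n=4, m=3)
        cfg = SolverConfig()
        _, v, _, _ = ssn_solve(ctx, 1e-5, cfg, np.zeros(4))
        d = -grad_phi(v, ctx)
        alpha = line_search(v, d, ctx, mu=1e-4, beta=0.5)
        assert alpha == 1.0

    def test_matches_exhaustive_scan(self, rng):
        ctx = make_ctx(rng, n=5, m=4, sigma=30.0)
        v = rng.standard_normal(5) * 3
        d = -grad_phi(v, ctx)
        mu, beta = 1e-4, 0.5
        alpha = line_search(v, d, ctx, mu=mu, beta=beta)
        f0 = phi(v, ctx)
        slope = float(grad_phi(v, ctx) @ d)
        # oracle: scan the geometric grid for the first acceptable step
        a = 1.0
        for _ in range(50):
            if phi(v + a * d, ctx) <= f0 + mu * a * slope:
                break
            a *= beta
        assert alpha == pytest.approx(a)


class TestSSNSolve:
    def test_toy_convergence_vs_generic_minimizer(self, identity_likelihood):
        n = m = 2
        x0 = np.full(m, 0.5)
        y0 = identity_likelihood.L @ x0
        ctx = SubproblemContext(
            Lmat=identity_likelihood, xk=x0, yk=y0 / n, sigma=1.0
        )
        cfg = SolverConfig()
        u, v, iters, diag = ssn_solve(ctx, 1e-10, cfg, np.zeros(n))
        assert iters <= 10
        assert np.linalg.norm(grad_phi(v, ctx)) <= 1e-10
        res = minimize(
            lambda t: phi(t, ctx), np.zeros(n), method="BFGS",
            options={"gtol": 1e-12},
        )
        assert phi(v, ctx) == pytest.approx(res.fun, abs=1e-8)

    def test_immediate_return_at_optimum(self, rng):
        ctx = make_ctx(rng)
        cfg = SolverConfig()
        _, v_star, _, _ = ssn_solve(ctx, 1e-11, cfg, np.zeros(6))
        _, _, iters, _ = ssn_solve(ctx, 1e-9, cfg, v_star)
        assert iters == 0

    def test_u_positive_and_stationary(self, rng):
        ctx = make_ctx(rng)
        cfg = SolverConfig()
        u, v, _, _ = ssn_solve(ctx, 1e-9, cfg, np.zeros(6))
        assert np.all(u > 0)
        w = v - ctx.yk / ctx.sigma
        assert np.allclose(ctx.sigma * (u - w), 1.0 / (ctx.n * u), rtol=1e-10)

    def test_monotone_descent_and_local_rate(self, rng):
        ctx = make_ctx(rng, n=8, m=6, sigma=5.0)
        cfg = SolverConfig()
        u, v, iters, diag = ssn_solve(ctx, 1e-11, cfg, rng.standard_normal(8))
        gnorms = diag.grad_norms
        assert gnorms[-1] <= 1e-11 or not diag.converged
        if len(gnorms) >= 3:
            # superlinear tail: the final contraction is at least 2x
            assert gnorms[-1] <= 0.5 * gnorms[-2]

    def test_hessian_directional_derivative(self, rng):
        # (grad(v + t d) - grad(v)) / t ~ H d away from kinks
        from npmix.ssn import _z_of, _hessian_matvec, active_set

        for _ in range(20):
            ctx = make_ctx(rng, n=7, m=5, sigma=2.0)
            v = rng.standard_normal(7)
            z = _z_of(v, ctx)
            if np.any(np.abs(z) < 1e-3):
                continue
            sys = active_set(v, ctx)
            d = rng.standard_normal(7)
            t = 1e-6
            fd = (grad_phi(v + t * d, ctx) - grad_phi(v, ctx)) / t
            hd = _hessian_matvec(d, sys, ctx)
            assert np.linalg.norm(fd - hd) <= 1e-4 * (1 + np.linalg.norm(hd))
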