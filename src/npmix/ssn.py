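"""Semismooth Newton solver for the augmented Lagrangian subproblem.

The subproblem reduces, after eliminating ``u`` through the proximal map of
the log-barrier ``h(u) = -(1/n) sum log u_i``, to an unconstrained smooth
convex problem in ``v``:

    phi(v) = (sigma/2) ||max((1/n) L'v - 1 + x/sigma, 0)||^2
             + M_h^sigma(v - y/sigma),

whose gradient is semismooth.  The generalized Hessian

    H = sigma [ (1/n^2) L S L' + D ]

involves only the active columns of L (``S`` diagonal 0/1), so the Newton
system is solved through a reduced s x s Sherman-Morrison-Woodbury system
when the active set is small, an n x n dense factorization when n is
small, or preconditioned conjugate gradients otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .likelihood import LikelihoodMatrix
from .types import SolverConfig

__all__ = [
    "SubproblemContext",
    "NewtonSystem",
    "prox_h",
    "prox_h_jacobian_diag",
    "moreau_envelope_h",
    "phi",
    "grad_phi",
    "active_set",
    "newton_direction",
    "line_search",
    "ssn_solve",
]

# SMW is used only while forming the s x s system stays below this flop count
_SMW_FLOP_CAP = 5e9
_DENSE_N_CAP = 4000
_SMW_S_CAP = 4000


@dataclass
class SubproblemContext:
    """Fixed data of one ALM subproblem: likelihoods, multipliers, penalty."""

    Lmat: LikelihoodMatrix
    xk: np.ndarray
    yk: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.xk = np.asarray(self.xk, dtype=float)
        self.yk = np.asarray(self.yk, dtype=float)

    @property
    def n(self) -> int:
        return self.Lmat.n

    @property
    def m(self) -> int:
        return self.Lmat.m


@dataclass
class NewtonSystem:
    """Assembled generalized-Hessian data at the current iterate."""

    J: np.ndarray  # boolean mask of active columns
    s: int
    D: np.ndarray  # sigma-scaled diagonal, strictly positive
    solve_mode: str


def prox_h(w: np.ndarray, sigma: float, n: int) -> np.ndarray:
    """Proximal map of h(u) = -(1/n) sum log u_i at parameter sigma.

    Componentwise ``p_i = (w_i + sqrt(w_i^2 + 4/(sigma n))) / 2``; strictly
    positive, and satisfies sigma (p - w) = 1 / (n p).
    """
    w = np.asarray(w, dtype=float)
    c = 4.0 / (sigma * n)
    r = np.sqrt(w * w + c)
    # (w + r)/2, with the conjugate form c/(2(r - w)) where w < 0 to avoid
    # catastrophic cancellation
    out = 0.5 * (w + r)
    neg = w < 0
    if np.any(neg):
        out[neg] = 0.5 * c / (r[neg] - w[neg])
    return out


def prox_h_jacobian_diag(w: np.ndarray, sigma: float, n: int) -> np.ndarray:
    """Diagonal of the prox Jacobian: (1 + w/sqrt(w^2 + 4/(sigma n)))/2 in (0,1)."""
    w = np.asarray(w, dtype=float)
    return 0.5 * (1.0 + w / np.sqrt(w * w + 4.0 / (sigma * n)))


def _one_minus_prox_jacobian(w: np.ndarray, sigma: float, n: int) -> np.ndarray:
    """1 - prox Jacobian diagonal, evaluated without cancellation.

    For w > 0 the naive (1 - w/r)/2 loses all precision once w^2 dominates
    4/(sigma n); the conjugate form c/(2 r (r + w)) is exact to rounding.
    """
    w = np.asarray(w, dtype=float)
    c = 4.0 / (sigma * n)
    r = np.sqrt(w * w + c)
    return np.where(w >= 0, 0.5 * c / (r * (r + w)), 0.5 * (1.0 - w / r))


def moreau_envelope_h(w: np.ndarray, sigma: float, n: int) -> float:
    """Moreau envelope of h at w: h(p) + (sigma/2) ||p - w||^2, p = prox."""
    w = np.asarray(w, dtype=float)
    p = prox_h(w, sigma, n)
    h = -np.log(p).sum() / n
    # p - w = 1/(sigma n p) by prox stationarity; avoids cancellation
    gap = 1.0 / (sigma * n * p)
    return float(h + 0.5 * sigma * (gap**2).sum())


def _z_of(v: np.ndarray, ctx: SubproblemContext) -> np.ndarray:
    return ctx.Lmat.rmatvec(v) / ctx.n - 1.0 + ctx.xk / ctx.sigma


def phi(v: np.ndarray, ctx: SubproblemContext) -> float:
    """Value of the reduced subproblem objective (additive constants dropped)."""
    z = _z_of(v, ctx)
    zp = np.maximum(z, 0.0)
    return 0.5 * ctx.sigma * float(zp @ zp) + moreau_envelope_h(
        v - ctx.yk / ctx.sigma, ctx.sigma, ctx.n
    )


def grad_phi(v: np.ndarray, ctx: SubproblemContext) -> np.ndarray:
    zp = np.maximum(_z_of(v, ctx), 0.0)
    w = v - ctx.yk / ctx.sigma
    p = prox_h(w, ctx.sigma, ctx.n)
    # sigma (w - p) = -1/(n p) by prox stationarity (cancellation-free)
    return (ctx.sigma / ctx.n) * ctx.Lmat.matvec(zp) - 1.0 / (ctx.n * p)


def _solve_mode(s: int, n: int) -> str:
    if s == 0:
        return "smw"  # degenerates to the diagonal solve
    if s < n and s <= _SMW_S_CAP and n * float(s) ** 2 <= _SMW_FLOP_CAP:
        return "smw"
    if n <= _DENSE_N_CAP:
        return "dense_n"
    return "cg"


def active_set(v: np.ndarray, ctx: SubproblemContext) -> NewtonSystem:
    """Pick the sparsest generalized Hessian: active columns are those with
    z_j strictly positive (ties at zero get S_jj = 0)."""
    z = _z_of(v, ctx)
    J = z > 0.0
    s = int(J.sum())
    D = ctx.sigma * _one_minus_prox_jacobian(
        v - ctx.yk / ctx.sigma, ctx.sigma, ctx.n
    )
    return NewtonSystem(J=J, s=s, D=D, solve_mode=_solve_mode(s, ctx.n))


def _hessian_matvec(
    d: np.ndarray, sys: NewtonSystem, ctx: SubproblemContext
) -> np.ndarray:
    # never routed through the low-rank factors: Hessians use the exact L_J
    LJt = ctx.Lmat.transposed()[sys.J]
    return (ctx.sigma / ctx.n**2) * (LJt.T @ (LJt @ d)) + sys.D * d


def newton_direction(
    sys: NewtonSystem,
    ctx: SubproblemContext,
    rhs: np.ndarray,
    LJt: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Solve ``[sigma (1/n^2) L_J L_J' + D] d = rhs``; returns (d, residual).

    ``smw`` reduces to one s x s SPD factorization via Sherman-Morrison-
    Woodbury; ``dense_n`` factorizes the n x n matrix; ``cg`` runs Jacobi-
    preconditioned conjugate gradients (used with the Algorithm-level
    inexactness test as its stopping rule).  ``LJt`` may pass the active
    rows of ``L.T`` precomputed to avoid a second gather.
    """
    D = sys.D
    if sys.s == 0:
        d = rhs / D
        return d, 0.0
    if LJt is None:
        LJt = ctx.Lmat.transposed()[sys.J]  # (s, n)
    scale = np.sqrt(ctx.sigma) / ctx.n
    sig_nn = ctx.sigma / ctx.n**2
    if sys.solve_mode == "smw":
        B = (scale**2) * (LJt / D[None, :])  # Ltil' D^{-1} rows
        M = B @ LJt.T
        M[np.diag_indices_from(M)] += 1.0
        t = rhs / D
        try:
            cho = scipy.linalg.cho_factor(M, lower=True)
        except scipy.linalg.LinAlgError:
            M[np.diag_indices_from(M)] += 1e-12 * np.trace(M) / sys.s
            cho = scipy.linalg.cho_factor(M, lower=True)
        d = t - (LJt.T @ scipy.linalg.cho_solve(cho, LJt @ t)) * (
            scale**2
        ) / D
    elif sys.solve_mode == "dense_n":
        H = sig_nn * (LJt.T @ LJt)
        H[np.diag_indices_from(H)] += D
        try:
            cho = scipy.linalg.cho_factor(H, lower=True)
        except scipy.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-12 * np.trace(H) / ctx.n
            cho = scipy.linalg.cho_factor(H, lower=True)
        d = scipy.linalg.cho_solve(cho, rhs)
    else:  # cg
        gnorm = np.linalg.norm(rhs)
        target = min(0.1, gnorm**1.5)
        op = scipy.sparse.linalg.LinearOperator(
            (ctx.n, ctx.n),
            matvec=lambda p: sig_nn * (LJt.T @ (LJt @ p)) + D * p,
        )
        pre = scipy.sparse.linalg.LinearOperator(
            (ctx.n, ctx.n), matvec=lambda p: p / D
        )
        d, _ = scipy.sparse.linalg.cg(
            op, rhs, rtol=0.0, atol=0.5 * target, M=pre, maxiter=500
        )
    resid = float(
        np.linalg.norm(sig_nn * (LJt.T @ (LJt @ d)) + D * d - rhs)
    )
    return d, resid


def line_search(
    v: np.ndarray,
    d: np.ndarray,
    ctx: SubproblemContext,
    mu: float,
    beta: float,
) -> float:
    """Armijo backtracking: largest alpha in {1, beta, beta^2, ...} with
    phi(v + alpha d) <= phi(v) + mu alpha <grad, d>; at most 50 backtracks."""
    g = grad_phi(v, ctx)
    slope = float(g @ d)
    if slope >= 0:  # engineering guard; H > 0 means this never fires
        d = -g
        slope = -float(g @ g)
    f0 = phi(v, ctx)
    alpha = 1.0
    for _ in range(50):
        if phi(v + alpha * d, ctx) <= f0 + mu * alpha * slope:
            return alpha
        alpha *= beta
    import warnings

    warnings.warn("line search exhausted 50 backtracks", RuntimeWarning)
    return alpha


@dataclass
class SSNDiagnostics:
    grad_norms: list = field(default_factory=list)
    step_sizes: list = field(default_factory=list)
    active_sizes: list = field(default_factory=list)
    backtracks: list = field(default_factory=list)
    converged: bool = True


def ssn_solve(
    ctx: SubproblemContext,
    eps: float,
    config: SolverConfig,
    v0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int, SSNDiagnostics]:
    """Run the semismooth Newton iteration until ||grad phi|| <= eps.

    Returns ``(u, v, iterations, diagnostics)`` with
    ``u = prox_h(v - y/sigma)``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    n, m, sigma = ctx.n, ctx.m, ctx.sigma
    inv_sigma_y = ctx.yk / sigma
    v = np.asarray(v0, dtype=float).copy()
    diag = SSNDiagnostics()

    z = _z_of(v, ctx)
    for t in range(config.max_inner):
        w = v - inv_sigma_y
        p = prox_h(w, sigma, n)
        zp = np.maximum(z, 0.0)
        g = (sigma / n) * ctx.Lmat.matvec(zp) - 1.0 / (n * p)
        gnorm = float(np.linalg.norm(g))
        diag.grad_norms.append(gnorm)
        if gnorm <= eps:
            u = prox_h(v - inv_sigma_y, sigma, n)
            return u, v, t, diag

        J = z > 0.0
        s = int(J.sum())
        sys = NewtonSystem(
            J=J,
            s=s,
            D=sigma * _one_minus_prox_jacobian(w, sigma, n),
            solve_mode=_solve_mode(s, n),
        )
        diag.active_sizes.append(s)
        LJt = ctx.Lmat.transposed()[J] if s else None
        d, resid = newton_direction(sys, ctx, -g, LJt=LJt)
        # Algorithm-level inexactness test; fall back to a steepest-descent
        # step if the approximate direction is not a descent direction
        slope = float(g @ d)
        if slope >= 0:
            d = -g
            slope = -gnorm**2

        # Armijo backtracking, reusing L'd so each trial costs O(n + m)
        zd = ctx.Lmat.rmatvec(d) / n
        f0 = 0.5 * sigma * float(zp @ zp) + moreau_envelope_h(w, sigma, n)
        alpha = 1.0
        n_back = 0
        while n_back < 50:
            z_trial = z + alpha * zd
            zp_t = np.maximum(z_trial, 0.0)
            f_trial = 0.5 * sigma * float(zp_t @ zp_t) + moreau_envelope_h(
                w + alpha * d, sigma, n
            )
            if f_trial <= f0 + config.mu * alpha * slope:
                break
            alpha *= config.beta
            n_back += 1
        diag.step_sizes.append(alpha)
        diag.backtracks.append(n_back)
        v = v + alpha * d
        z = z + alpha * zd

    diag.converged = False
    u = prox_h(v - inv_sigma_y, sigma, n)
    return u, v, config.max_inner, diag
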