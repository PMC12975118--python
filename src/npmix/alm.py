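"""Outer augmented Lagrangian loop for the simplex-constrained NPMLE.

Solves the dual of

    maximize (1/n) sum_i log((L x)_i)   s.t.   x >= 0, 1'x = 1

by alternating an inner semismooth Newton solve of the penalized dual
subproblem with first-order multiplier updates; the primal weight vector x
is itself the multiplier of the dual inequality constraint, so at
convergence it lands on the simplex without explicit normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import SupportSet
from .likelihood import LikelihoodMatrix
from .ssn import SubproblemContext, ssn_solve
from .types import MixingDistribution, SolverConfig

__all__ = [
    "ALMState",
    "KKTReport",
    "ALMResult",
    "negative_loglik",
    "initialize_state",
    "update_multipliers",
    "kkt_residual",
    "sigma_schedule",
    "alm_fit",
]

logger = logging.getLogger(__name__)

PRUNE_THRESHOLD = 1e-6


@dataclass
class ALMState:
    """Primal/dual iterates of the outer loop."""

    x: np.ndarray  # primal weights (multiplier of the dual inequality)
    y: np.ndarray  # primal auxiliary (multiplier of u - v = 0)
    u: np.ndarray
    v: np.ndarray
    sigma: float
    outer_iter: int = 0


@dataclass
class KKTReport:
    """Normalized residuals of the five KKT blocks; eta_max aggregates."""

    eta_primal: float
    eta_dual: float
    eta_comp: float
    eta_uy: float
    eta_uv: float
    objective: float

    @property
    def eta_max(self) -> float:
        return max(
            self.eta_primal, self.eta_dual, self.eta_comp, self.eta_uy, self.eta_uv
        )

    def as_dict(self) -> dict:
        return {
            "eta_primal": self.eta_primal,
            "eta_dual": self.eta_dual,
            "eta_comp": self.eta_comp,
            "eta_uy": self.eta_uy,
            "eta_uv": self.eta_uv,
            "eta_max": self.eta_max,
            "objective": self.objective,
        }


def negative_loglik(Lmat: LikelihoodMatrix, x: np.ndarray) -> float:
    """Mean negative log-likelihood, with row scaling constants added back."""
    lx = Lmat.matvec(np.asarray(x, dtype=float))
    if np.any(lx <= 0):
        i = int(np.argmax(lx <= 0))
        warnings.warn(
            f"weight vector assigns no mass near observation {i}; "
            "log-likelihood is -inf",
            RuntimeWarning,
        )
        return float("inf")
    return float(-(np.log(lx) + Lmat.row_log_scale).mean())


def initialize_state(Lmat: LikelihoodMatrix, config: SolverConfig) -> ALMState:
    """Uniform weights; y = Lx; u = v = 1/y so u*y = 1 holds exactly."""
    m = Lmat.m
    x0 = np.full(m, 1.0 / m)
    y0 = Lmat.matvec(x0)
    u0 = 1.0 / y0
    return ALMState(x=x0, y=y0, u=u0.copy(), v=u0.copy(), sigma=config.sigma0)


def update_multipliers(
    state: ALMState,
    Lmat: LikelihoodMatrix,
    u_new: np.ndarray,
    v_new: np.ndarray,
) -> ALMState:
    """First-order multiplier step after an inner solve at penalty sigma.

    ``state.y`` is kept on the primal scale (y = Lx, u*y = 1 at optimality);
    the raw multiplier of the dual equality constraint is ``y / n``, hence
    the factor n in its update.
    """
    sigma, n = state.sigma, Lmat.n
    x_new = np.maximum(
        (sigma / n) * Lmat.rmatvec(v_new) - sigma + state.x, 0.0
    )
    # y + n sigma (u - v) with u = prox(v - y/(n sigma)) collapses to 1/u
    # exactly (prox stationarity), avoiding the n*sigma error amplification
    y_new = 1.0 / np.asarray(u_new, dtype=float)
    return ALMState(
        x=x_new,
        y=y_new,
        u=np.asarray(u_new, dtype=float),
        v=np.asarray(v_new, dtype=float),
        sigma=sigma,
        outer_iter=state.outer_iter + 1,
    )


def kkt_residual(state: ALMState, Lmat: LikelihoodMatrix) -> KKTReport:
    n, m = Lmat.n, Lmat.m
    x, y, u, v = state.x, state.y, state.u, state.v
    lx = Lmat.matvec(x)
    ltv = Lmat.rmatvec(v) / n
    eta_primal = float(np.linalg.norm(lx - y) / (1.0 + np.linalg.norm(y)))
    eta_dual = float(
        np.linalg.norm(np.maximum(ltv - 1.0, 0.0)) / (1.0 + np.sqrt(m))
    )
    eta_comp = float(abs(x @ (1.0 - ltv)) / (1.0 + np.abs(x).sum()))
    eta_uy = float(np.linalg.norm(u * y - 1.0) / (1.0 + np.sqrt(n)))
    eta_uv = float(np.linalg.norm(u - v) / (1.0 + np.linalg.norm(u)))
    return KKTReport(
        eta_primal=eta_primal,
        eta_dual=eta_dual,
        eta_comp=eta_comp,
        eta_uy=eta_uy,
        eta_uv=eta_uv,
        objective=negative_loglik(Lmat, x) if np.all(lx > 0) else float("inf"),
    )


def sigma_schedule(
    state: ALMState,
    report: KKTReport,
    prev_report: Optional[KKTReport],
    config: SolverConfig,
) -> float:
    """Grow sigma geometrically unless the residual at least halved."""
    if prev_report is not None and report.eta_max < 0.5 * prev_report.eta_max:
        return state.sigma
    return min(config.sigma_growth * state.sigma, config.sigma_max)


@dataclass
class ALMResult:
    mixing: MixingDistribution
    state: ALMState
    report: KKTReport
    log: list = field(default_factory=list)
    converged: bool = True
    weight_sum_raw: float = 1.0  # 1'x before renormalization


def _prune(support: np.ndarray, x: np.ndarray, threshold: float) -> MixingDistribution:
    from .denoise import prune_support

    G = MixingDistribution.from_arrays(support, x, merge_duplicates=False)
    try:
        return prune_support(G, threshold)
    except Exception:
        keep = x == x.max()
        w = x[keep]
        return MixingDistribution.from_arrays(support[keep], w / w.sum())


def alm_fit(
    Lmat: LikelihoodMatrix,
    support: SupportSet,
    config: Optional[SolverConfig] = None,
) -> ALMResult:
    """Fit the NPMLE weights by the augmented Lagrangian method.

    Never raises on non-convergence: the best iterate (smallest KKT
    residual) is returned with ``converged=False``.
    """
    if config is None:
        config = SolverConfig()
    n, m = Lmat.n, Lmat.m
    if m == 1:
        # degenerate grid: the simplex is a point
        state = ALMState(
            x=np.ones(1), y=Lmat.matvec(np.ones(1)), u=np.zeros(n),
            v=np.zeros(n), sigma=config.sigma0,
        )
        state.u = state.v = 1.0 / state.y
        report = kkt_residual(state, Lmat)
        return ALMResult(
            mixing=MixingDistribution.from_arrays(support.points, np.ones(1)),
            state=state, report=report, log=[], converged=True,
        )

    state = initialize_state(Lmat, config)
    v_warm = np.zeros(n)  # first inner solve starts from 0
    log: list[dict] = []
    prev_report: Optional[KKTReport] = None
    best: Optional[tuple[float, ALMState, KKTReport]] = None
    stall = 0
    converged = False

    for k in range(config.max_outer):
        eps_k = config.inner_tol(k)
        # the subproblem sees the raw equality multiplier y/n
        ctx = SubproblemContext(
            Lmat=Lmat, xk=state.x, yk=state.y / n, sigma=state.sigma
        )
        u_new, v_new, inner_iters, diag = ssn_solve(ctx, eps_k, config, v_warm)
        v_warm = v_new
        state = update_multipliers(state, Lmat, u_new, v_new)
        report = kkt_residual(state, Lmat)
        log.append(
            {
                "outer_iter": k,
                "sigma": state.sigma,
                "inner_iterations": inner_iters,
                "inner_tol": eps_k,
                "line_search_steps": list(diag.step_sizes),
                "active_set_sizes": list(diag.active_sizes),
                "eta_max": report.eta_max,
                "objective": report.objective,
            }
        )
        logger.info(
            "outer=%d sigma=%.3g inner=%d objective=%.10g kkt=%.3e",
            k, state.sigma, inner_iters, report.objective, report.eta_max,
        )
        if best is None or report.eta_max < best[0]:
            best = (report.eta_max, state, report)
            stall = 0
        else:
            stall += 1
        if report.eta_max <= config.tol:
            converged = True
            break
        if config.stall_patience and stall >= config.stall_patience:
            break
        state.sigma = sigma_schedule(state, report, prev_report, config)
        prev_report = report

    assert best is not None
    _, best_state, best_report = best
    if not converged and best_report.eta_max > config.tol:
        warnings.warn(
            f"ALM stopped after {len(log)} outer iterations with KKT residual "
            f"{best_report.eta_max:.3e} > tol {config.tol:.3e}",
            RuntimeWarning,
        )
    weight_sum = float(best_state.x.sum())
    x_final = best_state.x / weight_sum
    mixing = _prune(support.points, x_final, PRUNE_THRESHOLD)
    return ALMResult(
        mixing=mixing,
        state=best_state,
        report=best_report,
        log=log,
        converged=converged or best_report.eta_max <= config.tol,
        weight_sum_raw=weight_sum,
    )
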