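"""Independent reference solvers for the mixture-weights MLE.

These exist to certify the main solver: a classical EM fixed point, a
projected-gradient method with exact simplex projection, and an exhaustive
simplex-lattice search for very small m.  They share the likelihood-matrix
convention of the main solver (row scaling cancels everywhere it matters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alm import negative_loglik
from .likelihood import LikelihoodMatrix
from .types import InputError

__all__ = [
    "OracleResult",
    "em_solve",
    "projected_gradient_solve",
    "brute_force_simplex",
    "project_simplex",
]


@dataclass
class OracleResult:
    weights: np.ndarray
    objective: float
    iterations: int


def em_solve(
    Lmat: LikelihoodMatrix, max_iter: int = 10000, tol: float = 1e-10
) -> OracleResult:
    """Classical EM fixed point x_j <- x_j * (1/n) sum_i L_ij / (Lx)_i."""
    n, m = Lmat.n, Lmat.m
    x = np.full(m, 1.0 / m)
    it = 0
    for it in range(1, max_iter + 1):
        lx = Lmat.L @ x
        x_new = x * (Lmat.L.T @ (1.0 / lx)) / n
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta <= tol:
            break
    return OracleResult(weights=x, objective=negative_loglik(Lmat, x), iterations=it)


def project_simplex(p: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sorting algorithm)."""
    p = np.asarray(p, dtype=float)
    u = np.sort(p)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, p.size + 1) > 0)[0][-1]
    lam = css[rho] / (rho + 1)
    return np.maximum(p - lam, 0.0)


def projected_gradient_solve(
    Lmat: LikelihoodMatrix, max_iter: int = 10000, tol: float = 1e-10
) -> OracleResult:
    """Projected gradient with Armijo backtracking on the simplex."""
    n, m = Lmat.n, Lmat.m
    x = np.full(m, 1.0 / m)
    f = negative_loglik(Lmat, x)
    step = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        lx = Lmat.L @ x
        grad = -(Lmat.L.T @ (1.0 / lx)) / n
        # backtracking on the projected step
        accepted = False
        for _ in range(60):
            x_new = project_simplex(x - step * grad)
            lx_new = Lmat.L @ x_new
            if np.all(lx_new > 0):
                f_new = float(-(np.log(lx_new) + Lmat.row_log_scale).mean())
                if f_new <= f + grad @ (x_new - x) + np.sum(
                    (x_new - x) ** 2
                ) / (2.0 * step):
                    accepted = True
                    break
            step *= 0.5
        if not accepted:
            break
        delta = np.abs(x_new - x).max()
        x, f = x_new, f_new
        step = min(step * 2.0, 1e6)
        if delta <= tol:
            break
    return OracleResult(weights=x, objective=negative_loglik(Lmat, x), iterations=it)


def _nll_quiet(Lmat: LikelihoodMatrix, x: np.ndarray) -> float:
    lx = Lmat.L @ x
    if np.any(lx <= 0):
        return np.inf
    return float(-(np.log(lx) + Lmat.row_log_scale).mean())


def _lattice(m: int, step: float):
    k = int(round(1.0 / step))
    if m == 1:
        yield np.array([1.0])
    elif m == 2:
        for i in range(k + 1):
            yield np.array([i / k, 1.0 - i / k])
    else:
        for i in range(k + 1):
            for j in range(k + 1 - i):
                yield np.array([i / k, j / k, 1.0 - (i + j) / k])


def brute_force_simplex(Lmat: LikelihoodMatrix, step: float = 1e-3) -> OracleResult:
    """Exhaustive lattice search over the simplex (m <= 3) followed by one
    local refinement pass at step/100 around the best lattice point."""
    m = Lmat.m
    if m > 3:
        raise InputError("brute_force_simplex supports m <= 3 only")
    best_x, best_f, count = None, np.inf, 0
    for x in _lattice(m, step):
        count += 1
        f = _nll_quiet(Lmat, x)
        if f < best_f:
            best_f, best_x = f, x
    # refinement: rescan a small box around the best point at step/100
    fine = step / 100.0
    if m > 1:
        center = best_x
        offsets = np.arange(-100, 101) * fine
        if m == 2:
            for da in offsets:
                a = center[0] + da
                if 0.0 <= a <= 1.0:
                    x = np.array([a, 1.0 - a])
                    f = _nll_quiet(Lmat, x)
                    count += 1
                    if f < best_f:
                        best_f, best_x = f, x
        else:
            coarse = np.arange(-10, 11) * (step / 10.0)
            for da in coarse:
                for db in coarse:
                    a, b = center[0] + da, center[1] + db
                    if a >= 0 and b >= 0 and a + b <= 1.0:
                        x = np.array([a, b, 1.0 - a - b])
                        f = _nll_quiet(Lmat, x)
                        count += 1
                        if f < best_f:
                            best_f, best_x = f, x
    return OracleResult(weights=best_x, objective=best_f, iterations=count)
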