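"""Likelihood-matrix assembly with underflow-safe row scaling.

The stored matrix has each row divided by its largest raw likelihood, so
the row maximum is exactly 1 and no entry underflows spuriously; the log
scaling constants are kept so the unscaled log-likelihood is recoverable.
An optional column-pivoted truncated QR factorization can be attached to
accelerate matrix-vector products in gradient evaluations (it is never
used for Hessian assembly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .grid import SupportSet
from .types import InputError, MixtureData

__all__ = ["LikelihoodMatrix", "compute_likelihood_matrix", "lowrank_factorize"]

_LOG_2PI = float(np.log(2.0 * np.pi))

# row-chunk size keeping temporaries near ~64 MB for wide matrices
_CHUNK_ELEMS = 8_000_000


@dataclass
class LikelihoodMatrix:
    """Row-scaled likelihood matrix.

    ``raw[i, j] = exp(row_log_scale[i]) * L[i, j]``.
    """

    L: np.ndarray
    row_log_scale: np.ndarray
    lowrank: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    def transposed(self) -> np.ndarray:
        """C-contiguous copy of ``L.T``, cached.

        Row gathers on the transpose are dramatically cheaper than column
        gathers on ``L``; the active-set Newton solve relies on this.
        """
        LT = getattr(self, "_LT", None)
        if LT is None:
            LT = np.ascontiguousarray(self.L.T)
            object.__setattr__(self, "_LT", LT)
        return LT

    @property
    def n(self) -> int:
        return self.L.shape[0]

    @property
    def m(self) -> int:
        return self.L.shape[1]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """``L @ x``, through the low-rank factors when attached."""
        if self.lowrank is not None:
            Q, R, perm = self.lowrank
            return Q @ (R @ x[perm])
        return self.L @ x

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        """``L.T @ v``, through the low-rank factors when attached."""
        if self.lowrank is not None:
            Q, R, perm = self.lowrank
            out = np.empty(self.m)
            out[perm] = R.T @ (Q.T @ v)
            return out
        return self.L.T @ v


def _cross_product(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """``A @ B.T`` for tall-skinny factors; broadcasting beats dgemm's
    degenerate rank-d kernel for small d on this class of BLAS."""
    d = A.shape[1]
    if d > 4:
        return A @ B.T
    out = np.multiply.outer(A[:, 0], B[:, 0])
    for k in range(1, d):
        out += np.multiply.outer(A[:, k], B[:, k])
    return out


def _log_density_location(data: MixtureData, points: np.ndarray) -> np.ndarray:
    """log phi_{Sigma_i}(Y_i - mu_j) for all (i, j), computed blockwise."""
    Y, d = data.Y, data.d
    n, m = data.n, points.shape[0]
    if data.cov_mode == "shared":
        cho = scipy.linalg.cho_factor(data.covs, lower=True)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        Sinv = scipy.linalg.cho_solve(cho, np.eye(d))
        # (y-mu)' Sinv (y-mu) = a_i - 2 y' Sinv mu + c_j; one gemm plus
        # in-place broadcast subtractions (no n x m temporaries)
        YS = Y @ Sinv
        a = np.einsum("ij,ij->i", YS, Y)
        c = np.einsum("ij,ij->i", points @ Sinv, points)
        out = _cross_product(YS, points)
        out -= 0.5 * c[None, :]
        out -= (0.5 * (a + d * _LOG_2PI + logdet))[:, None]
    elif data.cov_mode == "diag":
        inv = 1.0 / data.covs  # (n, d)
        logdet = np.log(data.covs).sum(axis=1)
        a = ((Y**2) * inv).sum(axis=1)
        out = inv @ (points.T**2)
        out *= -0.5
        out += _cross_product(Y * inv, points)
        out -= (0.5 * (a + d * _LOG_2PI + logdet))[:, None]
    else:  # full: cache factorizations of repeated covariance blocks
        out = np.empty((n, m))
        cache: dict[bytes, tuple] = {}
        for i in range(n):
            key = data.covs[i].tobytes()
            if key not in cache:
                cho = scipy.linalg.cho_factor(data.covs[i], lower=True)
                cache[key] = (cho, 2.0 * np.log(np.diag(cho[0])).sum())
            cho, logdet = cache[key]
            diff = Y[i][None, :] - points  # (m, d)
            sol = scipy.linalg.cho_solve(cho, diff.T)
            out[i] = -0.5 * np.einsum("jm,mj->m", sol, diff)
            out[i] -= 0.5 * (d * _LOG_2PI + logdet)
    return out


def _log_density_scale(data: MixtureData, variances: np.ndarray) -> np.ndarray:
    y2 = data.Y.ravel() ** 2
    v = variances.ravel()
    return -0.5 * (np.outer(y2, 1.0 / v) + (_LOG_2PI + np.log(v))[None, :])


def compute_likelihood_matrix(
    data: MixtureData, support: SupportSet
) -> LikelihoodMatrix:
    """Evaluate the n x m likelihood matrix in the log domain and scale each
    row by its maximum so every stored row has maximum exactly 1."""
    if support.kind == "scale":
        if data.d != 1:
            raise InputError("scale mixtures require one-dimensional data")
        logL = _log_density_scale(data, support.points)
    else:
        if support.d != data.d:
            raise InputError(
                f"support dimension {support.d} != data dimension {data.d}"
            )
        logL = _log_density_location(data, support.points)
    row_log_scale = logL.max(axis=1)
    # exponentiate in row chunks to bound temporaries; entries below the
    # subnormal range are flushed to exact zero (subnormals would make all
    # downstream BLAS dramatically slower without affecting the solution)
    n, m = logL.shape
    step = max(1, _CHUNK_ELEMS // max(m, 1))
    for start in range(0, n, step):
        sl = slice(start, min(start + step, n))
        block = logL[sl]
        block -= row_log_scale[sl, None]
        np.maximum(block, -700.0, out=block)
        np.exp(block, out=block)
        block[block <= 1e-300] = 0.0
    return LikelihoodMatrix(L=logL, row_log_scale=row_log_scale)


def lowrank_factorize(
    Lmat: LikelihoodMatrix, rank_tol: float, max_rank: int
) -> LikelihoodMatrix:
    """Attach a column-pivoted truncated QR factorization ``L ~ Q R P^T``.

    The rank k is the smallest for which the trailing block of R satisfies
    ``||L - Q R P^T||_F <= rank_tol * ||L||_F``; if that k exceeds
    ``max_rank`` the matrix is returned without factors.
    """
    if rank_tol <= 0:
        raise InputError("rank_tol must be positive")
    L = Lmat.L
    Q, R, perm = scipy.linalg.qr(L, mode="economic", pivoting=True)
    # residual of the rank-k truncation is the Frobenius norm of R[k:, :]
    row_sq = (R**2).sum(axis=1)
    tail = np.concatenate([np.cumsum(row_sq[::-1])[::-1], [0.0]])
    target = (rank_tol * np.linalg.norm(L)) ** 2
    k = int(np.searchsorted(-tail, -target))  # smallest k with tail[k] <= target
    k = max(k, 1)
    if k > max_rank:
        return LikelihoodMatrix(L=L, row_log_scale=Lmat.row_log_scale)
    return LikelihoodMatrix(
        L=L,
        row_log_scale=Lmat.row_log_scale,
        lowrank=(np.ascontiguousarray(Q[:, :k]), np.ascontiguousarray(R[:k]), perm),
    )
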