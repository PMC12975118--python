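"""Core data types shared across the package.

Conventions: rows index observations, columns index coordinates. Support
matrices are ``(m, d)``; weight vectors live on the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "InputError",
    "ParseError",
    "ValidationError",
    "MixtureData",
    "MixingDistribution",
    "SolverConfig",
    "SPD_TOL",
]

#: tolerance used when certifying positive definiteness of covariances
SPD_TOL = 1e-12


class InputError(ValueError):
    """Malformed or dimensionally inconsistent user input."""


class ParseError(InputError):
    """A cell of a delimited file could not be parsed as a number."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _check_spd(mat: np.ndarray, label: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10, rtol=0.0):
        raise ValidationError(f"{label}: covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= SPD_TOL:
        raise ValidationError(
            f"{label}: covariance is not positive definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )


@dataclass
class MixtureData:
    """Observations with known per-observation Gaussian noise covariances.

    Parameters
    ----------
    Y
        ``(n, d)`` observation matrix.
    covs
        Covariance specification, interpreted according to ``cov_mode``:
        ``"shared"`` — a single ``(d, d)`` SPD matrix; ``"diag"`` — an
        ``(n, d)`` matrix of positive per-coordinate variances; ``"full"`` —
        an ``(n, d, d)`` stack of SPD matrices.
    cov_mode
        One of ``{"shared", "diag", "full"}``.
    """

    Y: np.ndarray
    covs: np.ndarray
    cov_mode: str = "shared"

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        n, d = self.Y.shape
        if n < 1 or d < 1:
            raise ValidationError("need n >= 1 and d >= 1")
        if not np.all(np.isfinite(self.Y)):
            raise ValidationError("non-finite entries in observation matrix")
        if self.cov_mode == "shared":
            if self.covs.shape != (d, d):
                raise InputError(
                    f"shared covariance must be {d}x{d}, got {self.covs.shape}"
                )
            _check_spd(self.covs, "shared covariance")
        elif self.cov_mode == "diag":
            if self.covs.shape != (n, d):
                raise InputError(
                    f"diagonal variances must be {n}x{d}, got {self.covs.shape}"
                )
            if np.any(self.covs <= SPD_TOL):
                i = int(np.argwhere(self.covs.min(axis=1) <= SPD_TOL)[0, 0])
                raise ValidationError(
                    f"observation {i}: nonpositive variance in diagonal covariance"
                )
        elif self.cov_mode == "full":
            if self.covs.shape != (n, d, d):
                raise InputError(
                    f"full covariances must be {n}x{d}x{d}, got {self.covs.shape}"
                )
            for i in range(n):
                _check_spd(self.covs[i], f"observation {i}")
        else:
            raise InputError(f"unknown cov_mode {self.cov_mode!r}")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def d(self) -> int:
        return self.Y.shape[1]


def _merge_duplicate_rows(
    support: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(support, axis=0, return_inverse=True)
    merged = np.zeros(uniq.shape[0])
    np.add.at(merged, inverse, weights)
    return uniq, merged


@dataclass
class MixingDistribution:
    """Discrete mixing distribution: atoms ``support`` with ``weights``."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.atleast_2d(np.asarray(self.support, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.size == 0:
            raise ValidationError("mixing distribution has no atoms")
        if self.support.shape[0] != self.weights.size:
            raise ValidationError(
                f"{self.support.shape[0]} atoms but {self.weights.size} weights"
            )
        if np.any(self.weights < 0):
            raise ValidationError("negative mixture weights")
        if not np.all(np.isfinite(self.support)):
            raise ValidationError("non-finite support points")

    @classmethod
    def from_arrays(
        cls,
        support: np.ndarray,
        weights: np.ndarray,
        merge_duplicates: bool = True,
    ) -> "MixingDistribution":
        support = np.atleast_2d(np.asarray(support, dtype=float))
        weights = np.asarray(weights, dtype=float).ravel()
        if merge_duplicates and support.shape[0] > 1:
            support, weights = _merge_duplicate_rows(support, weights)
        return cls(support, weights)

    @property
    def m(self) -> int:
        return self.weights.size

    @property
    def d(self) -> int:
        return self.support.shape[1]

    def has_duplicate_atoms(self) -> bool:
        return np.unique(self.support, axis=0).shape[0] < self.support.shape[0]

    def check_normalized(self, tol: float = 1e-8) -> None:
        s = self.weights.sum()
        if abs(s - 1.0) > tol:
            raise ValidationError(f"weights sum to {s!r}, not 1")


@dataclass
class SolverConfig:
    """Tuning knobs for the augmented Lagrangian solver.

    ``inner_tol0 * inner_tol_decay**k`` (floored at ``0.1 * tol``) is the
    gradient-norm tolerance handed to the inner Newton solver at outer
    iteration ``k``; the geometric decay makes the schedule summable.
    """

    sigma0: float = 1.0
    sigma_growth: float = 3.0
    sigma_max: float = 1e8
    tol: float = 1e-6
    max_outer: int = 100
    inner_tol0: float = 1e-3
    inner_tol_decay: float = 0.5
    eta_bar: float = 0.1
    tau: float = 0.5
    mu: float = 1e-4
    beta: float = 0.5
    max_inner: int = 50
    seed: int = 0
    # stop when eta_max has not improved for this many consecutive outer
    # iterations (0 disables the rule); the best iterate is returned
    stall_patience: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.sigma_max <= 0:
            raise ValidationError("penalty parameters must be positive")
        if self.sigma_growth < 1:
            raise ValidationError("sigma_growth must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValidationError("iteration limits must be positive")
        if not (0 < self.inner_tol_decay < 1) or self.inner_tol0 <= 0:
            raise ValidationError("inner tolerance schedule must be summable")
        if not (0 < self.eta_bar < 1):
            raise ValidationError("eta_bar must lie in (0, 1)")
        if not (0 < self.tau <= 1):
            raise ValidationError("tau must lie in (0, 1]")
        if not (0 < self.mu < 0.5):
            raise ValidationError("mu must lie in (0, 1/2)")
        if not (0 < self.beta < 1):
            raise ValidationError("beta must lie in (0, 1)")

    def inner_tol(self, k: int) -> float:
        return max(self.inner_tol0 * self.inner_tol_decay**k, 0.1 * self.tol)
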