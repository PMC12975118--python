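"""Seeded generators for the simulation designs used throughout the tests.

All generators are pure functions of their arguments and the seed; latent
truths are returned for evaluation only and never enter the fitting path.
"""

from __future__ import annotations

import numpy as np

from .types import InputError, MixingDistribution, MixtureData

__all__ = ["gen_example1", "gen_example2", "gen_circles", "gen_generic"]


def gen_example1(
    n: int,
    nu: float,
    tau: int,
    seed: int,
    bernoulli: bool = False,
) -> tuple[MixtureData, np.ndarray]:
    """Sparse two-point design: tau latent means equal nu, the rest 0;
    unit Gaussian noise.

    By default exactly ``tau`` uniformly chosen indices carry the signal;
    ``bernoulli=True`` instead flips an independent coin with probability
    tau/n per observation.
    """
    if not (0 <= tau <= n):
        raise InputError("need 0 <= tau <= n")
    rng = np.random.default_rng(seed)
    theta = np.zeros(n)
    if bernoulli:
        theta[rng.random(n) < tau / n] = nu
    elif tau > 0:
        theta[rng.choice(n, size=tau, replace=False)] = nu
    Y = theta + rng.standard_normal(n)
    data = MixtureData(Y=Y[:, None], covs=np.eye(1), cov_mode="shared")
    return data, theta


def gen_example2(n: int, seed: int) -> MixtureData:
    """Heavy-tail design: contiguous blocks drawn from N(0,1), t_4, t_6 with
    exact counts (round(0.2 n), round(0.3 n), remainder to the normal block).
    Block order is normal, t4, t6."""
    if n < 1:
        raise InputError("need n >= 1")
    n2 = int(round(0.2 * n))
    n3 = int(round(0.3 * n))
    n1 = n - n2 - n3
    rng = np.random.default_rng(seed)
    blocks = [
        rng.standard_normal(n1),
        rng.standard_t(4, size=n2),
        rng.standard_t(6, size=n3),
    ]
    Y = np.concatenate(blocks)
    return MixtureData(Y=Y[:, None], covs=np.eye(1), cov_mode="shared")


def gen_circles(
    n: int,
    radii: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
) -> tuple[MixtureData, np.ndarray]:
    """Latent means uniform on two concentric circles (half each), with
    standard bivariate Gaussian noise."""
    if n % 2 != 0:
        raise InputError("need an even n (half the points per circle)")
    if min(radii) <= 0:
        raise InputError("radii must be positive")
    rng = np.random.default_rng(seed)
    half = n // 2
    theta = np.empty((n, 2))
    for b, r in enumerate(radii):
        ang = rng.uniform(0.0, 2.0 * np.pi, size=half)
        theta[b * half : (b + 1) * half, 0] = r * np.cos(ang)
        theta[b * half : (b + 1) * half, 1] = r * np.sin(ang)
    Y = theta + rng.standard_normal((n, 2))
    data = MixtureData(Y=Y, covs=np.eye(2), cov_mode="shared")
    return data, theta


def gen_generic(
    n: int,
    G_star: MixingDistribution,
    covs: np.ndarray,
    seed: int,
    cov_mode: str = "shared",
) -> tuple[MixtureData, np.ndarray]:
    """Location mixture: theta_i i.i.d. from the discrete G_star, plus
    independent Gaussian noise with the given covariance specification."""
    if n < 1:
        raise InputError("need n >= 1")
    G_star.check_normalized()
    rng = np.random.default_rng(seed)
    d = G_star.d
    idx = rng.choice(G_star.m, size=n, p=G_star.weights)
    theta = G_star.support[idx]
    covs = np.asarray(covs, dtype=float)
    if cov_mode == "shared":
        Z = rng.multivariate_normal(np.zeros(d), covs, size=n)
    elif cov_mode == "diag":
        Z = rng.standard_normal((n, d)) * np.sqrt(covs)
    elif cov_mode == "full":
        Z = np.empty((n, d))
        for i in range(n):
            Z[i] = rng.multivariate_normal(np.zeros(d), covs[i])
    else:
        raise InputError(f"unknown cov_mode {cov_mode!r}")
    data = MixtureData(Y=theta + Z, covs=covs, cov_mode=cov_mode)
    return data, theta
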