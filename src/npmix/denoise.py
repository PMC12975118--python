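"""Post-fit denoising: posterior means and optimal-transport projection.

Two denoisers are provided.  The posterior-mean estimator shrinks each
observation toward a likelihood-weighted average of the fitted atoms; its
outputs can land far from the fitted support.  The transport-based
estimator instead couples the empirical law of the observations with the
fitted mixing distribution through an exact Kantorovich linear program and
maps each observation to the barycenter of its coupled atoms, so outputs
concentrate on the fitted support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.optimize import linprog

from .likelihood import LikelihoodMatrix
from .types import MixingDistribution, MixtureData, ValidationError

__all__ = [
    "TransportPlan",
    "posterior_mean",
    "prune_support",
    "ot_plan",
    "barycentric_projection",
    "denoise",
]

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_THRESHOLD = 1e-6
MAX_OT_ATOMS = 5000


@dataclass
class TransportPlan:
    """Optimal coupling between the empirical law of Y and the fitted atoms."""

    pi: np.ndarray  # (n, k) nonnegative
    atoms: np.ndarray  # (k, d)
    atom_weights: np.ndarray  # (k,)
    cost: float  # squared-Wasserstein transport cost


def posterior_mean(
    data: MixtureData, Lmat: LikelihoodMatrix, G: MixingDistribution
) -> np.ndarray:
    """Posterior-mean denoiser: theta_hat_i = sum_j w_ij mu_j with
    w_ij proportional to L_ij x_j (row scaling cancels in the ratio)."""
    if G.m != Lmat.m:
        raise ValidationError(
            f"mixing distribution has {G.m} atoms but likelihood matrix "
            f"has {Lmat.m} columns; they must share the support grid"
        )
    W = Lmat.L * G.weights[None, :]
    row_sums = W.sum(axis=1)
    if np.any(row_sums <= 0):
        i = int(np.argmax(row_sums <= 0))
        raise ValidationError(
            f"observation {i} receives zero posterior mass; the support grid "
            "does not cover it"
        )
    return (W / row_sums[:, None]) @ G.support


def prune_support(G: MixingDistribution, threshold: float) -> MixingDistribution:
    """Drop atoms with weight <= threshold and renormalize."""
    if not (0 <= threshold < 1):
        raise ValidationError("threshold must lie in [0, 1)")
    keep = G.weights > threshold
    if not np.any(keep):
        raise ValidationError(
            f"threshold {threshold} prunes every atom; use a smaller threshold"
        )
    w = G.weights[keep]
    return MixingDistribution.from_arrays(G.support[keep], w / w.sum())


def ot_plan(data: MixtureData, G: MixingDistribution) -> TransportPlan:
    """Solve the discrete Kantorovich problem between the empirical law of
    the observations (mass 1/n each) and the fitted mixing distribution,
    with squared Euclidean cost, to exact LP optimality."""
    n, k = data.n, G.m
    if k > MAX_OT_ATOMS:
        raise ValidationError(
            f"{k} atoms exceeds the transport cap {MAX_OT_ATOMS}; prune first"
        )
    if abs(G.weights.sum() - 1.0) > 1e-8:
        raise ValidationError("atom weights must sum to 1 for transport")
    # squared distances ||Y_i - a_j||^2
    sq = (
        (data.Y**2).sum(axis=1)[:, None]
        - 2.0 * data.Y @ G.support.T
        + (G.support**2).sum(axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    c = sq.ravel()

    # marginal constraints: row sums 1/n, column sums alpha (last one
    # redundant and dropped for numerical rank)
    rows = scipy.sparse.kron(
        scipy.sparse.eye(n, format="csr"), np.ones((1, k)), format="csr"
    )
    cols = scipy.sparse.kron(
        np.ones((1, n)), scipy.sparse.eye(k, format="csr"), format="csr"
    )[:-1]
    A_eq = scipy.sparse.vstack([rows, cols], format="csc")
    b_eq = np.concatenate([np.full(n, 1.0 / n), G.weights[:-1]])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if res.status != 0:
        raise RuntimeError(f"transport LP failed: {res.message}")
    pi = res.x.reshape(n, k)
    cost = float((pi * sq).sum())
    nnz = int((pi > 0).sum())
    if nnz > n + k - 1:
        logger.info(
            "transport plan has %d nonzeros (> n + k - 1 = %d): degenerate ties",
            nnz, n + k - 1,
        )
    return TransportPlan(pi=pi, atoms=G.support, atom_weights=G.weights, cost=cost)


def barycentric_projection(plan: TransportPlan) -> np.ndarray:
    """Map each observation to the conditional mean atom under the plan:
    T(Y_i) = n * sum_j pi_ij a_j (each plan row carries mass 1/n)."""
    n = plan.pi.shape[0]
    return n * (plan.pi @ plan.atoms)


def denoise(
    data: MixtureData,
    Lmat: LikelihoodMatrix,
    G: MixingDistribution,
    method: str = "both",
) -> dict:
    """Dispatch to the posterior-mean and/or transport denoiser.

    Returns a dict with keys among {"eb", "ot", "ot_cost", "plan"}.
    """
    if method not in ("eb", "ot", "both"):
        raise ValidationError(f"unknown denoising method {method!r}")
    if data.cov_mode != "shared":
        logger.info(
            "transport denoising guarantee assumes a shared covariance; "
            "inputs are heteroscedastic"
        )
    out: dict = {}
    if method in ("eb", "both"):
        out["eb"] = posterior_mean(data, Lmat, G)
    if method in ("ot", "both"):
        plan = ot_plan(data, G)
        out["ot"] = barycentric_projection(plan)
        out["ot_cost"] = plan.cost
        out["plan"] = plan
    return out
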