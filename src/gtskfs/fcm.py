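"""Fuzzy C-Means clustering and rule-premise estimation.

FCM soft-partitions the training samples into K clusters; the graded
memberships u_jk then seed the antecedents of the K fuzzy rules: each
rule's per-dimension Gaussian center is the membership-weighted mean and
its width is h times the membership-weighted variance.  Membership weights
enter the premise estimate at first power (the clustering itself uses the
fuzzified u^m in its center updates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .antecedent import FuzzyRuleBase
from .cohort import FeatureMatrix
from .errors import DegenerateRuleError, InfeasibleError

#: Width floor keeping Gaussian memberships defined for zero-variance clusters.
WIDTH_FLOOR = 1e-6


@dataclass
class FcmResult:
    """Converged FCM state.

    membership : (N, K) matrix U; rows sum to 1.
    centers : (K, d) cluster centers V.
    m : fuzzifier (> 1).
    objective_trace : J = sum_jk u_jk^m ||x_j - v_k||^2 per iteration.
    n_iter : iterations actually run.
    seed : RNG seed the initial memberships were drawn with.
    """

    membership: np.ndarray
    centers: np.ndarray
    m: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    seed: int = 0


def fcm_fit(
    x: FeatureMatrix | np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Run FCM with Dirichlet-initialized memberships.

    Alternates the standard updates
    ``v_k = sum_j u_jk^m x_j / sum_j u_jk^m`` and
    ``u_jk = 1 / sum_l (||x_j - v_k|| / ||x_j - v_l||)^(2/(m-1))``
    until the max absolute membership change drops below ``tol``.
    Deterministic given ``seed``; a sample coincident with a center gets
    membership 1 on that center (split equally if several coincide).
    """
    X = x.X if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise InfeasibleError(f"need at least one cluster, got k={k}")
    if k > n:
        raise InfeasibleError(f"k={k} clusters infeasible with n={n} samples")
    if m <= 1:
        raise InfeasibleError(f"fuzzifier must be > 1, got m={m}")

    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)
    trace: list[float] = []
    exponent = 2.0 / (m - 1.0)
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        U_new = _membership_from_distances(d2, exponent)
        trace.append(float((U_new**m * d2).sum()))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            break
    return FcmResult(
        membership=U, centers=centers, m=m, objective_trace=trace, n_iter=it, seed=seed
    )


def _membership_from_distances(d2: np.ndarray, exponent: float) -> np.ndarray:
    """u_jk from squared distances, honoring the coincident-point rule."""
    coincident = d2 <= 0.0
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-exponent / 2.0)  # (1/d_jk)^(2/(m-1))
    U = np.where(np.isfinite(inv), inv, 0.0)
    hit = coincident.any(axis=1)
    U[hit] = coincident[hit].astype(float)
    return U / U.sum(axis=1, keepdims=True)


def premise_from_fcm(
    x: FeatureMatrix | np.ndarray, result: FcmResult, h: float = 2.0
) -> FuzzyRuleBase:
    """Estimate the Gaussian rule premises from FCM memberships.

    Per rule k and dimension i, with first-power membership weights:
    center ``c = sum_j u_jk x_ji / sum_j u_jk`` and width
    ``delta = h * sum_j u_jk (x_ji - c)^2 / sum_j u_jk`` (a scaled weighted
    variance), floored at ``WIDTH_FLOOR`` so degenerate zero-variance
    clusters keep well-defined memberships.
    """
    X = x.X if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    U = result.membership
    colsum = U.sum(axis=0)
    if np.any(colsum <= 0):
        empty = int(np.flatnonzero(colsum <= 0)[0])
        raise DegenerateRuleError(f"cluster {empty} has zero total membership")
    centers = (U.T @ X) / colsum[:, None]
    sq = (X[:, None, :] - centers[None, :, :]) ** 2  # (N, K, d)
    widths = h * np.einsum("jk,jki->ki", U, sq) / colsum[:, None]
    widths = np.maximum(widths, WIDTH_FLOOR)
    return FuzzyRuleBase(centers=centers, widths=widths, h=h)
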