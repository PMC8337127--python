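"""Closed-form consequent estimation (ridge and graph-regularized).

Because the TSK system is linear in the stacked consequent vector p_g, the
training objective

    E = ||y - X_g p_g||^2 + beta * (X_g p_g)^T L (X_g p_g) + lambda * ||p_g||^2

is a convex quadratic whose unique minimizer (for lambda > 0, or full-rank
X_g) satisfies the normal equations

    (X_g^T X_g + lambda I + beta X_g^T L X_g) p_g = X_g^T y.

I is the K(d+1) identity on consequent space; the ridge term shrinks the
per-rule bias coefficients too.  The SPD system is solved by Cholesky
factorization rather than explicit inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, lstsq

from .antecedent import MappedDesign
from .errors import RankDeficiencyError, ShapeError
from .graph import GraphPenalty


@dataclass(frozen=True)
class ObjectiveSpec:
    """Regularization coefficients: ridge ``lam`` and graph ``beta``."""

    lam: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.beta < 0:
            raise ValueError(
                f"regularization coefficients must be >= 0, got "
                f"lambda={self.lam}, beta={self.beta}"
            )


def _design(x_g: MappedDesign | np.ndarray) -> np.ndarray:
    return x_g.x_g if isinstance(x_g, MappedDesign) else np.asarray(x_g, dtype=float)


def solve_consequents(
    x_g: MappedDesign | np.ndarray,
    y: np.ndarray,
    graph: GraphPenalty | None = None,
    spec: ObjectiveSpec = ObjectiveSpec(),
) -> np.ndarray:
    """Minimize the (graph-)regularized least-squares objective for p_g."""
    X = _design(x_g)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if yv.size != n:
        raise ShapeError(f"target length {yv.size} != {n} design rows")
    if spec.beta > 0 and graph is None:
        raise ShapeError("beta > 0 requires a graph penalty")
    if graph is not None and graph.n != n:
        raise ShapeError(f"graph size {graph.n} != {n} design rows")

    if spec.lam == 0 and spec.beta == 0:
        # pure least squares: a QR solve avoids squaring the condition number
        sol, _, rank, _ = lstsq(X, yv)
        if rank < p:
            raise RankDeficiencyError(
                f"design has rank {rank} < {p}; set lambda > 0 to regularize"
            )
        return sol

    A = X.T @ X + spec.lam * np.eye(p)
    if spec.beta > 0 and graph is not None:
        A += spec.beta * X.T @ (graph.laplacian @ X)
    A = (A + A.T) / 2.0
    b = X.T @ yv
    try:
        return cho_solve(cho_factor(A), b)
    except LinAlgError as exc:
        if spec.lam == 0:
            raise RankDeficiencyError(
                "normal matrix is singular; set lambda > 0 to regularize"
            ) from exc
        raise


def objective_value(
    x_g: MappedDesign | np.ndarray,
    y: np.ndarray,
    graph: GraphPenalty | None,
    spec: ObjectiveSpec,
    p: np.ndarray,
) -> tuple[float, dict[str, float]]:
    """Objective E at a given consequent vector, with per-term diagnostics.

    Returns ``(E, terms)`` where terms holds the residual sum of squares,
    the graph penalty (already scaled by beta) and the ridge penalty
    (scaled by lambda).
    """
    X = _design(x_g)
    yv = np.asarray(y, dtype=float).ravel()
    pv = np.asarray(p, dtype=float).ravel()
    if pv.size != X.shape[1]:
        raise ShapeError(f"consequent length {pv.size} != {X.shape[1]} columns")
    if yv.size != X.shape[0]:
        raise ShapeError(f"target length {yv.size} != {X.shape[0]} rows")
    yhat = X @ pv
    rss = float(((yv - yhat) ** 2).sum())
    graph_term = 0.0
    if spec.beta > 0:
        if graph is None:
            raise ShapeError("beta > 0 requires a graph penalty")
        graph_term = spec.beta * float(yhat @ graph.laplacian @ yhat)
    ridge_term = spec.lam * float(pv @ pv)
    terms = {"rss": rss, "graph": graph_term, "ridge": ridge_term}
    return rss + graph_term + ridge_term, terms


def objective_gradient(
    x_g: MappedDesign | np.ndarray,
    y: np.ndarray,
    graph: GraphPenalty | None,
    spec: ObjectiveSpec,
    p: np.ndarray,
) -> np.ndarray:
    """Analytic gradient of the objective; zero at the returned solution."""
    X = _design(x_g)
    yv = np.asarray(y, dtype=float).ravel()
    pv = np.asarray(p, dtype=float).ravel()
    grad = -2.0 * X.T @ (yv - X @ pv) + 2.0 * spec.lam * pv
    if spec.beta > 0 and graph is not None:
        grad += 2.0 * spec.beta * X.T @ (graph.laplacian @ (X @ pv))
    return grad
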