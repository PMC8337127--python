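"""Sample-similarity graph and normalized Laplacian for the regularizer.

Patients with similar clinical profiles should receive similar predicted
Kt/V; the graph penalty encodes that as yhat^T L yhat with L the
symmetric-normalized Laplacian of a cosine-similarity affinity over the
(standardized) feature vectors.  Cosine similarity of standardized features
can be negative; negative entries are clipped to zero by default so the
affinity is valid and L is positive semidefinite (a (1+cos)/2 rescaling is
available instead).  Matrices are dense — cohorts here are a few hundred
patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FeatureMatrix
from .errors import GraphError


@dataclass
class GraphPenalty:
    """Similarity graph with its Laplacians.

    similarity : (N, N) symmetric affinity S with entries in [0, 1].
    degree : (N,) degrees D_ii = sum_j S_ij.
    laplacian_raw : Delta = D - S (row sums zero).
    laplacian : L = D^{-1/2} Delta D^{-1/2} (symmetric, PSD).
    """

    similarity: np.ndarray
    degree: np.ndarray
    laplacian_raw: np.ndarray
    laplacian: np.ndarray

    @property
    def n(self) -> int:
        return self.similarity.shape[0]


def cosine_similarity_matrix(
    x: FeatureMatrix | np.ndarray, mode: str = "clip"
) -> np.ndarray:
    """Pairwise cosine affinity of sample feature vectors.

    mode="clip" (default): S_ij = max(0, cos(x_i, x_j)); mode="shift":
    S_ij = (1 + cos(x_i, x_j)) / 2.  Either way S_ii = 1 and S is symmetric
    with entries in [0, 1].
    """
    X = x.X if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise GraphError(f"zero-norm feature vector at row {zero[0]}")
    cos = (X / norms[:, None]) @ (X / norms[:, None]).T
    cos = (cos + cos.T) / 2.0
    if mode == "clip":
        S = np.clip(cos, 0.0, 1.0)
    elif mode == "shift":
        S = np.clip((1.0 + cos) / 2.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown similarity mode: {mode!r}")
    np.fill_diagonal(S, 1.0)
    return S


def normalized_laplacian(s: np.ndarray) -> GraphPenalty:
    """Build Delta = D - S and L = D^{-1/2} Delta D^{-1/2} from an affinity."""
    S = np.asarray(s, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise GraphError(f"similarity must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-12):
        raise GraphError("similarity matrix is not symmetric")
    if np.any(S < 0):
        raise GraphError("similarity matrix has negative entries")
    degree = S.sum(axis=1)
    isolated = np.flatnonzero(degree <= 0)
    if isolated.size:
        raise GraphError(f"isolated node (zero degree) at row {isolated[0]}")
    delta = np.diag(degree) - S
    inv_sqrt = 1.0 / np.sqrt(degree)
    laplacian = delta * np.outer(inv_sqrt, inv_sqrt)
    laplacian = (laplacian + laplacian.T) / 2.0
    return GraphPenalty(
        similarity=S, degree=degree, laplacian_raw=delta, laplacian=laplacian
    )


def penalty_value(graph: GraphPenalty, yhat: np.ndarray) -> float:
    """Quadratic-form penalty yhat^T L yhat on a vector of predictions.

    Equals 0.5 * sum_ij S_ij (yhat_i / sqrt(D_ii) - yhat_j / sqrt(D_jj))^2.
    """
    v = np.asarray(yhat, dtype=float).ravel()
    if v.size != graph.n:
        raise GraphError(f"prediction length {v.size} != graph size {graph.n}")
    return float(v @ graph.laplacian @ v)
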