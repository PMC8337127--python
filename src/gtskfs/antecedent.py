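"""Gaussian rule antecedents, firing strengths and the fuzzy feature map.

A first-order TSK fuzzy system holds K rules; rule k fires on an input
x in R^d with strength

    mu^k(x) = prod_i exp(-(x_i - c_i^k)^2 / (2 delta_i^k)),

normalized across rules so the strengths sum to one.  Each rule's
consequent is affine, and the whole system is linear in the stacked
consequent coefficients once the inputs are pushed through the fuzzy-rule
feature map: row x becomes the K(d+1)-vector concatenating
mu_bar^k(x) * (1, x^T) over k.  Products are evaluated in log space with a
log-sum-exp normalization so high-dimensional inputs cannot underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .cohort import FeatureMatrix
from .errors import ShapeError

logger = logging.getLogger(__name__)


@dataclass
class FuzzyRuleBase:
    """Premises of the K rules: per-rule, per-dimension Gaussian parameters.

    centers : (K, d), on the (standardized) feature scale.
    widths : (K, d), strictly positive; these are h-scaled variances, so the
        membership exponent is (x - c)^2 / (2 * width) with no extra square.
    h : the width-scale hyperparameter the widths were built with.
    """

    centers: np.ndarray
    widths: np.ndarray
    h: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        if self.centers.shape != self.widths.shape:
            raise ShapeError(
                f"centers {self.centers.shape} vs widths {self.widths.shape}"
            )
        if np.any(self.widths <= 0):
            raise ShapeError("all rule widths must be strictly positive")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]


@dataclass
class MappedDesign:
    """Fuzzy-rule-mapped design matrix and the firing strengths behind it.

    x_g : (N, K(d+1)); row blocks ordered k = 1..K, each block
        mu_bar^k(x) * (1, x_1, ..., x_d) — bias first.
    firing : (N, K) normalized firing strengths; rows sum to 1.
    """

    x_g: np.ndarray
    firing: np.ndarray


def _as_rows(x: np.ndarray, d: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != d:
        raise ShapeError(f"expected vectors of dimension {d}, got shape {arr.shape}")
    return arr


def log_membership(rule_base: FuzzyRuleBase, x: np.ndarray) -> np.ndarray:
    """Per-rule log-memberships log mu^k(x); shape (N, K) (or (K,) for 1 row).

    The product over dimensions becomes a sum of negative quadratic terms;
    a point at a rule's center scores exactly 0 (membership 1).
    """
    arr = _as_rows(x, rule_base.d)
    diff = arr[:, None, :] - rule_base.centers[None, :, :]
    with np.errstate(over="ignore"):  # distant points may overflow to -inf
        out = -(diff**2 / (2.0 * rule_base.widths[None, :, :])).sum(axis=2)
    return out[0] if np.asarray(x).ndim == 1 else out


def membership(rule_base: FuzzyRuleBase, x: np.ndarray) -> np.ndarray:
    """Per-rule memberships mu^k(x) on the natural scale."""
    return np.exp(log_membership(rule_base, x))


def firing_strengths(rule_base: FuzzyRuleBase, x: np.ndarray) -> np.ndarray:
    """Normalized firing strengths mu_bar^k(x); each row sums to 1.

    Computed as a log-sum-exp softmax of the log-memberships.  If every
    rule's membership underflows to -inf for some row (possible only
    through the width floor on wildly out-of-range inputs), that row falls
    back to the uninformative uniform 1/K with a logged warning.
    """
    logmu = np.atleast_2d(log_membership(rule_base, x))
    norm = logsumexp(logmu, axis=1, keepdims=True)
    dead = ~np.isfinite(norm[:, 0])
    if dead.any():
        logger.warning(
            "all %d rule memberships underflowed for %d input row(s); "
            "falling back to uniform firing",
            rule_base.k,
            int(dead.sum()),
        )
    with np.errstate(invalid="ignore"):
        out = np.exp(logmu - norm)
    out[dead] = 1.0 / rule_base.k
    return out[0] if np.asarray(x).ndim == 1 else out


def map_features(rule_base: FuzzyRuleBase, x: FeatureMatrix | np.ndarray) -> MappedDesign:
    """Fuzzy-rule feature map x -> x_g.

    Row blocks are ordered k = 1..K; within a block the bias column comes
    first, then the d feature columns, each scaled by the rule's normalized
    firing strength.
    """
    arr = x.X if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    arr = _as_rows(arr, rule_base.d)
    mu_bar = np.atleast_2d(firing_strengths(rule_base, arr))
    ones = np.ones((arr.shape[0], 1))
    x_e = np.hstack([ones, arr])  # (N, d+1)
    blocks = mu_bar[:, :, None] * x_e[:, None, :]  # (N, K, d+1)
    return MappedDesign(x_g=blocks.reshape(arr.shape[0], -1), firing=mu_bar)


def predict_output(mapped: MappedDesign | np.ndarray, p_g: np.ndarray) -> np.ndarray:
    """System output y = X_g p_g for stacked consequent coefficients p_g."""
    x_g = mapped.x_g if isinstance(mapped, MappedDesign) else np.asarray(mapped, dtype=float)
    p = np.asarray(p_g, dtype=float).ravel()
    if x_g.shape[1] != p.size:
        raise ShapeError(
            f"consequent length {p.size} does not match {x_g.shape[1]} mapped columns"
        )
    return x_g @ p
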