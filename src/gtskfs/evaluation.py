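"""Model evaluation: metrics, 10-fold CV, grid search, Bland-Altman.

The evaluation protocol scores pooled out-of-fold predictions from k-fold
cross-validation with RMSE, R-squared and adjusted R-squared (adjusted for
the number of raw input features).  Hyperparameters are chosen by a
two-stage grid search: stage 1 fixes beta = 2^0 and scans rule count K in
{1..10} against lambda in {2^-10..2^0}; stage 2 fixes the stage-1 winners
and scans beta over the same dyadic ladder.  Agreement between predicted
and clinically measured Kt/V is quantified with Bland-Altman limits of
agreement on pairwise percent differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from . import model as gtsk_model
from .cohort import FeatureMatrix, apply_scaler, standardize
from .errors import InfeasibleError, ShapeError
from .model import Hyperparams

logger = logging.getLogger(__name__)

#: Dyadic ladders of the hyperparameter search (2^-10 .. 2^0).
GRID_K = tuple(range(1, 11))
GRID_LAMBDA = tuple(2.0**e for e in range(-10, 1))
GRID_BETA = tuple(2.0**e for e in range(-10, 1))
STAGE1_BETA = 2.0**0


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error."""
    yv, pv = _paired(y, yhat)
    return float(np.sqrt(np.mean((yv - pv) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray, d_predictors: int) -> tuple[float, float]:
    """(R-squared, adjusted R-squared) of predictions against targets.

    adj R2 = 1 - (1 - R2)(n - 1)/(n - d - 1), with d the number of raw
    input features.
    """
    yv, pv = _paired(y, yhat)
    n = yv.size
    if n <= d_predictors + 1:
        raise InfeasibleError(
            f"adjusted R-squared needs n > d+1 (n={n}, d={d_predictors})"
        )
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    if ss_tot == 0:
        raise InfeasibleError("R-squared undefined for constant targets")
    r2 = 1.0 - float(((yv - pv) ** 2).sum()) / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - d_predictors - 1)
    return r2, adj


def _paired(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    yv = np.asarray(y, dtype=float).ravel()
    pv = np.asarray(yhat, dtype=float).ravel()
    if yv.size == 0 or yv.size != pv.size:
        raise ShapeError(f"paired vectors required, got {yv.size} and {pv.size}")
    return yv, pv


@dataclass
class EvalReport:
    """Cross-validation scores on pooled out-of-fold predictions."""

    rmse: float
    r_squared: float
    adj_r_squared: float
    per_fold_rmse: list[float]
    n: int
    d: int
    predictions: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "per_fold_rmse": self.per_fold_rmse,
            "n": self.n,
            "d": self.d,
        }


def cross_validate(
    data: FeatureMatrix,
    hp: Hyperparams,
    variant: str = "gtsk",
    folds: int = 10,
    seed: int = 0,
    scale_features: bool = True,
) -> EvalReport:
    """k-fold CV of the (G-)TSK model; every stage refit per fold.

    Fold assignment is a seeded shuffle.  The scaler, FCM clustering, rule
    premises, similarity graph and consequents are all re-estimated on each
    training split; the held-out rows are scored with the training-fold
    scaler, so no test information leaks into fitting.
    """
    return _run_cv(
        data,
        folds,
        seed,
        lambda tr: gtsk_model.fit(tr, hp=hp, variant=variant, scale_features=scale_features),
        lambda fitted, te: gtsk_model.predict(fitted, te),
        min_train=hp.k,
    )


def linear_baseline(data: FeatureMatrix, folds: int = 10, seed: int = 0) -> EvalReport:
    """Ordinary least squares on standardized features, same CV protocol.

    The textbook comparator: an affine model y = b0 + b^T x solved by
    lstsq, anchoring comparative reports.
    """

    def fit_ols(tr: FeatureMatrix):
        work = standardize(tr)
        design = np.hstack([np.ones((work.n, 1)), work.X])
        coef, *_ = np.linalg.lstsq(design, tr.y, rcond=None)
        return (coef, work.scaler_mean, work.scaler_scale)

    def predict_ols(fitted, te: FeatureMatrix):
        coef, mean, scale = fitted
        scaled = apply_scaler(te, mean, scale)
        return np.hstack([np.ones((te.n, 1)), scaled.X]) @ coef

    return _run_cv(data, folds, seed, fit_ols, predict_ols, min_train=1)


def _run_cv(data, folds, seed, fit_fn, predict_fn, min_train) -> EvalReport:
    if data.y is None:
        raise ShapeError("cross-validation requires targets")
    if not 2 <= folds <= data.n:
        raise InfeasibleError(f"folds={folds} infeasible for n={data.n}")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(data.n, np.nan)
    per_fold = []
    for train_idx, test_idx in splitter.split(data.X):
        if train_idx.size < min_train:
            raise InfeasibleError(
                f"training fold of {train_idx.size} rows cannot support the model"
            )
        fitted = fit_fn(data.subset(train_idx))
        pred = predict_fn(fitted, data.subset(test_idx))
        oof[test_idx] = pred
        per_fold.append(rmse(data.y[test_idx], pred))
    r2, adj = r_squared(data.y, oof, d_predictors=data.d)
    return EvalReport(
        rmse=rmse(data.y, oof),
        r_squared=r2,
        adj_r_squared=adj,
        per_fold_rmse=per_fold,
        n=data.n,
        d=data.d,
        predictions=oof,
    )


@dataclass
class GridSearchResult:
    """Two-stage hyperparameter search outcome."""

    best_k: int
    best_lambda: float
    best_beta: float
    best_rmse: float
    stage1_rmse: np.ndarray  # (len(GRID_K), len(GRID_LAMBDA))
    stage2_rmse: np.ndarray  # (len(GRID_BETA),)
    stage1_cells: int
    stage2_cells: int
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_k": self.best_k,
            "best_lambda": self.best_lambda,
            "best_beta": self.best_beta,
            "best_rmse": self.best_rmse,
            "stage1_rmse": self.stage1_rmse.tolist(),
            "stage2_rmse": self.stage2_rmse.tolist(),
            "stage1_cells": self.stage1_cells,
            "stage2_cells": self.stage2_cells,
            "errors": self.errors,
        }


def grid_search(
    data: FeatureMatrix,
    seed: int = 0,
    folds: int = 10,
    k_grid: tuple[int, ...] = GRID_K,
    lambda_grid: tuple[float, ...] = GRID_LAMBDA,
    beta_grid: tuple[float, ...] = GRID_BETA,
    h: float = 2.0,
    m: float = 2.0,
) -> GridSearchResult:
    """Two-stage grid search by CV-RMSE.

    Stage 1 fixes beta = 2^0 and scans every (K, lambda) cell; stage 2
    fixes the stage-1 winners and scans beta.  Ties break toward the more
    parsimonious model: smaller K, then larger lambda, then larger beta.
    A cell whose CV fails is recorded and skipped.
    """
    stage1 = np.full((len(k_grid), len(lambda_grid)), np.nan)
    errors: list[str] = []
    for i, k in enumerate(k_grid):
        for j, lam in enumerate(lambda_grid):
            hp = Hyperparams(k=k, lam=lam, beta=STAGE1_BETA, h=h, m=m, seed=seed)
            try:
                stage1[i, j] = cross_validate(data, hp, folds=folds, seed=seed).rmse
            except Exception as exc:  # cell marked invalid, search continues
                errors.append(f"stage1 K={k} lambda={lam}: {exc}")
    if np.all(np.isnan(stage1)):
        raise InfeasibleError("every stage-1 grid cell failed")
    # min with ties toward smaller K then larger lambda
    best = min(
        (
            (stage1[i, j], k_grid[i], -lambda_grid[j], i, j)
            for i in range(len(k_grid))
            for j in range(len(lambda_grid))
            if np.isfinite(stage1[i, j])
        )
    )
    best_k, best_lam = best[1], -best[2]

    stage2 = np.full(len(beta_grid), np.nan)
    for j, beta in enumerate(beta_grid):
        hp = Hyperparams(k=best_k, lam=best_lam, beta=beta, h=h, m=m, seed=seed)
        try:
            stage2[j] = cross_validate(data, hp, folds=folds, seed=seed).rmse
        except Exception as exc:
            errors.append(f"stage2 beta={beta}: {exc}")
    if np.all(np.isnan(stage2)):
        raise InfeasibleError("every stage-2 grid cell failed")
    best2 = min(
        (stage2[j], -beta_grid[j], j)
        for j in range(len(beta_grid))
        if np.isfinite(stage2[j])
    )
    best_beta = -best2[1]
    if errors:
        logger.warning("grid search skipped %d failing cells", len(errors))
    return GridSearchResult(
        best_k=best_k,
        best_lambda=best_lam,
        best_beta=best_beta,
        best_rmse=float(best2[0]),
        stage1_rmse=stage1,
        stage2_rmse=stage2,
        stage1_cells=int(np.isfinite(stage1).sum()) + len([e for e in errors if e.startswith("stage1")]),
        stage2_cells=int(np.isfinite(stage2).sum()) + len([e for e in errors if e.startswith("stage2")]),
        errors=errors,
    )


@dataclass
class BlandAltmanReport:
    """Bland-Altman limits of agreement on percent differences.

    Differences are d_i = 100 (yhat_i - y_i) / ((yhat_i + y_i)/2), the
    ratio-style Bland-Altman convention; limits are mean +/- 1.96 SD
    (n-1 denominator).
    """

    mean_diff_pct: float
    sd_diff_pct: float
    lower_limit: float
    upper_limit: float
    n_outside: int
    n_total: int

    def to_dict(self) -> dict:
        return {
            "mean_diff_pct": self.mean_diff_pct,
            "sd_diff_pct": self.sd_diff_pct,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
            "n_outside": self.n_outside,
            "n_total": self.n_total,
        }


def bland_altman(y: np.ndarray, yhat: np.ndarray) -> BlandAltmanReport:
    """Agreement between predicted and measured values."""
    yv, pv = _paired(y, yhat)
    pair_mean = (yv + pv) / 2.0
    if np.any(pair_mean == 0):
        row = int(np.flatnonzero(pair_mean == 0)[0])
        raise InfeasibleError(f"pair at row {row} averages to 0; percent difference undefined")
    diff = 100.0 * (pv - yv) / pair_mean
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(((diff < lower) | (diff > upper)).sum())
    return BlandAltmanReport(
        mean_diff_pct=mean,
        sd_diff_pct=sd,
        lower_limit=lower,
        upper_limit=upper,
        n_outside=outside,
        n_total=int(diff.size),
    )
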