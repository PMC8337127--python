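"""Metrics, cross-validation, grid search and Bland-Altman agreement."""

import numpy as np
import pytest

from gtskfs import (
    FeatureMatrix,
    Hyperparams,
    bland_altman,
    cross_validate,
    fit,
    grid_search,
    linear_baseline,
    predict,
    r_squared,
    rmse,
)
from gtskfs.cohort import apply_scaler, standardize
from gtskfs.errors import InfeasibleError, ShapeError
from gtskfs.synthetic import TskOracleSpec, generate_tsk_oracle


def test_rmse_values():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(1 / 3))
    y = np.array([0.3, -1.2, 2.0])
    yhat = np.array([0.1, 0.2, 1.5])
    assert rmse(3 * y, 3 * yhat) == pytest.approx(3 * rmse(y, yhat))


def test_rmse_shape_error():
    with pytest.raises(ShapeError):
        rmse([1, 2], [1])


def test_r_squared_values():
    assert r_squared([1, 2, 3, 4], [1, 2, 3, 4], 1) == (1.0, 1.0)
    r2, _ = r_squared([1.0, 2, 3, 4], [2.5, 2.5, 2.5, 2.5], 1)
    assert r2 == pytest.approx(0.0)
    y = np.array([1.0, 2, 3, 4])
    yhat = np.array([1.1, 1.9, 3.2, 3.8])
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2, adj = r_squared(y, yhat, 1)
    assert r2 == pytest.approx(1 - ss_res / ss_tot)
    assert adj == pytest.approx(1 - (1 - r2) * 3 / 2)
    assert adj <= r2


def test_r_squared_degenerate_targets():
    with pytest.raises(InfeasibleError):
        r_squared([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 2.0], 1)


def test_cv_noiseless_affine_is_exact(affine_matrix):
    hp = Hyperparams(k=1, lam=0.0, beta=0.0, seed=0)
    report = cross_validate(affine_matrix, hp, variant="tsk", folds=10, seed=0)
    assert report.rmse < 1e-6
    assert len(report.per_fold_rmse) == 10


def test_cv_deterministic(affine_matrix):
    hp = Hyperparams(k=2, lam=0.01, beta=0.01, seed=3)
    a = cross_validate(affine_matrix, hp, folds=5, seed=3)
    b = cross_validate(affine_matrix, hp, folds=5, seed=3)
    assert a.rmse == b.rmse and a.per_fold_rmse == b.per_fold_rmse


def test_cv_folds_equal_n_is_leave_one_out(rng):
    X = rng.normal(0, 1, size=(12, 2))
    y = 0.5 + X @ [1.0, -0.5] + rng.normal(0, 0.05, 12)
    data = FeatureMatrix(X=X, columns=["a", "b"], y=y)
    hp = Hyperparams(k=1, lam=1e-6, beta=0.0, seed=0)
    report = cross_validate(data, hp, variant="tsk", folds=12, seed=0)
    # manual leave-one-out: fit on all rows but i, predict row i
    manual = np.empty(12)
    for i in range(12):
        rest = np.setdiff1d(np.arange(12), [i])
        m = fit(data.subset(rest), hp, variant="tsk")
        manual[i] = predict(m, data.subset(np.array([i])))[0]
    np.testing.assert_allclose(report.predictions, manual, atol=1e-10)


def test_cv_infeasible_folds(affine_matrix):
    with pytest.raises(InfeasibleError):
        cross_validate(affine_matrix, Hyperparams(k=1, seed=0), folds=1, seed=0)


def test_grid_search_best_is_minimum_and_ties_prefer_parsimony(rng):
    data, _ = generate_tsk_oracle(TskOracleSpec(k_true=1, d=2, n=40, noise_sd=0.1, seed=2))
    res = grid_search(
        data,
        seed=2,
        folds=5,
        k_grid=(1, 2, 3),
        lambda_grid=(2.0**-6, 2.0**-3, 1.0),
        beta_grid=(2.0**-4, 2.0**-2, 1.0),
    )
    assert res.stage1_cells == 9 and res.stage2_cells == 3
    finite = res.stage1_rmse[np.isfinite(res.stage1_rmse)]
    best_idx = np.unravel_index(np.nanargmin(res.stage1_rmse), res.stage1_rmse.shape)
    assert res.stage1_rmse[best_idx] == finite.min()
    assert res.best_rmse == np.nanmin(res.stage2_rmse)


def test_grid_search_single_rule_data_prefers_small_k():
    """Affine-plus-noise data should not reward many rules."""
    picks = []
    for seed in range(3):
        data, _ = generate_tsk_oracle(
            TskOracleSpec(k_true=1, d=2, n=40, noise_sd=0.1, seed=seed)
        )
        res = grid_search(
            data,
            seed=seed,
            folds=5,
            k_grid=(1, 2, 3, 4, 5, 6),
            lambda_grid=(2.0**-8, 2.0**-4, 1.0),
            beta_grid=(2.0**-5, 1.0),
        )
        picks.append(res.best_k)
    assert all(k <= 3 for k in picks)


def test_bland_altman_identical_inputs():
    rep = bland_altman([1.0, 1.2, 1.5], [1.0, 1.2, 1.5])
    assert (rep.mean_diff_pct, rep.sd_diff_pct, rep.n_outside) == (0.0, 0.0, 0)
    assert rep.lower_limit == rep.upper_limit == 0.0


def test_bland_altman_constant_ratio():
    y = np.array([1.0, 1.3, 1.6, 2.0])
    rep = bland_altman(y, 1.10 * y)
    assert rep.mean_diff_pct == pytest.approx(100 * 0.10 / 1.05)
    assert rep.sd_diff_pct == pytest.approx(0.0, abs=1e-12)


def test_bland_altman_zero_pair_mean_rejected():
    with pytest.raises(InfeasibleError):
        bland_altman([1.0, -1.0], [1.0, 1.0])


def test_bland_altman_gaussian_coverage(rng):
    n = 10_000
    diffs = rng.normal(0, 5, n)  # target percent differences
    y = np.full(n, 100.0)
    yhat = y * (200.0 + diffs) / (200.0 - diffs)  # inverts the percent formula
    rep = bland_altman(y, yhat)
    assert 0.04 <= rep.n_outside / rep.n_total <= 0.06


def test_linear_baseline_equals_single_rule_tsk(rng):
    X = rng.normal(0, 1, size=(50, 3))
    y = 0.2 + X @ [1.0, 0.5, -0.3] + rng.normal(0, 0.2, 50)
    data = FeatureMatrix(X=X, columns=["a", "b", "c"], y=y)
    lr = linear_baseline(data, folds=5, seed=1)
    tsk = cross_validate(
        data, Hyperparams(k=1, lam=0.0, beta=0.0, seed=1), variant="tsk",
        folds=5, seed=1,
    )
    np.testing.assert_allclose(lr.predictions, tsk.predictions, atol=1e-8)


def test_linear_baseline_exact_on_affine_data(affine_matrix):
    assert linear_baseline(affine_matrix, folds=5, seed=0).rmse < 1e-8


def test_linear_baseline_matches_simple_regression_formulas(rng):
    x = rng.normal(0, 2, size=30)
    y = 1.5 + 0.8 * x + rng.normal(0, 0.3, 30)
    data = FeatureMatrix(X=x[:, None], columns=["x"], y=y)
    work = standardize(data)
    slope = np.cov(work.X[:, 0], y, ddof=1)[0, 1] / np.var(work.X[:, 0], ddof=1)
    intercept = y.mean() - slope * work.X[:, 0].mean()
    design = np.hstack([np.ones((30, 1)), work.X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    assert coef[0] == pytest.approx(intercept)
    assert coef[1] == pytest.approx(slope)
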