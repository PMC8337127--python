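"""End-to-end fit/predict pipeline and model serialization."""

import numpy as np
import pytest

from gtskfs import (
    FeatureMatrix,
    Hyperparams,
    fit,
    generate_tsk_oracle,
    load_model,
    predict,
    sample_from_model,
    save_model,
)
from gtskfs.errors import FormatError, InfeasibleError, SchemaError
from gtskfs.evaluation import rmse
from gtskfs.synthetic import TskOracleSpec


def cohort_like(rng, n=60, d=4):
    X = rng.normal(0, 1, size=(n, d))
    y = 1.2 + 0.3 * np.tanh(X[:, 0]) + 0.1 * X[:, 1] + rng.normal(0, 0.1, n)
    return FeatureMatrix(X=X, columns=[f"x{i}" for i in range(d)], y=y)


def test_tsk_variant_equals_gtsk_with_zero_beta(rng):
    data = cohort_like(rng)
    hp = Hyperparams(k=3, lam=0.01, beta=0.0, seed=4)
    a = fit(data, hp, variant="tsk")
    b = fit(data, hp, variant="gtsk")
    np.testing.assert_allclose(a.p_g, b.p_g, atol=1e-10)


def test_single_rule_recovers_affine_truth(affine_matrix):
    hp = Hyperparams(k=1, lam=0.0, beta=0.0, seed=0)
    m = fit(affine_matrix, hp, variant="tsk")
    assert m.diagnostics["train_rmse"] < 1e-8


def test_fit_is_deterministic(rng):
    data = cohort_like(rng)
    hp = Hyperparams(k=2, seed=9)
    a = fit(data, hp)
    b = fit(data, hp)
    assert np.array_equal(a.p_g, b.p_g)


def test_row_permutation_leaves_predictions_stable(two_cloud_data, rng):
    """On well-separated data FCM lands in the same basin after a row shuffle;
    predictions agree to high precision (rule labels may swap)."""
    n = two_cloud_data.shape[0]
    y = two_cloud_data[:, 0] * 0.1 + 1.0 + rng.normal(0, 0.01, n)
    data = FeatureMatrix(X=two_cloud_data, columns=["a", "b"], y=y)
    perm = rng.permutation(n)
    shuffled = FeatureMatrix(X=two_cloud_data[perm], columns=["a", "b"], y=y[perm])
    hp = Hyperparams(k=2, lam=0.01, beta=0.0, seed=5)
    probe = FeatureMatrix(X=rng.normal(0, 5, size=(10, 2)), columns=["a", "b"])
    pred_a = predict(fit(data, hp), probe)
    pred_b = predict(fit(shuffled, hp), probe)
    np.testing.assert_allclose(pred_a, pred_b, atol=1e-6)


def test_predict_matches_training_diagnostics(rng):
    data = cohort_like(rng)
    m = fit(data, Hyperparams(k=2, seed=1))
    yhat = predict(m, data)
    assert rmse(data.y, yhat) == pytest.approx(m.diagnostics["train_rmse"], abs=1e-12)


def test_single_row_equals_batch_row(rng):
    data = cohort_like(rng)
    m = fit(data, Hyperparams(k=2, seed=1))
    batch = predict(m, data)
    one = predict(m, data.subset(np.array([7])))
    assert one[0] == pytest.approx(batch[7], abs=1e-12)


def test_predict_rejects_wrong_schema(rng):
    data = cohort_like(rng)
    m = fit(data, Hyperparams(k=2, seed=1))
    wrong = FeatureMatrix(X=data.X, columns=["w", "x", "y", "z"])
    with pytest.raises(SchemaError):
        predict(m, wrong)


def test_predict_reorders_columns(rng):
    data = cohort_like(rng)
    m = fit(data, Hyperparams(k=2, seed=1))
    rev = FeatureMatrix(X=data.X[:, ::-1], columns=list(data.columns[::-1]))
    np.testing.assert_allclose(predict(m, rev), predict(m, data), atol=1e-12)


def test_serialization_round_trip(tmp_path, rng):
    data = cohort_like(rng)
    m = fit(data, Hyperparams(k=3, seed=2))
    path = tmp_path / "model.json"
    save_model(m, path)
    loaded = load_model(path)
    assert np.array_equal(loaded.p_g, m.p_g)
    assert np.array_equal(loaded.rule_base.centers, m.rule_base.centers)
    assert loaded.hyperparams == m.hyperparams
    np.testing.assert_allclose(predict(loaded, data), predict(m, data), atol=1e-12)


@pytest.mark.parametrize("content", ["", "not json {", '{"schema": "other/9"}'])
def test_corrupt_model_files_rejected(tmp_path, content):
    path = tmp_path / "bad.json"
    path.write_text(content)
    with pytest.raises(FormatError):
        load_model(path)


def test_fit_requires_targets_and_enough_rows(rng):
    data = cohort_like(rng, n=3)
    with pytest.raises(InfeasibleError):
        fit(data, Hyperparams(k=5, seed=0))
    no_targets = FeatureMatrix(X=data.X, columns=data.columns)
    with pytest.raises(SchemaError):
        fit(no_targets, Hyperparams(k=1, seed=0))


def test_recovery_gap_shrinks_with_sample_size():
    """Held-out RMSE approaches the generative noise SD as N grows."""
    sigma = 0.05
    gaps = []
    for n in (100, 400, 1600):
        data, truth = generate_tsk_oracle(
            TskOracleSpec(k_true=2, d=3, n=n, noise_sd=sigma, seed=21)
        )
        test = sample_from_model(truth, 800, noise_sd=sigma, seed=9021)
        m = fit(data, Hyperparams(k=2, lam=1e-8, beta=0.0, seed=21),
                variant="tsk", scale_features=False)
        gaps.append(rmse(test.y, predict(m, test)) - sigma)
    assert gaps[0] > gaps[-1]
    assert abs(gaps[-1]) < 0.01
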