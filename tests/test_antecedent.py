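"""Gaussian memberships, firing strengths and the fuzzy feature map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtskfs import (
    FuzzyRuleBase,
    firing_strengths,
    map_features,
    membership,
    predict_output,
)
from gtskfs.errors import ShapeError
from tests.conftest import random_rule_base


def test_membership_is_one_at_center():
    rb = FuzzyRuleBase(centers=[[1.0, -2.0]], widths=[[0.5, 1.5]])
    assert membership(rb, np.array([1.0, -2.0]))[0] == pytest.approx(1.0)


def test_membership_one_dim_value():
    rb = FuzzyRuleBase(centers=[[0.0]], widths=[[0.5]])
    assert membership(rb, np.array([1.0]))[0] == pytest.approx(np.exp(-1.0), abs=1e-14)


def test_membership_monotone_in_width():
    rb1 = FuzzyRuleBase(centers=[[0.0, 0.0]], widths=[[0.5, 0.5]])
    rb2 = FuzzyRuleBase(centers=[[0.0, 0.0]], widths=[[1.0, 1.0]])
    x = np.array([1.0, 2.0])
    assert membership(rb2, x)[0] > membership(rb1, x)[0]


def test_membership_dimension_mismatch():
    rb = FuzzyRuleBase(centers=[[0.0, 0.0]], widths=[[1.0, 1.0]])
    with pytest.raises(ShapeError):
        membership(rb, np.array([1.0, 2.0, 3.0]))


def test_firing_single_rule_is_exactly_one():
    rb = FuzzyRuleBase(centers=[[0.0]], widths=[[1.0]])
    assert firing_strengths(rb, np.array([3.0]))[0] == 1.0


def test_firing_identical_rules_split_evenly():
    rb = FuzzyRuleBase(centers=[[1.0], [1.0]], widths=[[0.7], [0.7]])
    np.testing.assert_allclose(firing_strengths(rb, np.array([4.0])), [0.5, 0.5])


def test_firing_matches_naive_ratio(rng):
    rb = random_rule_base(rng, k=3, d=4)
    for _ in range(20):
        x = rng.normal(0, 1, size=4)
        mu = membership(rb, x)
        np.testing.assert_allclose(firing_strengths(rb, x), mu / mu.sum(), atol=1e-12)


def test_log_space_resolves_extreme_memberships():
    """Narrow rules far from the query do not underflow to 0/0: the nearer
    rule takes all the mass."""
    rb = FuzzyRuleBase(centers=[[0.0], [1.0]], widths=[[1e-6], [1e-6]])
    np.testing.assert_allclose(firing_strengths(rb, np.array([1e6])), [0.0, 1.0])


def test_firing_overflow_fallback_is_uniform():
    """When every rule's log-membership overflows to -inf the row falls
    back to uninformative uniform weights."""
    rb = FuzzyRuleBase(centers=[[0.0], [1.0]], widths=[[1e-6], [1e-6]])
    out = firing_strengths(rb, np.array([1e160]))
    np.testing.assert_allclose(out, [0.5, 0.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    k=st.integers(1, 6),
    d=st.integers(1, 20),
)
def test_firing_rows_always_sum_to_one(seed, k, d):
    rng = np.random.default_rng(seed)
    rb = random_rule_base(rng, k=k, d=d, width_lo=0.05, width_hi=3.0)
    x = rng.normal(0, 3, size=(5, d))
    total = firing_strengths(rb, x).sum(axis=1)
    np.testing.assert_allclose(total, 1.0, atol=1e-12)


def test_map_single_rule_is_affine_design():
    rb = FuzzyRuleBase(centers=[[0.0, 0.0]], widths=[[1.0, 1.0]])
    X = np.array([[2.0, -1.0], [0.5, 3.0]])
    mapped = map_features(rb, X)
    np.testing.assert_allclose(mapped.x_g, [[1, 2, -1], [1, 0.5, 3]])


def test_map_hand_example_two_rules():
    """d=1, K=2, firing (0.25, 0.75) at x=2 maps to (0.25, 0.5, 0.75, 1.5)."""
    # rule 2 sits at the point (mu2 = 1); rule 1 at distance d1 with
    # mu1 = exp(-d1^2/(2w)) = 1/3, so normalized firing is (1/4, 3/4)
    w = 1.0
    d1 = np.sqrt(2.0 * w * np.log(3.0))
    rb = FuzzyRuleBase(centers=[[2.0 - d1], [2.0]], widths=[[w], [w]])
    mapped = map_features(rb, np.array([[2.0]]))
    np.testing.assert_allclose(mapped.firing[0], [0.25, 0.75], atol=1e-12)
    np.testing.assert_allclose(mapped.x_g[0], [0.25, 0.5, 0.75, 1.5], atol=1e-12)


def test_map_bias_columns_sum_to_one(rng):
    rb = random_rule_base(rng, k=4, d=3)
    X = rng.normal(0, 1, size=(10, 3))
    mapped = map_features(rb, X)
    bias_cols = mapped.x_g[:, ::4]  # every (d+1)-th column is a bias column
    np.testing.assert_allclose(bias_cols.sum(axis=1), 1.0, atol=1e-12)


def test_predict_zero_consequents():
    rb = FuzzyRuleBase(centers=[[0.0]], widths=[[1.0]])
    mapped = map_features(rb, np.array([[1.0], [2.0]]))
    np.testing.assert_allclose(predict_output(mapped, np.zeros(2)), 0.0)


def test_predict_single_rule_is_affine(rng):
    rb = FuzzyRuleBase(centers=[[0.0, 0.0]], widths=[[1.0, 1.0]])
    X = rng.normal(0, 1, size=(8, 2))
    p = np.array([0.3, 1.5, -2.0])
    out = predict_output(map_features(rb, X), p)
    np.testing.assert_allclose(out, 0.3 + X @ p[1:], atol=1e-12)


def test_matrix_form_equals_rule_sum_form(rng):
    """y = X_g p_g equals sum_k mu_bar^k (p0^k + p^k . x) on random cases."""
    for _ in range(100):
        k, d = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        rb = random_rule_base(rng, k=k, d=d)
        x = rng.normal(0, 1, size=(1, d))
        p = rng.normal(0, 1, size=k * (d + 1))
        matrix_form = predict_output(map_features(rb, x), p)[0]
        mu = firing_strengths(rb, x)[0]
        blocks = p.reshape(k, d + 1)
        rule_sum = sum(
            mu[j] * (blocks[j, 0] + blocks[j, 1:] @ x[0]) for j in range(k)
        )
        assert matrix_form == pytest.approx(rule_sum, abs=1e-10)


def test_predict_length_mismatch():
    rb = FuzzyRuleBase(centers=[[0.0]], widths=[[1.0]])
    mapped = map_features(rb, np.array([[1.0]]))
    with pytest.raises(ShapeError):
        predict_output(mapped, np.zeros(5))
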