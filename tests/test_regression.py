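"""Weighted MLR, PLS and the metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bigsol.errors import ConfigurationError, SingularDesignError, ValidationError
from bigsol.regression import (
    MetricsReport, evaluate, pls_fit, select_pls_components, weighted_mlr,
)


def _toy(seed=0, n=120, p=4, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.5 + X @ beta + noise * rng.normal(size=n)
    sd = rng.uniform(0.05, 0.7, n)
    return X, y, sd


def test_exact_line_recovered_with_equal_weights():
    x = np.arange(10.0)
    X = np.column_stack([np.ones(10), x])
    fit = weighted_mlr(X, 2 + 3 * x, np.full(10, 0.3))
    assert fit.coefficients == pytest.approx([2.0, 3.0], abs=1e-10)


def test_two_point_weighted_mean_follows_precise_observation():
    # same x observed twice with very different SDs: the fit sits at the
    # inverse-variance weighted mean, essentially on the precise point
    X = np.ones((3, 1))
    y = np.array([0.0, 1.0, 0.0])
    sd = np.array([0.1, 10.0, 0.1])
    fit = weighted_mlr(X, y, sd)
    w = 1 / np.maximum(sd, 0.05) ** 2
    assert fit.coefficients[0] == pytest.approx(np.average(y, weights=w), abs=1e-12)
    assert abs(fit.coefficients[0] - 0.0) < 0.02


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=5))
def test_equal_sd_matches_normal_equations_oracle(seed, p):
    """With all SDs equal, weighted MLR equals the explicit normal-equations
    solution (X'X)^-1 X'y."""
    rng = np.random.default_rng(seed)
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = rng.normal(size=n)
    fit = weighted_mlr(X, y, np.full(n, 0.4))
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coefficients, oracle, atol=1e-9)


def test_rank_deficient_design_names_dependent_columns():
    X, y, sd = _toy()
    X_dup = np.column_stack([np.ones(len(y)), X, X[:, 0]])
    with pytest.raises(SingularDesignError, match="rank-deficient"):
        weighted_mlr(X_dup, y, sd)


def test_more_parameters_than_rows_rejected():
    with pytest.raises(ValidationError, match="more observations"):
        weighted_mlr(np.ones((3, 3)), np.zeros(3), None)


def test_pls_full_components_equals_weighted_mlr():
    X, y, sd = _toy(seed=3, p=5)
    wls = weighted_mlr(np.column_stack([np.ones(len(y)), X]), y, sd)
    pls = pls_fit(X, y, sd, n_components=5)
    assert np.allclose(pls.coefficients, wls.coefficients, atol=1e-8)


def test_pls_tolerates_duplicated_column():
    X, y, sd = _toy(seed=4, p=3)
    X_dup = np.column_stack([X, X[:, 0]])
    pls = pls_fit(X_dup, y, sd, n_components=4)
    assert np.all(np.isfinite(pls.coefficients))


def test_pls_single_component_fits_rank_one_response():
    rng = np.random.default_rng(7)
    raw = rng.normal(size=(60, 4))
    Xc, _ = np.linalg.qr(raw - raw.mean(axis=0))  # orthogonal zero-mean columns
    y = 3.0 * Xc[:, 0]
    pls = pls_fit(Xc, y, None, n_components=1)
    pred = pls.coefficients[0] + Xc @ pls.coefficients[1:]
    assert evaluate(y, pred).r2 == pytest.approx(1.0, abs=1e-10)


def test_pls_component_count_validation():
    X, y, sd = _toy(p=3)
    with pytest.raises(ConfigurationError):
        pls_fit(X, y, sd, n_components=7)


def test_component_selection_is_deterministic():
    X, y, sd = _toy(seed=9, p=5)
    k1 = select_pls_components(X, y, sd, seed=11)
    k2 = select_pls_components(X, y, sd, seed=11)
    assert k1 == k2 and 1 <= k1 <= 5


def test_evaluate_identity_prediction():
    obs = np.array([-3.0, -4.5, -2.2])
    rep = evaluate(obs, obs)
    assert rep.rmse == 0 and rep.mpp == 100 and rep.r2 == 1 and rep.bias == 0


def test_evaluate_mpp_threshold_count():
    rep = evaluate(np.zeros(4), np.array([0.4, 0.6, 0.6, 0.6]))
    assert rep.mpp == 25.0


def test_evaluate_r2_floored_at_zero():
    obs = np.array([0.0, 1.0, 2.0])
    rep = evaluate(obs, obs[::-1] + 5)
    assert rep.r2 == 0.0


def test_evaluate_invariant_under_joint_permutation():
    rng = np.random.default_rng(1)
    obs, pred = rng.normal(size=20), rng.normal(size=20)
    perm = rng.permutation(20)
    a, b = evaluate(obs, pred), evaluate(obs[perm], pred[perm])
    for fname in ("rmse", "r2", "bias", "sd", "mpp"):
        assert getattr(a, fname) == pytest.approx(getattr(b, fname), abs=1e-12)


def test_evaluate_length_mismatch():
    with pytest.raises(ValidationError):
        evaluate(np.zeros(3), np.zeros(4))


@settings(deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_rmse_dominates_bias(seed):
    rng = np.random.default_rng(seed)
    rep = evaluate(rng.normal(size=15), rng.normal(size=15))
    assert rep.rmse >= abs(rep.bias) - 1e-12
    assert 0 <= rep.mpp <= 100 and 0 <= rep.r2 <= 1


def test_metrics_report_serialization(tmp_path):
    rep = evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.1, 2.2, 2.7]), n_params=1)
    path = tmp_path / "report.json"
    rep.to_json(path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded["n"] == 3 and isinstance(loaded["mpp"], int)
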