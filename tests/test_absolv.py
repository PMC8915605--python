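"""Abraham solvation model, exponent scan and rotatable-bond correction."""

import numpy as np
import pytest

from bigsol import (
    ABSOLV_2020,
    AbrahamDescriptors,
    AbsolvCoefficients,
    NrotCorrection,
    CompoundRecord,
    apply_nrot_correction,
    fit_absolv,
    fit_nrot_correction,
    predict_absolv,
    z_scan,
)
from bigsol.errors import ConfigurationError, SingularDesignError, ValidationError
from bigsol.simulate import GeneratorConfig, generate_bz_set, generate_small_set


def test_preset_reproduces_reference_predictions(big31, reference):
    """The packaged coefficient preset reproduces every reference ABSOLV
    prediction to <= 0.05 log (over-determined inversion cross-check)."""
    pred = np.array([predict_absolv(r.abraham, ABSOLV_2020) for r, _ in big31])
    assert np.max(np.abs(pred - reference["absolv"].to_numpy())) <= 0.05


def test_cyclosporine_prediction(big31):
    rec = next(r for r, _ in big31 if r.id == "cyclosporine-a")
    assert predict_absolv(rec.abraham, ABSOLV_2020) == pytest.approx(-7.12, abs=0.05)


def test_intercept_only_coefficients():
    desc = AbrahamDescriptors(A=0, B=0, S_pi=0, E=0, V=2.0)
    coeffs = AbsolvCoefficients(c0=-1.5, c_A=1, c_B=1, c_S=1, c_E=1, c_V=0, c_AB=1)
    assert predict_absolv(desc, coeffs) == pytest.approx(-1.5)


def test_missing_descriptor_named():
    desc = AbrahamDescriptors(A=1, B=float("nan"), S_pi=1, E=1, V=1)
    with pytest.raises(ValidationError, match="'B'"):
        predict_absolv(desc, ABSOLV_2020)


def test_linearity_superposition():
    """Without the nonlinear term the model is linear in each descriptor."""
    c = ABSOLV_2020
    d1 = AbrahamDescriptors(A=1.0, B=2.0, S_pi=3.0, E=1.0, V=4.0)
    d2 = AbrahamDescriptors(A=0.5, B=1.0, S_pi=0.5, E=2.0, V=1.0)
    dsum = AbrahamDescriptors(A=1.5, B=3.0, S_pi=3.5, E=3.0, V=5.0)
    lhs = predict_absolv(dsum, c) - c.c_AB * dsum.AB
    rhs = (predict_absolv(d1, c) - c.c_AB * d1.AB) + (predict_absolv(d2, c) - c.c_AB * d2.AB) - c.c0
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_bz_term_pairing_enforced():
    with pytest.raises(ValidationError):
        AbsolvCoefficients(c0=0, c_A=0, c_B=0, c_S=0, c_E=0, c_V=0, c_AB=0, c_Bz=1.0)


def test_fit_recovers_noiseless_generating_coefficients():
    pairs = generate_small_set(GeneratorConfig(n_compounds=200, seed=2, model="absolv", noise_sd=0.0))
    coeffs, _, metrics = fit_absolv(pairs)
    assert np.allclose(coeffs.as_array(), ABSOLV_2020.as_array(), atol=1e-8)
    assert metrics.rmse < 1e-8


def test_fit_recovers_noisy_coefficients_within_ci():
    pairs = generate_small_set(GeneratorConfig(n_compounds=2000, seed=6, model="absolv", noise_sd=0.5))
    _, fit, _ = fit_absolv(pairs)
    z = (fit.coefficients - ABSOLV_2020.as_array()) / fit.standard_errors
    assert np.all(np.abs(z) < 3.5)


def test_degenerate_acidity_column_flagged():
    pairs = generate_small_set(GeneratorConfig(n_compounds=100, seed=2, model="absolv", noise_sd=0.1))
    zeroed = [
        (CompoundRecord(
            id=r.id, mw=r.mw, mp=r.mp, clogp=r.clogp,
            abraham=AbrahamDescriptors(A=0.0, B=r.abraham.B, S_pi=r.abraham.S_pi,
                                       E=r.abraham.E, V=r.abraham.V)), e)
        for r, e in pairs
    ]
    with pytest.raises(SingularDesignError, match="c_A"):
        fit_absolv(zeroed)


def test_fit_minimum_size(big31):
    with pytest.raises(ValidationError, match=">= 9"):
        fit_absolv(big31[:5])


def test_z_scan_noiseless_hits_grid_point_exactly():
    pairs = generate_bz_set(GeneratorConfig(
        n_compounds=300, seed=2, model="absolv_bz", noise_sd=0.0, z_true=1.11))
    z_best, table = z_scan(pairs, seed=0)
    assert z_best == 1.11
    assert len(table) == 111
    # the RMSE curve at the generating z is within one grid step of the minimum
    at_true = table.loc[np.isclose(table.z, 1.11), "rmse"].iloc[0]
    assert at_true <= table.rmse.min() + 1e-10


def test_z_scan_empty_grid():
    pairs = generate_bz_set(GeneratorConfig(
        n_compounds=50, seed=2, model="absolv_bz", noise_sd=0.1, z_true=1.2))
    with pytest.raises(ConfigurationError, match="empty"):
        z_scan(pairs, np.array([]))


def test_nrot_three_point_line():
    recs = [CompoundRecord(id=str(i), mw=900, nrot=n) for i, n in enumerate([0, 10, 20])]
    corr, _, _ = fit_nrot_correction(recs, np.array([1.0, 2.0, 3.0]), np.zeros(3))
    assert corr.slope == pytest.approx(0.1, abs=1e-12)
    assert corr.intercept == pytest.approx(1.0, abs=1e-12)
    assert corr.apply(-5.0, 10) == pytest.approx(-3.0)


def test_nrot_zero_residuals_give_flat_zero_line():
    recs = [CompoundRecord(id=str(i), mw=900, nrot=n) for i, n in enumerate([1, 5, 9, 13])]
    obs = np.array([-3.0, -4.0, -5.0, -6.0])
    corr, _, _ = fit_nrot_correction(recs, obs, obs.copy())
    assert corr.slope == pytest.approx(0.0, abs=1e-12)
    assert corr.intercept == pytest.approx(0.0, abs=1e-12)


def test_nrot_constant_counts_singular():
    recs = [CompoundRecord(id=str(i), mw=900, nrot=5) for i in range(4)]
    with pytest.raises(SingularDesignError):
        fit_nrot_correction(recs, np.zeros(4), np.ones(4))


def test_nrot_correction_improves_fixture_predictions(big31, reference):
    """On the big-molecule fixture, the rotatable-bond correction removes the
    systematic underprediction: |bias| < 0.2 and RMSE drops."""
    from bigsol.regression import evaluate

    records = [r for r, _ in big31]
    obs = reference["obs"].to_numpy()
    pred = reference["absolv"].to_numpy()
    corr, _, line_metrics = fit_nrot_correction(records, obs, pred)
    corrected = apply_nrot_correction(corr, records, pred)
    before = evaluate(obs, pred)
    after = evaluate(obs, corrected)
    assert abs(after.bias) < 0.2
    assert after.rmse < before.rmse
    assert line_metrics.r2 == pytest.approx(0.44, abs=0.02)
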