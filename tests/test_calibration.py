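"""Calibration fitting, mode-bias analysis and correction factors.

The shipped reference-equation fixture drives the closed-form checks; OLS
behaviour is verified against exact generation and a replicated-noise
oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxisim.calibration import (
    CalibrationCurve,
    CorrectionFactor,
    DEFAULT_CORRECTION_GRID,
    apply_correction,
    bias_analysis,
    correction_factor,
    fit_curve,
    invert_reference,
    load_reference_curves,
    rmse,
)


@pytest.fixture(scope="module")
def curves():
    return load_reference_curves()


# --- fixture sanity ---------------------------------------------------------


def test_fixture_ships_seven_positive_slope_curves(curves):
    assert len(curves) == 7
    assert all(c.slope > 0 for c in curves.values())
    assert curves[("light", "reflectance")].intercept == 110.8
    assert curves[("commercial", "commercial")].predict(0.4) == pytest.approx(100.0)


# --- OLS fitting ------------------------------------------------------------


def test_fit_recovers_generating_line_exactly(curves):
    gen = curves[("light", "reflectance")]
    r = np.linspace(0.3, 1.4, 7)
    pts = list(zip(gen.predict(r), r))
    fit = fit_curve(pts, skin_type="light")
    assert fit.intercept == pytest.approx(110.8, abs=1e-9)
    assert fit.slope == pytest.approx(29.98, abs=1e-9)
    assert np.allclose(fit.residuals, 0.0, atol=1e-9)


def test_two_points_give_exact_interpolating_line():
    fit = fit_curve([(100.0, 0.4), (90.0, 0.8)])
    assert fit.intercept == pytest.approx(110.0)
    assert fit.slope == pytest.approx(25.0)


def test_fit_is_unbiased_under_noise():
    """OLS unbiasedness oracle: 500 noisy replicates of a known line."""
    rng = np.random.default_rng(123)
    a, b, sigma, n = 110.8, 29.98, 0.5, 7
    r = np.linspace(0.36, 1.36, n)
    intercepts, slopes = [], []
    for _ in range(500):
        sao2 = a - b * r + rng.normal(0, sigma, n)
        fit = fit_curve(list(zip(sao2, r)))
        intercepts.append(fit.intercept)
        slopes.append(fit.slope)
    for est, truth in ((intercepts, a), (slopes, b)):
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - truth) < 3 * se


def test_fit_rejects_degenerate_r_spread():
    with pytest.raises(ValueError):
        fit_curve([(95.0, 0.5), (96.0, 0.5)])


def test_fit_summary_mentions_equation():
    fit = fit_curve([(100.0, 0.4), (95.0, 0.6), (90.0, 0.8)], skin_type="light")
    text = fit.summary()
    assert "SaO2" in text and "light" in text


# --- reference inversion ----------------------------------------------------


def test_invert_reference_values():
    assert invert_reference(95) == pytest.approx(0.550314465408805, rel=1e-12)
    assert invert_reference(109) == pytest.approx(0.0, abs=1e-12)


@given(s=st.floats(50, 109))
@settings(deadline=None, max_examples=50)
def test_invert_predict_round_trip(s):
    ref = CalibrationCurve("light", "transmittance", 109.0, 25.44)
    assert ref.predict(ref.invert(s)) == pytest.approx(s, abs=1e-9)


# --- bias analysis ----------------------------------------------------------

# expected bias vectors on the 95..100 grid, computed in closed form from
# the fixture equations: bias(s) = (a_t - a_r) + (b_r - b_t) * R_ref(s)
LIGHT_BIAS = (0.698428, 0.519969, 0.341509, 0.163050, -0.015409, -0.193868)
MODERATE_BIAS = (0.937579, 0.927752, 0.917925, 0.908097, 0.898270, 0.888443)


def test_light_skin_bias_vector(curves):
    rep = bias_analysis(curves[("light", "transmittance")], curves[("light", "reflectance")])
    assert rep.bias == pytest.approx(LIGHT_BIAS, abs=5e-6)
    assert rep.rmse == pytest.approx(0.395644, abs=5e-6)


def test_moderate_skin_bias_vector(curves):
    rep = bias_analysis(
        curves[("moderate", "transmittance")], curves[("moderate", "reflectance")]
    )
    assert rep.bias == pytest.approx(MODERATE_BIAS, abs=5e-6)
    assert rep.rmse == pytest.approx(0.913165, abs=5e-6)


def test_dark_skin_rmse(curves):
    rep = bias_analysis(curves[("dark", "transmittance")], curves[("dark", "reflectance")])
    assert rep.rmse == pytest.approx(8.411061, abs=5e-6)


def test_identical_curves_give_zero_bias(curves):
    c = curves[("light", "reflectance")]
    rep = bias_analysis(c, c)
    assert rep.bias == pytest.approx((0.0,) * 6, abs=1e-12)
    assert rep.rmse == 0.0


def test_bias_is_linear_in_curve_differences(curves):
    """Scaling the transmittance-reflectance gap scales the bias vector."""
    refl = curves[("light", "reflectance")]
    trans = curves[("light", "transmittance")]
    for c in (0.5, 2.0, -1.0):
        scaled = CalibrationCurve(
            "light",
            "transmittance",
            refl.intercept + c * (trans.intercept - refl.intercept),
            refl.slope + c * (trans.slope - refl.slope),
        )
        base = np.asarray(bias_analysis(trans, refl).bias)
        got = np.asarray(bias_analysis(scaled, refl).bias)
        assert got == pytest.approx(c * base, abs=1e-9)


def test_empty_bias_grid_rejected(curves):
    with pytest.raises(ValueError):
        bias_analysis(
            curves[("light", "transmittance")],
            curves[("light", "reflectance")],
            grid=(),
        )


# --- rmse -------------------------------------------------------------------


def test_rmse_basic_cases():
    assert rmse([0.0, 0.0]) == 0.0
    assert rmse([-2.5]) == 2.5
    with pytest.raises(ValueError):
        rmse([])


@given(
    vec=st.lists(st.floats(-10, 10), min_size=1, max_size=8),
    seed=st.integers(0, 100),
)
@settings(deadline=None, max_examples=50)
def test_rmse_invariant_to_sign_and_order(vec, seed):
    rng = np.random.default_rng(seed)
    flipped = np.asarray(vec) * rng.choice([-1, 1], size=len(vec))
    assert rmse(rng.permutation(flipped)) == pytest.approx(rmse(vec), rel=1e-12)


# --- correction factors -----------------------------------------------------


def test_correction_factor_identity(curves):
    c = curves[("light", "reflectance")]
    assert correction_factor(c, c).factor == pytest.approx(1.0, abs=1e-12)


def test_dark_and_moderate_factors(curves):
    light = curves[("light", "reflectance")]
    dark = correction_factor(curves[("dark", "reflectance")], light)
    moderate = correction_factor(curves[("moderate", "reflectance")], light)
    assert dark.factor == pytest.approx(2.1665022136852534, rel=1e-12)
    assert round(dark.factor, 2) == 2.17
    assert moderate.factor == pytest.approx(1.2184732469033615, rel=1e-12)
    assert round(moderate.factor, 2) == 1.22


def test_correction_factor_endpoint_ratios(curves):
    # ratio of inverted R values at the grid ends, computed by hand
    light = curves[("light", "reflectance")]
    dark = curves[("dark", "reflectance")]
    assert light.invert(70) / dark.invert(70) == pytest.approx(2.33355, abs=1e-4)
    assert light.invert(100) / dark.invert(100) == pytest.approx(1.86140, abs=1e-4)


def test_correction_factor_zero_r_rejected(curves):
    target = CalibrationCurve("odd", "reflectance", 100.0, 10.0)  # R(100) = 0
    with pytest.raises(ValueError):
        correction_factor(target, curves[("light", "reflectance")])


def test_correction_factor_positive_validation():
    with pytest.raises(ValueError):
        CorrectionFactor("dark", 0.0)


# --- applying corrections ---------------------------------------------------


def test_apply_correction_identity_and_scaling():
    pts = [(95.0, 0.5), (90.0, 0.7)]
    assert apply_correction(pts, 1.0) == pts
    assert apply_correction([(95.0, 0.5)], 2.0) == [(95.0, 1.0)]


def test_corrected_dark_curve_refits_closer_to_light(curves):
    light = curves[("light", "reflectance")]
    dark = curves[("dark", "reflectance")]
    grid = np.asarray(DEFAULT_CORRECTION_GRID, dtype=float)
    pts = list(zip(grid, dark.invert(grid)))
    factor = correction_factor(dark, light)
    # rescaled R values refit to a slope much nearer the light-skin slope
    corrected = fit_curve(apply_correction(pts, factor))
    assert abs(corrected.slope - light.slope) < abs(dark.slope - light.slope)
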