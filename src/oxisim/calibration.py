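"""Calibration curves, skin-type correction factors and mode-bias analysis.

Pulse-oximeter calibration maps the ratio of ratios ``R`` to oxygen
saturation through a linear curve ``SaO2 = a - b*R``.  This module

* fits such curves to simulated ``(SaO2, R)`` points by ordinary least
  squares (:func:`fit_curve`);
* quantifies the disagreement between transmittance- and reflectance-mode
  calibration for each skin type (:func:`bias_analysis`): a reference curve
  (by default the light-skin transmittance curve, which closely matches the
  commercial algorithm) is inverted on a healthy-SaO2 grid and the
  resulting R values are substituted into both curves;
* derives multiplicative correction factors that map a darker skin type's
  R values onto the light-skin calibration (:func:`correction_factor`), as
  the mean ratio of inverted-curve R values over the 70-100% grid.

A versioned fixture ships the six linear calibration equations for
simulated finger transmittance/reflectance at light, moderate and dark
skin, plus a typical commercial algorithm ``SpO2 = 110 - 25*R``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationCurve",
    "CalibrationFit",
    "BiasReport",
    "CorrectionFactor",
    "load_reference_curves",
    "get_reference_curve",
    "fit_curve",
    "invert_reference",
    "bias_analysis",
    "rmse",
    "correction_factor",
    "apply_correction",
    "DEFAULT_BIAS_GRID",
    "DEFAULT_CORRECTION_GRID",
]

#: Healthy-range SaO2 grid (%) on which mode bias is evaluated.
DEFAULT_BIAS_GRID = tuple(range(95, 101))

#: Full simulated SaO2 grid (%) on which correction factors are averaged.
DEFAULT_CORRECTION_GRID = tuple(range(70, 101, 5))


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration ``SaO2 = intercept - slope * R``.

    ``slope`` is stored positive for the usual negative correlation of R
    with saturation; ``predict`` applies the minus sign.
    """

    skin_type: str
    mode: str
    intercept: float
    slope: float

    def predict(self, r) -> np.ndarray | float:
        """SaO2 (%) predicted at ratio-of-ratios ``r``."""
        return self.intercept - self.slope * np.asarray(r, dtype=float)

    def invert(self, sao2) -> np.ndarray | float:
        """Ratio of ratios at which the curve predicts ``sao2`` (%)."""
        return (self.intercept - np.asarray(sao2, dtype=float)) / self.slope

    def __str__(self) -> str:
        return f"SaO2 = {self.intercept:g} - {self.slope:g} x R  ({self.skin_type} {self.mode})"


def load_reference_curves(path: str | Path | None = None) -> dict[tuple[str, str], CalibrationCurve]:
    """Load the shipped (or an alternative) calibration-curve fixture.

    Returns a mapping keyed by ``(skin_type, mode)``.
    """
    if path is None:
        text = resources.files("oxisim.data").joinpath("table2_curves.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    curves = {}
    for entry in payload["curves"]:
        curve = CalibrationCurve(
            skin_type=entry["skin_type"],
            mode=entry["mode"],
            intercept=float(entry["intercept"]),
            slope=float(entry["slope"]),
        )
        if curve.slope <= 0:
            raise ValueError(f"fixture curve {curve} must have positive slope")
        curves[(curve.skin_type, curve.mode)] = curve
    return curves


def get_reference_curve(skin_type: str = "light", mode: str = "transmittance") -> CalibrationCurve:
    return load_reference_curves()[(skin_type, mode)]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of SaO2 on R: the curve plus estimation diagnostics."""

    curve: CalibrationCurve
    stderr_intercept: float
    stderr_slope: float
    residuals: np.ndarray
    r_squared: float
    nobs: int

    @property
    def intercept(self) -> float:
        return self.curve.intercept

    @property
    def slope(self) -> float:
        return self.curve.slope

    def summary(self) -> str:
        c = self.curve
        lines = [
            f"Calibration fit ({c.skin_type}, {c.mode}), n = {self.nobs}",
            f"  SaO2 = {c.intercept:.4f} - {c.slope:.4f} x R",
            f"  se(intercept) = {self.stderr_intercept:.4f}, se(slope) = {self.stderr_slope:.4f}",
            f"  R^2 = {self.r_squared:.5f}, residual RMS = {rmse(self.residuals):.4f}",
        ]
        return "\n".join(lines)


def fit_curve(points, *, skin_type: str = "custom", mode: str = "reflectance") -> CalibrationFit:
    """Ordinary least squares of SaO2 (%) on the ratio of ratios.

    ``points`` is an iterable of ``(sao2_percent, r)`` pairs (at least two
    distinct R values).  The fitted line is reported in the field's
    ``SaO2 = a - b*R`` convention, so ``slope`` is the negated regression
    coefficient.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (sao2, r) pairs")
    sao2, r = pts[:, 0], pts[:, 1]
    if len(np.unique(r)) < 2:
        raise ValueError("need at least two distinct R values to fit a line")
    model = sm.OLS(sao2, sm.add_constant(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        # diagnostics are lazy; evaluate them here so the n=2 exact-fit
        # case (df_resid = 0) cannot emit divide warnings downstream
        res = model.fit()
        intercept, coef = res.params
        bse0, bse1 = float(res.bse[0]), float(res.bse[1])
        resid = np.asarray(res.resid)
        rsq = float(res.rsquared) if len(pts) > 2 else 1.0
    return CalibrationFit(
        curve=CalibrationCurve(
            skin_type=skin_type, mode=mode, intercept=float(intercept), slope=float(-coef)
        ),
        stderr_intercept=bse0,
        stderr_slope=bse1,
        residuals=resid,
        r_squared=rsq,
        nobs=int(res.nobs),
    )


def invert_reference(sao2, reference: CalibrationCurve | None = None):
    """Ratio of ratios at a given SaO2 (%) under the reference curve.

    The default reference is the light-skin transmittance curve of the
    shipped fixture.
    """
    reference = reference or get_reference_curve()
    return reference.invert(sao2)


def rmse(bias_vector) -> float:
    """Root mean square of a bias vector (%)."""
    vec = np.asarray(bias_vector, dtype=float)
    if vec.size == 0:
        raise ValueError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean(vec**2)))


@dataclass(frozen=True)
class BiasReport:
    """Transmittance-minus-reflectance prediction bias over an SaO2 grid."""

    skin_type: str
    sao2_grid: tuple[float, ...]
    r_values: tuple[float, ...]
    bias: tuple[float, ...]

    @property
    def rmse(self) -> float:
        return rmse(self.bias)

    @property
    def min_bias(self) -> float:
        return float(np.min(self.bias))

    @property
    def max_bias(self) -> float:
        return float(np.max(self.bias))


def bias_analysis(
    trans: CalibrationCurve,
    refl: CalibrationCurve,
    reference: CalibrationCurve | None = None,
    grid=DEFAULT_BIAS_GRID,
) -> BiasReport:
    """Bias between transmittance and reflectance calibration of one skin type.

    For each grid SaO2 the reference curve is inverted to an R value, and
    the bias is the transmittance prediction minus the reflectance
    prediction at that R.
    """
    grid = tuple(float(s) for s in grid)
    if not grid:
        raise ValueError("bias grid must be non-empty")
    r_values = np.asarray(invert_reference(grid, reference))
    bias = np.asarray(trans.predict(r_values)) - np.asarray(refl.predict(r_values))
    skin = trans.skin_type if trans.skin_type == refl.skin_type else f"{trans.skin_type}/{refl.skin_type}"
    return BiasReport(
        skin_type=skin,
        sao2_grid=grid,
        r_values=tuple(float(v) for v in r_values),
        bias=tuple(float(b) for b in bias),
    )


@dataclass(frozen=True)
class CorrectionFactor:
    """Multiplier applied to a skin type's R values before calibration."""

    skin_type: str
    factor: float

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError(f"correction factor must be positive, got {self.factor}")


def correction_factor(
    target: CalibrationCurve,
    baseline: CalibrationCurve,
    grid=DEFAULT_CORRECTION_GRID,
) -> CorrectionFactor:
    """Mean ratio of baseline to target inverted-curve R values.

    Both curves are inverted on the SaO2 grid (default 70-100% in 5%
    steps); the factor is the mean of ``R_baseline / R_target``, i.e. the
    average rescaling that maps the target skin type's R range onto the
    baseline's.
    """
    grid = np.asarray(tuple(float(s) for s in grid))
    if grid.size == 0:
        raise ValueError("correction grid must be non-empty")
    r_base = np.asarray(baseline.invert(grid))
    r_target = np.asarray(target.invert(grid))
    if np.any(r_target == 0):
        raise ValueError("target curve inverts to R = 0 on the grid")
    return CorrectionFactor(
        skin_type=target.skin_type, factor=float(np.mean(r_base / r_target))
    )


def apply_correction(points, factor: CorrectionFactor | float):
    """Rescale the R value of each (sao2, r) point by the correction factor."""
    f = factor.factor if isinstance(factor, CorrectionFactor) else float(factor)
    if not f > 0:
        raise ValueError("correction factor must be positive")
    return [(float(s), float(r) * f) for s, r in points]
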