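"""Tissue chromophore absorption.

Absorption coefficients (all in mm^-1, wavelengths in nm) are composed from
volume fractions of the optically dominant chromophores of perfused skin:

* melanin, via the melanosome power law ``6.6e10 * lambda**-3.33``;
* a pigment-free "skin baseline", ``7.84e7 * lambda**-3.255``;
* oxy-/deoxy-haemoglobin and water, tabulated per wavelength in a
  :class:`ChromophoreTable` (shipped as an editable CSV fixture).

The epidermis mixes melanin, water and baseline; dermal sublayers mix
arterial and venous whole blood (at their respective oxygen saturations),
water and baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "EpidermisComposition",
    "BloodLayerComposition",
    "melanin_mua",
    "skin_baseline_mua",
    "epidermis_mua",
    "blood_layer_mua",
    "venous_sat_from_arterial",
]

#: Melanosome absorption power law coefficients (mu_a in mm^-1, lambda in nm).
MELANIN_SCALE = 6.6e10
MELANIN_EXPONENT = -3.33

#: Pigment-free skin baseline power law coefficients.
BASELINE_SCALE = 7.84e7
BASELINE_EXPONENT = -3.255

#: Venous saturation is taken as a fixed offset below arterial saturation.
VENOUS_OFFSET = 0.10

_FRACTION_TOL = 1e-12


def melanin_mua(lambda_nm: float) -> float:
    """Absorption coefficient of a melanosome interior (mm^-1).

    Parameters
    ----------
    lambda_nm : float
        Wavelength in nanometres; must be positive.
    """
    if lambda_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_nm}")
    return MELANIN_SCALE * lambda_nm**MELANIN_EXPONENT


def skin_baseline_mua(lambda_nm: float) -> float:
    """Absorption coefficient of pigment-free, bloodless skin tissue (mm^-1)."""
    if lambda_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_nm}")
    return BASELINE_SCALE * lambda_nm**BASELINE_EXPONENT


def venous_sat_from_arterial(sat_a: float) -> float:
    """Venous oxygen saturation implied by arterial saturation.

    Venous blood is modelled as a fixed 10-percentage-point desaturation of
    arterial blood, so the result is ``sat_a - 0.10``.
    """
    sat_v = sat_a - VENOUS_OFFSET
    if sat_v < 0:
        raise ValueError(
            f"arterial saturation {sat_a} implies negative venous saturation"
        )
    if sat_a > 1:
        raise ValueError(f"arterial saturation {sat_a} exceeds 1")
    return sat_v


class ChromophoreTable:
    """Wavelength-indexed absorption coefficients of HbO2, HHb and water.

    Values are whole-blood (for the haemoglobins) and pure-water absorption
    coefficients in mm^-1.  Lookup of a wavelength that is not tabulated
    raises ``KeyError`` unless log-log interpolation is explicitly enabled
    (``interpolate=True``), so a typo in a wavelength cannot silently return
    a nearby value.
    """

    REQUIRED_WAVELENGTHS = (660.0, 940.0)
    COLUMNS = ("mu_a_hbo2_mm", "mu_a_hhb_mm", "mu_a_water_mm")

    def __init__(self, frame: pd.DataFrame, *, interpolate: bool = False):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"chromophore table missing columns {missing}")
        frame = frame.copy()
        frame["wavelength_nm"] = frame["wavelength_nm"].astype(float)
        frame = frame.set_index("wavelength_nm").sort_index()
        if (frame[list(self.COLUMNS)] < 0).any().any():
            raise ValueError("chromophore table contains negative mu_a values")
        for wl in self.REQUIRED_WAVELENGTHS:
            if wl not in frame.index:
                raise ValueError(f"chromophore table must tabulate {wl} nm")
        self._frame = frame
        self.interpolate = interpolate

    @classmethod
    def default(cls, *, interpolate: bool = False) -> "ChromophoreTable":
        """Load the packaged literature-default spectra."""
        with resources.files("oxisim.data").joinpath(
            "chromophore_spectra.csv"
        ).open() as fh:
            frame = pd.read_csv(fh, comment="#")
        return cls(frame, interpolate=interpolate)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ChromophoreTable":
        return cls(pd.read_csv(path, comment="#"), **kwargs)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(self._frame.index)

    def _lookup(self, lambda_nm: float, column: str) -> float:
        lam = float(lambda_nm)
        if lam in self._frame.index:
            return float(self._frame.at[lam, column])
        if not self.interpolate:
            raise KeyError(
                f"{lambda_nm} nm not tabulated (have {self.wavelengths}); "
                "pass interpolate=True for log-log interpolation"
            )
        wls = self._frame.index.to_numpy()
        if not (wls.min() <= lam <= wls.max()):
            raise KeyError(f"{lambda_nm} nm outside tabulated range")
        vals = self._frame[column].to_numpy()
        # log-log interpolation; guard zero entries by flooring at tiny mu_a
        floor = 1e-12
        return float(
            math.exp(
                np.interp(math.log(lam), np.log(wls), np.log(np.maximum(vals, floor)))
            )
        )

    def mu_a_hbo2(self, lambda_nm: float) -> float:
        """Whole-blood oxyhaemoglobin absorption (mm^-1)."""
        return self._lookup(lambda_nm, "mu_a_hbo2_mm")

    def mu_a_hhb(self, lambda_nm: float) -> float:
        """Whole-blood deoxyhaemoglobin absorption (mm^-1)."""
        return self._lookup(lambda_nm, "mu_a_hhb_mm")

    def mu_a_water(self, lambda_nm: float) -> float:
        """Pure-water absorption (mm^-1)."""
        return self._lookup(lambda_nm, "mu_a_water_mm")

    def __repr__(self) -> str:  # pragma: no cover
        return f"ChromophoreTable(wavelengths={self.wavelengths})"


@dataclass(frozen=True)
class EpidermisComposition:
    """Volume fractions of the epidermis: melanosomes and water.

    The remainder ``1 - vmel - vw`` is attributed to the pigment-free skin
    baseline.
    """

    vmel: float
    vw: float = 0.0

    def __post_init__(self):
        if self.vmel < 0 or self.vw < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.vmel + self.vw > 1 + _FRACTION_TOL:
            raise ValueError(
                f"vmel + vw = {self.vmel + self.vw:.4f} exceeds unity"
            )


@dataclass(frozen=True)
class BloodLayerComposition:
    """Volume fractions and saturations of a perfused (dermal) layer.

    ``va`` and ``vv`` are arterial and venous whole-blood volume fractions,
    ``vw`` the water fraction; the remainder is skin baseline.  ``sat_a`` is
    arterial oxygen saturation; ``sat_v`` defaults to ``sat_a - 0.10``.
    """

    va: float
    vv: float
    vw: float
    sat_a: float
    sat_v: float | None = None

    def __post_init__(self):
        if self.sat_v is None:
            object.__setattr__(self, "sat_v", venous_sat_from_arterial(self.sat_a))
        if min(self.va, self.vv, self.vw) < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.va + self.vv + self.vw > 1 + _FRACTION_TOL:
            raise ValueError(
                f"va + vv + vw = {self.va + self.vv + self.vw:.4f} exceeds unity"
            )
        if not (0 <= self.sat_a <= 1 and 0 <= self.sat_v <= 1):
            raise ValueError("saturations must lie in [0, 1]")

    @property
    def total_blood(self) -> float:
        return self.va + self.vv


def epidermis_mua(
    lambda_nm: float,
    comp: EpidermisComposition,
    table: ChromophoreTable,
) -> float:
    """Epidermal absorption coefficient (mm^-1).

    ``vmel * mu_a_melanin + vw * mu_a_water + (1 - vmel - vw) * mu_a_baseline``.
    """
    residual = 1.0 - comp.vmel - comp.vw
    return (
        comp.vmel * melanin_mua(lambda_nm)
        + comp.vw * table.mu_a_water(lambda_nm)
        + residual * skin_baseline_mua(lambda_nm)
    )


def blood_layer_mua(
    lambda_nm: float,
    comp: BloodLayerComposition,
    table: ChromophoreTable,
) -> float:
    """Absorption coefficient of a perfused dermal sublayer (mm^-1).

    Arterial and venous blood are mixed at their own saturations:

    ``[satA*muaHbO2 + (1-satA)*muaHHb]*vA + [satV*muaHbO2 + (1-satV)*muaHHb]*vV
    + vw*mua_water + (1 - vA - vV - vw) * mu_a_baseline``.
    """
    hbo2 = table.mu_a_hbo2(lambda_nm)
    hhb = table.mu_a_hhb(lambda_nm)
    arterial = (comp.sat_a * hbo2 + (1.0 - comp.sat_a) * hhb) * comp.va
    venous = (comp.sat_v * hbo2 + (1.0 - comp.sat_v) * hhb) * comp.vv
    water = comp.vw * table.mu_a_water(lambda_nm)
    residual = (1.0 - (comp.va + comp.vv + comp.vw)) * skin_baseline_mua(lambda_nm)
    return arterial + venous + water + residual
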