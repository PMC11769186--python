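"""Pulse-oximetry simulation pipeline.

Orchestrates transport runs over the {wavelength x cardiac phase x SaO2 x
skin preset} grid and reduces the raw systolic/diastolic reflectances to
the photoplethysmography quantities a pulse oximeter works with:

* ``DC`` - the baseline (diastolic) reflectance at one wavelength;
* ``AC`` - the pulsatile excursion, diastolic minus systolic reflectance;
* ``PI`` - the perfusion index AC/DC;
* ``R``  - the ratio of ratios, PI(660 nm) / PI(940 nm), the quantity a
  calibration curve maps to SpO2.

Every transport run gets a child seed that is a stable hash of
(base seed, skin, wavelength, phase, SaO2), so the full grid is a pure
function of its inputs and adding grid points never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import ChromophoreTable
from .engine import DetectorSpec, EngineSettings, TransportResult, transport
from .tissue import (
    PhysiologicalState,
    STANDARD_SAT_GRID,
    TissueConfig,
    build_stack,
    load_preset,
)

__all__ = [
    "ReflectanceRecord",
    "PulseOxPoint",
    "child_seed",
    "run_grid",
    "reduce_point",
    "ratio_curve",
    "records_to_frame",
    "points_to_frame",
    "WAVELENGTHS",
    "DESK_DETECTED_TARGET",
    "PAPER_DETECTED_TARGET",
]

#: The two operating wavelengths of pulse oximetry (nm).
WAVELENGTHS = (660.0, 940.0)

PHASES = ("diastole", "systole")

#: Detected-packet stop targets: desk scale for routine runs, paper scale
#: for the one-million-detected criterion.
DESK_DETECTED_TARGET = 100_000
PAPER_DETECTED_TARGET = 1_000_000


def child_seed(
    base_seed: int, skin: str, lambda_nm: float, phase: str, sat_a: float
) -> int:
    """Deterministic per-run seed from the grid coordinates.

    A stable cryptographic hash of the tuple, truncated to 31 bits, so the
    seed of one (skin, wavelength, phase, SaO2) combination never depends
    on which other combinations are simulated.
    """
    key = f"{int(base_seed)}|{skin}|{float(lambda_nm):.6g}|{phase}|{float(sat_a):.6g}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class ReflectanceRecord:
    """Detected reflectance of one transport run."""

    skin_type: str
    lambda_nm: float
    phase: str
    sat_a: float
    reflectance: float
    detected_count: int
    launched_count: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.reflectance <= 1:
            raise ValueError(f"reflectance {self.reflectance} outside [0, 1]")


@dataclass(frozen=True)
class PulseOxPoint:
    """AC/DC/PI at both wavelengths and the ratio of ratios at one SaO2."""

    sat_a: float
    ac_660: float
    dc_660: float
    pi_660: float
    ac_940: float
    dc_940: float
    pi_940: float
    r: float


def _strip_bone(config: TissueConfig, include_bone: bool) -> TissueConfig:
    if include_bone:
        return config
    return dataclasses.replace(config, bone=None)


def _resolve_config(skin) -> tuple[str, TissueConfig]:
    if isinstance(skin, TissueConfig):
        return "custom", skin
    return str(skin), load_preset(str(skin))


def run_grid(
    skin,
    *,
    base_seed: int,
    sat_grid=STANDARD_SAT_GRID,
    wavelengths=WAVELENGTHS,
    detected_target: int = DESK_DETECTED_TARGET,
    detector: DetectorSpec | None = None,
    settings: EngineSettings | None = None,
    table: ChromophoreTable | None = None,
    include_bone: bool = False,
    skin_label: str | None = None,
) -> list[ReflectanceRecord]:
    """One transport run per (wavelength, phase, SaO2) for one skin preset.

    ``skin`` is a preset name (``light``/``moderate``/``dark``) or a
    :class:`TissueConfig`.  By default the bone cylinder is omitted
    (slab-only geometry): at 3 mm source-detector separation in reflectance
    mode, detected photons essentially never reach bone depth.

    Raises ``RuntimeError`` naming the failing combination if any transport
    cannot reach its detected-packet target.
    """
    sat_grid = tuple(float(s) for s in sat_grid)
    if not sat_grid:
        raise ValueError("sat_grid must be non-empty")
    label, config = _resolve_config(skin)
    if skin_label is not None:
        label = skin_label
    config = _strip_bone(config, include_bone)
    table = table or ChromophoreTable.default()
    records = []
    for sat_a in sat_grid:
        for lam in wavelengths:
            for phase in PHASES:
                seed = child_seed(base_seed, label, lam, phase, sat_a)
                stack = build_stack(config, lam, PhysiologicalState(sat_a, phase), table)
                try:
                    res: TransportResult = transport(
                        stack,
                        detector,
                        seed=seed,
                        detected_target=detected_target,
                        settings=settings,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"transport failed for skin={label}, lambda={lam}, "
                        f"phase={phase}, sat_a={sat_a}: {exc}"
                    ) from exc
                records.append(
                    ReflectanceRecord(
                        skin_type=label,
                        lambda_nm=lam,
                        phase=phase,
                        sat_a=sat_a,
                        reflectance=res.reflectance,
                        detected_count=res.detected_count,
                        launched_count=res.launched_count,
                        seed=seed,
                    )
                )
    return records


def reduce_point(records: list[ReflectanceRecord], *, dc_mode: str = "diastole") -> PulseOxPoint:
    """Collapse the four runs of one SaO2 into a :class:`PulseOxPoint`.

    Expects exactly one record per (wavelength, phase).  The pulsatile
    convention is ``AC = R_diastole - R_systole`` (systolic blood influx
    absorbs more light) and ``DC = R_diastole``; ``dc_mode='mean'`` uses
    the two-phase mean as the baseline instead.
    """
    if dc_mode not in ("diastole", "mean"):
        raise ValueError("dc_mode must be 'diastole' or 'mean'")
    if len(records) != 4:
        raise ValueError(f"expected 4 records for one SaO2, got {len(records)}")
    sats = {rec.sat_a for rec in records}
    if len(sats) != 1:
        raise ValueError(f"records span several SaO2 values: {sorted(sats)}")
    by_key = {(rec.lambda_nm, rec.phase): rec.reflectance for rec in records}
    if len(by_key) != 4:
        raise ValueError("duplicate (wavelength, phase) combination")

    def _acdc(lam: float) -> tuple[float, float]:
        try:
            dia = by_key[(lam, "diastole")]
            sys_ = by_key[(lam, "systole")]
        except KeyError as exc:
            raise ValueError(f"missing record for {lam} nm: {exc}") from exc
        ac = dia - sys_
        dc = dia if dc_mode == "diastole" else 0.5 * (dia + sys_)
        return ac, dc

    ac660, dc660 = _acdc(660.0)
    ac940, dc940 = _acdc(940.0)
    if dc660 <= 0 or dc940 <= 0:
        raise ValueError("degenerate signal: DC must be positive")
    pi660 = ac660 / dc660
    pi940 = ac940 / dc940
    if pi940 == 0:
        raise ValueError("degenerate signal: PI at 940 nm is zero")
    return PulseOxPoint(
        sat_a=records[0].sat_a,
        ac_660=ac660,
        dc_660=dc660,
        pi_660=pi660,
        ac_940=ac940,
        dc_940=dc940,
        pi_940=pi940,
        r=pi660 / pi940,
    )


def ratio_curve(skin, *, base_seed: int, dc_mode: str = "diastole", **kwargs) -> list[PulseOxPoint]:
    """Simulated calibration data: one (SaO2, R) point per grid saturation.

    Runs :func:`run_grid` and reduces each saturation; accepts the same
    keyword arguments as :func:`run_grid`.
    """
    records = run_grid(skin, base_seed=base_seed, **kwargs)
    return reduce_records(records, dc_mode=dc_mode)


def reduce_records(
    records: list[ReflectanceRecord], *, dc_mode: str = "diastole"
) -> list[PulseOxPoint]:
    """Group raw records by SaO2 and reduce each group, ascending in SaO2."""
    groups: dict[float, list[ReflectanceRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sat_a, []).append(rec)
    return [reduce_point(groups[s], dc_mode=dc_mode) for s in sorted(groups)]


def records_to_frame(records: list[ReflectanceRecord]) -> pd.DataFrame:
    """Raw transport records as a tidy DataFrame."""
    return pd.DataFrame([dataclasses.asdict(rec) for rec in records])


def points_to_frame(points: list[PulseOxPoint], skin_type: str | None = None) -> pd.DataFrame:
    """Reduced pulse-ox points as a DataFrame (ratio_curves.csv schema)."""
    frame = pd.DataFrame([dataclasses.asdict(pt) for pt in points])
    if skin_type is not None:
        frame.insert(0, "skin_type", skin_type)
    return frame
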