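"""Layered finger geometry with resolved optical properties.

The finger is modelled as a stack of plane-parallel slabs (epidermis, dermal
sublayers, subcutaneous fat, muscle) with an optional cylindrical bone whose
axis runs horizontally through the muscle.  Coordinates: origin at the photon
entry point on the skin surface, ``z`` positive into the tissue, the detector
displaced along ``+x``; all lengths in mm.

A :class:`TissueConfig` holds the wavelength-independent description (loaded
from YAML); :func:`build_stack` resolves it at one wavelength and one cardiac
phase into a :class:`TissueStack` with scalar ``mu_a``, ``mu_s``, ``g``, ``n``
per layer.  The systolic phase doubles each perfused layer's arterial and
venous blood volume fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Union

import numpy as np
import yaml

from .chromophores import (
    BloodLayerComposition,
    ChromophoreTable,
    EpidermisComposition,
    blood_layer_mua,
    epidermis_mua,
    venous_sat_from_arterial,
)

__all__ = [
    "ConfigError",
    "FixedAbsorption",
    "LayerConfig",
    "BoneConfig",
    "TissueConfig",
    "PhysiologicalState",
    "ResolvedLayer",
    "ResolvedBone",
    "TissueStack",
    "apply_systole",
    "build_stack",
    "locate",
    "load_preset",
    "PRESETS",
    "SKIN_PRESET_VMEL",
]

PRESETS = ("light", "moderate", "dark")

#: Melanosome volume fractions of the three shipped skin-type presets.
SKIN_PRESET_VMEL = {"light": 0.0255, "moderate": 0.155, "dark": 0.305}

#: Standard arterial-saturation grid: 70% to 100% in 5% steps.
STANDARD_SAT_GRID = tuple(np.round(np.arange(0.70, 1.0001, 0.05), 4))

ABOVE_SURFACE = "above-surface"
BELOW_STACK = "below-stack"
INSIDE_BONE = "inside-bone"


class ConfigError(ValueError):
    """A tissue configuration failed validation; message names the field."""


@dataclass(frozen=True)
class FixedAbsorption:
    """Per-wavelength absorption for layers without modelled chromophores."""

    mu_a_mm: dict[float, float]

    def __post_init__(self):
        object.__setattr__(
            self, "mu_a_mm", {float(k): float(v) for k, v in self.mu_a_mm.items()}
        )
        if any(v < 0 for v in self.mu_a_mm.values()):
            raise ConfigError("fixed mu_a values must be non-negative")


Composition = Union[EpidermisComposition, BloodLayerComposition, FixedAbsorption]


def _per_wavelength(mapping, path: str) -> dict[float, float]:
    try:
        return {float(k): float(v) for k, v in mapping.items()}
    except (TypeError, AttributeError) as exc:
        raise ConfigError(f"{path}: expected a wavelength->value mapping") from exc


@dataclass(frozen=True)
class LayerConfig:
    """One slab: geometry, scattering properties and composition."""

    name: str
    thickness_mm: float
    mu_s_mm: dict[float, float]
    g: dict[float, float]
    n: float
    composition: Composition

    def __post_init__(self):
        object.__setattr__(self, "mu_s_mm", _per_wavelength(self.mu_s_mm, self.name))
        object.__setattr__(self, "g", _per_wavelength(self.g, self.name))
        if self.thickness_mm <= 0:
            raise ConfigError(f"layers.{self.name}.thickness_mm must be > 0")
        if any(v < 0 for v in self.mu_s_mm.values()):
            raise ConfigError(f"layers.{self.name}.mu_s_mm must be >= 0")
        if any(not -1 <= v <= 1 for v in self.g.values()):
            raise ConfigError(f"layers.{self.name}.g must lie in [-1, 1]")
        if self.n < 1:
            raise ConfigError(f"layers.{self.name}.n must be >= 1")


@dataclass(frozen=True)
class BoneConfig:
    """Cylindrical bone, axis along y at (center_x_mm, center_depth_mm)."""

    center_depth_mm: float
    radius_mm: float
    mu_a_mm: dict[float, float]
    mu_s_mm: dict[float, float]
    g: dict[float, float]
    n: float = 1.55
    center_x_mm: float = 0.0

    def __post_init__(self):
        for name in ("mu_a_mm", "mu_s_mm", "g"):
            object.__setattr__(
                self, name, _per_wavelength(getattr(self, name), f"bone.{name}")
            )
        if self.radius_mm <= 0:
            raise ConfigError("bone.radius_mm must be > 0")


def _composition_from_dict(d: dict, path: str) -> Composition:
    if not isinstance(d, dict) or "kind" not in d:
        raise ConfigError(f"{path}.composition: missing 'kind'")
    kind = d["kind"]
    fields = {k: v for k, v in d.items() if k != "kind"}
    try:
        if kind == "epidermis":
            return EpidermisComposition(**fields)
        if kind == "blood":
            # sat_a is physiological state, resolved at build time
            return BloodLayerComposition(sat_a=1.0, **fields)
        if kind == "fixed":
            return FixedAbsorption(**fields)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}.composition: {exc}") from exc
    raise ConfigError(f"{path}.composition.kind: unknown kind {kind!r}")


def _composition_to_dict(comp: Composition) -> dict:
    if isinstance(comp, EpidermisComposition):
        return {"kind": "epidermis", "vmel": comp.vmel, "vw": comp.vw}
    if isinstance(comp, BloodLayerComposition):
        return {"kind": "blood", "va": comp.va, "vv": comp.vv, "vw": comp.vw}
    return {"kind": "fixed", "mu_a_mm": dict(comp.mu_a_mm)}


@dataclass(frozen=True)
class TissueConfig:
    """Wavelength-independent tissue description (the YAML schema)."""

    layers: tuple[LayerConfig, ...]
    bone: BoneConfig | None = None
    ambient_n: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ConfigError("layers: at least one layer required")

    @classmethod
    def from_dict(cls, d: dict) -> "TissueConfig":
        if "layers" not in d:
            raise ConfigError("layers: missing")
        layers = []
        for i, ld in enumerate(d["layers"]):
            path = f"layers[{i}]"
            missing = {"name", "thickness_mm", "mu_s_mm", "g", "n", "composition"} - set(
                ld
            )
            if missing:
                raise ConfigError(f"{path}: missing fields {sorted(missing)}")
            layers.append(
                LayerConfig(
                    name=ld["name"],
                    thickness_mm=float(ld["thickness_mm"]),
                    mu_s_mm=ld["mu_s_mm"],
                    g=ld["g"],
                    n=float(ld["n"]),
                    composition=_composition_from_dict(ld["composition"], path),
                )
            )
        bone = None
        if d.get("bone") is not None:
            try:
                bone = BoneConfig(**d["bone"])
            except TypeError as exc:
                raise ConfigError(f"bone: {exc}") from exc
        return cls(layers=tuple(layers), bone=bone, ambient_n=float(d.get("ambient_n", 1.0)))

    def to_dict(self) -> dict:
        return {
            "ambient_n": self.ambient_n,
            "layers": [
                {
                    "name": lay.name,
                    "thickness_mm": lay.thickness_mm,
                    "mu_s_mm": dict(lay.mu_s_mm),
                    "g": dict(lay.g),
                    "n": lay.n,
                    "composition": _composition_to_dict(lay.composition),
                }
                for lay in self.layers
            ],
            "bone": None
            if self.bone is None
            else {
                "center_depth_mm": self.bone.center_depth_mm,
                "center_x_mm": self.bone.center_x_mm,
                "radius_mm": self.bone.radius_mm,
                "mu_a_mm": dict(self.bone.mu_a_mm),
                "mu_s_mm": dict(self.bone.mu_s_mm),
                "g": dict(self.bone.g),
                "n": self.bone.n,
            },
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def total_depth(self) -> float:
        return sum(lay.thickness_mm for lay in self.layers)


def load_preset(name: str) -> TissueConfig:
    """Load one of the shipped skin-type presets (light/moderate/dark)."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    with resources.files("oxisim.data").joinpath(f"{name}.yaml").open() as fh:
        return TissueConfig.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PhysiologicalState:
    """Arterial saturation and cardiac phase at which the stack is resolved."""

    sat_a: float
    phase: Literal["diastole", "systole"] = "diastole"

    def __post_init__(self):
        if not 0 <= self.sat_a <= 1:
            raise ValueError(f"sat_a must lie in [0, 1], got {self.sat_a}")
        if self.phase not in ("diastole", "systole"):
            raise ValueError(f"phase must be diastole or systole, got {self.phase}")

    @property
    def sat_v(self) -> float:
        return venous_sat_from_arterial(self.sat_a)


def apply_systole(comp: BloodLayerComposition) -> BloodLayerComposition:
    """Double both blood compartments of a perfused layer.

    The systolic pulse is modelled as a doubling of the diastolic blood
    volume, distributed equally between the arterial and venous compartments
    (each compartment doubles).
    """
    va, vv = 2.0 * comp.va, 2.0 * comp.vv
    if va + vv + comp.vw > 1 + 1e-12:
        raise ValueError(
            f"systolic blood fractions exceed unity budget: "
            f"2*(va+vv)+vw = {va + vv + comp.vw:.4f}"
        )
    return dataclasses.replace(comp, va=va, vv=vv)


@dataclass(frozen=True)
class ResolvedLayer:
    """One slab with scalar optical properties at a single wavelength/phase."""

    name: str
    z_top: float
    z_bottom: float
    mu_a: float
    mu_s: float
    g: float
    n: float

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top


@dataclass(frozen=True)
class ResolvedBone:
    center_depth: float
    center_x: float
    radius: float
    mu_a: float
    mu_s: float
    g: float
    n: float


@dataclass(frozen=True)
class TissueStack:
    """Resolved stack ready for photon transport."""

    layers: tuple[ResolvedLayer, ...]
    ambient_n_above: float
    ambient_n_below: float
    lambda_nm: float
    state: PhysiologicalState
    bone: ResolvedBone | None = None

    def __post_init__(self):
        for lay in self.layers:
            if not np.isfinite(lay.mu_a) or lay.mu_a < 0:
                raise ValueError(f"layer {lay.name}: non-finite or negative mu_a")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if abs(prev.z_bottom - nxt.z_top) > 1e-12:
                raise ValueError(
                    f"gap/overlap between {prev.name} and {nxt.name}"
                )

    @property
    def total_depth(self) -> float:
        return self.layers[-1].z_bottom

    def layer_index_at(self, depth: float) -> int:
        """Index of the slab containing a depth in [0, total_depth)."""
        for i, lay in enumerate(self.layers):
            if lay.z_top <= depth < lay.z_bottom:
                return i
        raise ValueError(f"depth {depth} outside the stack")


def _pick(mapping: dict[float, float], lambda_nm: float, path: str) -> float:
    lam = float(lambda_nm)
    if lam not in mapping:
        raise ConfigError(
            f"{path}: wavelength {lambda_nm} nm not tabulated (have {sorted(mapping)})"
        )
    return mapping[lam]


def build_stack(
    config: TissueConfig,
    lambda_nm: float,
    state: PhysiologicalState,
    table: ChromophoreTable,
) -> TissueStack:
    """Resolve a configuration at one wavelength and cardiac phase.

    Epidermal layers get their absorption from the melanin/water/baseline
    mixture; perfused layers from the arterial+venous blood mixture at the
    state's saturations (blood volumes doubled during systole); fixed layers
    from their tabulated values.  Scattering properties are phase-invariant.
    """
    z = 0.0
    resolved = []
    for lay in config.layers:
        comp = lay.composition
        if isinstance(comp, EpidermisComposition):
            mu_a = epidermis_mua(lambda_nm, comp, table)
        elif isinstance(comp, BloodLayerComposition):
            comp = dataclasses.replace(
                comp, sat_a=state.sat_a, sat_v=venous_sat_from_arterial(state.sat_a)
            )
            if state.phase == "systole":
                comp = apply_systole(comp)
            mu_a = blood_layer_mua(lambda_nm, comp, table)
        else:
            mu_a = _pick(comp.mu_a_mm, lambda_nm, f"layers.{lay.name}.mu_a_mm")
        resolved.append(
            ResolvedLayer(
                name=lay.name,
                z_top=z,
                z_bottom=z + lay.thickness_mm,
                mu_a=mu_a,
                mu_s=_pick(lay.mu_s_mm, lambda_nm, f"layers.{lay.name}.mu_s_mm"),
                g=_pick(lay.g, lambda_nm, f"layers.{lay.name}.g"),
                n=lay.n,
            )
        )
        z += lay.thickness_mm
    bone = None
    if config.bone is not None:
        b = config.bone
        bone = ResolvedBone(
            center_depth=b.center_depth_mm,
            center_x=b.center_x_mm,
            radius=b.radius_mm,
            mu_a=_pick(b.mu_a_mm, lambda_nm, "bone.mu_a_mm"),
            mu_s=_pick(b.mu_s_mm, lambda_nm, "bone.mu_s_mm"),
            g=_pick(b.g, lambda_nm, "bone.g"),
            n=b.n,
        )
    return TissueStack(
        layers=tuple(resolved),
        ambient_n_above=config.ambient_n,
        ambient_n_below=config.ambient_n,
        lambda_nm=float(lambda_nm),
        state=state,
        bone=bone,
    )


def locate(point, stack: TissueStack) -> int | str:
    """Classify a 3D point: layer index, above-surface, below-stack or bone.

    Every point maps to exactly one region; the bone cylinder takes
    precedence over the slab it is embedded in.
    """
    x, _, z = (float(c) for c in point)
    if z < 0:
        return ABOVE_SURFACE
    if z >= stack.total_depth:
        return BELOW_STACK
    if stack.bone is not None:
        dx = x - stack.bone.center_x
        dz = z - stack.bone.center_depth
        if dx * dx + dz * dz < stack.bone.radius**2:
            return INSIDE_BONE
    return stack.layer_index_at(z)
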