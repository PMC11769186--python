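import dataclasses

import pytest

from oxisim.chromophores import ChromophoreTable
from oxisim.tissue import TissueConfig, load_preset


@pytest.fixture(scope="session")
def table() -> ChromophoreTable:
    return ChromophoreTable.default()


@pytest.fixture(scope="session")
def light_config() -> TissueConfig:
    return load_preset("light")


@pytest.fixture(scope="session")
def light_slab(light_config) -> TissueConfig:
    """Light-skin preset without the bone cylinder."""
    return dataclasses.replace(light_config, bone=None)


def homogeneous_slab(
    mu_a: float,
    mu_s: float,
    g: float = 0.0,
    thickness: float = 1.0,
    n: float = 1.4,
    ambient_n: float = 1.0,
) -> TissueConfig:
    """Single uniform layer with fixed absorption (both wavelengths)."""
    return TissueConfig.from_dict(
        {
            "ambient_n": ambient_n,
            "layers": [
                {
                    "name": "slab",
                    "thickness_mm": thickness,
                    "mu_s_mm": {660: mu_s, 940: mu_s},
                    "g": {660: g, 940: g},
                    "n": n,
                    "composition": {
                        "kind": "fixed",
                        "mu_a_mm": {660: mu_a, 940: mu_a},
                    },
                }
            ],
            "bone": None,
        }
    )
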