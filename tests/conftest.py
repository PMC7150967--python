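import numpy as np
import pytest

from foamquant.presets import GeneratorPreset


@pytest.fixture
def small_preset() -> GeneratorPreset:
    """A fast, small-cell population for unit tests (not a study condition)."""
    p = GeneratorPreset(
        name="test_small",
        cell_area_mean=250.0,
        cell_area_sd=25.0,
        nucleus_area_fraction=0.15,
        vacuole_count_mean=10.0,
        vacuole_count_dispersion=None,
        vacuole_radius_mean=0.9,
        vacuole_radius_sd=0.1,
    )
    p.validate()
    return p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
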