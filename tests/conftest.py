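"""Shared fixtures: small deterministic simulator configs and RNGs."""
from __future__ import annotations

import numpy as np
import pytest

from hcscreen.simulate import Condition, PlateSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Zero-noise, zero-background config: every rendered pixel is analytic."""
    return PlateSimConfig(
        conditions={"vehicle": Condition(compound="vehicle", ratio=3.0)},
        read_noise_sd=0.0,
        shot_noise_scale=0.0,
        background_level=0.0,
        intensity_cv=0.0,
        ratio_cv=0.0,
        mito_intensity_cv=0.0,
        cells_per_field=10,
        touching_fraction=0.0,
    )


@pytest.fixture
def noisy_config():
    """Default noise levels, single vehicle condition."""
    return PlateSimConfig(
        conditions={"vehicle": Condition(compound="vehicle")},
        cells_per_field=50,
    )
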