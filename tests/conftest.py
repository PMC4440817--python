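from __future__ import annotations

import numpy as np
import pytest

from farmscape import GeneratorConfig, LandscapeConfig, ModelConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def small_gen_config() -> GeneratorConfig:
    """A ~10,000-ha catchment (~60 farms) for fast unit tests."""
    return GeneratorConfig(n_rows=20, n_cols=20, mean_cells=6.0)


@pytest.fixture
def small_model_config(small_gen_config) -> ModelConfig:
    return ModelConfig(landscape=LandscapeConfig(generator=small_gen_config))
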