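from __future__ import annotations

import numpy as np
import pytest

from lymphopatch.config import LBPConfig, PatchConfig, SynthConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth_cfg() -> SynthConfig:
    """Small images for fast unit tests; class parameters stay at defaults."""
    return SynthConfig(image_size=(200, 200))


@pytest.fixture(scope="session")
def small_patch_cfg() -> PatchConfig:
    return PatchConfig(s1=100, s2=50, r_o=0.5)


@pytest.fixture(scope="session")
def lbp_cfg() -> LBPConfig:
    return LBPConfig()
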