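import dataclasses

import numpy as np
import pytest

from plumekin.config import AnalysisConfig
from plumekin.synthetic import GroundTruth, SyntheticConfig


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def synth() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def short_synth() -> SyntheticConfig:
    """A 40 s world for fast unit tests."""
    return dataclasses.replace(SyntheticConfig(), duration=40.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_truth() -> GroundTruth:
    return GroundTruth.null()
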