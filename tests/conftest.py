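"""Shared fixtures: small synthetic scenes sized for fast unit tests."""

import numpy as np
import pytest

from scmseg import ImageModelConfig, generate_frame

SMALL_FRAME = 256
# Object density matching the default model (750 objects / 10^6 px).
SMALL_N = 48


@pytest.fixture(scope="session")
def small_config() -> ImageModelConfig:
    return ImageModelConfig(frame_size=SMALL_FRAME, n_objects=SMALL_N,
                            contrast=2.2, seed=7)


@pytest.fixture(scope="session")
def small_frame(small_config):
    """A 256-px synthetic frame with 48 nuclei and its ground truth."""
    return generate_frame(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
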