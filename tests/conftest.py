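import dataclasses

import numpy as np
import pytest

from nbihisto import phantom
from nbihisto.config import PipelineConfig


@pytest.fixture(scope="session")
def clean_cohort():
    """Twelve artifact-free phantoms, three per histology label."""
    return phantom.generate_set(
        [3, 3, 3, 3], base_spec=phantom.artifact_free(), seed=7, blur=False
    )


@pytest.fixture(scope="session")
def artifact_cohort():
    """Eight phantoms with injected blackout, halation and defocus."""
    return phantom.generate_set([2, 2, 2, 2], seed=11)


@pytest.fixture
def oracle_config():
    return dataclasses.replace(PipelineConfig(), backend="oracle")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def checkerboard(n=128, period=2, high=255.0):
    idx = np.indices((n, n)).sum(axis=0)
    return ((idx // (period // 2)) % 2).astype(np.float64) * high


def rgb_constant(shape, r, g, b):
    out = np.empty((*shape, 3), dtype=np.uint8)
    out[..., 0], out[..., 1], out[..., 2] = r, g, b
    return out
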