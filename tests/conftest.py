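"""Shared fixtures: a small, fast acquisition geometry for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from clusterecho.simulate import AcquisitionSpec, EchoSpec, SceneSpec


@pytest.fixture
def small_acq() -> AcquisitionSpec:
    """8 elements x 192 depth samples — cheap to simulate, still >= 160 deep."""
    return AcquisitionSpec(n_elements=8, n_samples=192)


@pytest.fixture
def small_scene() -> SceneSpec:
    return SceneSpec(
        n_frames=50,
        tunnel_depth_span=(16, 176),
        tunnel_element_span=(2, 5),
        seed=7,
    )


@pytest.fixture
def echo() -> EchoSpec:
    return EchoSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
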