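"""Shared fixtures: small protocols and scenes that keep unit tests fast."""

import numpy as np
import pytest

from insfoct import AcquisitionProtocol, SceneSpec, Vessel, default_scene
from insfoct.protocol import ResponseTemplate


@pytest.fixture(scope="session")
def small_protocol():
    """Short trial, small frame: 100 frames of 24 x 32 pixels."""
    return AcquisitionProtocol(prestim_s=0.2, stim_s=0.5, poststim_s=0.3,
                               n_trials=3, oct_fps=100.0, oisi_fps=20.0,
                               n_z=24, n_x=32)


@pytest.fixture(scope="session")
def small_scene(small_protocol):
    return default_scene(small_protocol)


@pytest.fixture
def quiet_scene(small_protocol):
    """No vessels, no noise, no trial jitter: deterministic template recovery."""
    scene = default_scene(small_protocol)
    return SceneSpec(reflectivity_map=scene.reflectivity_map,
                     activation_region=scene.activation_region,
                     vessels=[], noise_floor=0.0,
                     response_template=scene.response_template,
                     oisi_template=scene.oisi_template,
                     hemodynamic_template=None,
                     amplitude_cv=0.0, oisi_noise_fraction=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
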