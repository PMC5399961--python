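"""Shared fixtures: small deterministic recordings and the demo scene."""

from __future__ import annotations

import numpy as np
import pytest

from ar2eeg import AR2Config, EEGRecording, SceneConfig, run_ar2_recording, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng) -> EEGRecording:
    """19-channel Gaussian noise, 200 Hz, 20 s — enough for a 500-tap filter."""
    labels = [f"ch{i:02d}" for i in range(19)]
    return EEGRecording(labels=labels, fs_hz=200.0,
                        data_uv=rng.normal(0.0, 30.0, (19, 4000)))


@pytest.fixture(scope="session")
def demo_scene():
    """The default synthetic scene (seed 0) with its ground truth."""
    return simulate_scene(SceneConfig(seed=0))


@pytest.fixture(scope="session")
def demo_cleaned(demo_scene):
    """Demo scene run end to end once; shared across tests for speed."""
    rec, truth = demo_scene
    with np.errstate(all="ignore"):
        cleaned, report = run_ar2_recording(rec, AR2Config(seed=0))
    return cleaned, report
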