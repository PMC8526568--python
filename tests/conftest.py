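"""Shared fixtures: small, fast synthetic scenes and alignments."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lgt.pipeline import CorrectionToggles
from lgt.synthetic import SceneConfig, simulate_scene


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline stages warn on purpose (skipped frames etc.); keep logs clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """Compact scene (96×96, 10 frames) for fast unit tests."""
    return SceneConfig(shape=(96, 96), n_frames=10, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    """Rendered small scene: (stack, bundle, truth)."""
    return simulate_scene(small_config)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, artifact-light scene for exact round-trip checks."""
    from lgt.preprocess import AffineTransform

    cfg = SceneConfig(
        shape=(96, 96), n_frames=8, seed=21, shot_gain=0.0, read_sd=0.0,
        bleach=None, misregistration=AffineTransform.identity(),
    )
    return simulate_scene(cfg), cfg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
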