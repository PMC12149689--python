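"""Shared fixtures.

The trained model bundle is session-scoped and shared between the model unit
tests and the acceptance tests so the (CPU-minutes) training cost is paid
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from echoqc.config import RunConfig
from echoqc.phantom import generate_dataset

#: Scenario mix used for detector training: over-represents rotated hearts so
#: the angle head sees the full orientation range.
DETECTOR_BALANCE = {
    "standard": 3, "caa_low": 3, "caa_high": 3,
    "gain_low": 2, "gain_high": 2, "depth_low": 2, "depth_high": 2,
    "dropout_essential": 8, "dropout_valve": 1,
}

TRAIN_SEED = 11
HELDOUT_SEED = 99


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    cfg = RunConfig(seed=1)
    cfg.model.detector_epochs = 24
    cfg.model.phase_epochs = 30
    cfg.model.gain_epochs = 40
    return cfg


@pytest.fixture(scope="session")
def trained_bundle(run_config):
    """Backbone + all three heads, staged training on phantoms."""
    from echoqc.models import (
        phantom_training_sets,
        train_detector,
        train_gain,
        train_phase,
    )

    det_samples = generate_dataset(75, balance=DETECTOR_BALANCE, seed=TRAIN_SEED)
    det_set, _, _ = phantom_training_sets(det_samples, frames_per_video=2, seed=1)
    bundle = train_detector(det_set, run_config)

    aux_samples = generate_dataset(40, seed=TRAIN_SEED + 1)
    _, phase_set, gain_set = phantom_training_sets(aux_samples, frames_per_video=3, seed=2)
    bundle = train_phase(phase_set, bundle, run_config)
    bundle = train_gain(gain_set, bundle, run_config)
    return bundle


@pytest.fixture(scope="session")
def heldout_samples():
    return generate_dataset(12, seed=HELDOUT_SEED)


@pytest.fixture(scope="session")
def heldout_rendered(heldout_samples):
    return [s.build() for s in heldout_samples]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
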