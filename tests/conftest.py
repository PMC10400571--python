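"""Shared fixtures. The expensive cohort fixtures are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from blinkerp.config import NoiseConfig, PipelineConfig, ProtocolConfig
from blinkerp.dipolefit import HeadModel
from blinkerp.synthio import default_source_model, simulate_subject


@pytest.fixture(scope="session")
def headmodel() -> HeadModel:
    return HeadModel()


@pytest.fixture(scope="session")
def source_model():
    return default_source_model()


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseConfig:
    """No background at all; for exact signal-path checks."""
    return NoiseConfig(pink_rms_uv=0.0, sensor_white_rms_uv=0.0)


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """One short run; keeps rendering and ICA fast in unit tests."""
    return ProtocolConfig(n_runs=1, n_stimuli_per_run=25)


@pytest.fixture(scope="session")
def default_subject(source_model):
    """One subject simulated at full default conditions."""
    return simulate_subject(20250901, subject_id="sub-fix",
                            sources=source_model)


@pytest.fixture(scope="session")
def default_cohort_report():
    """Full pipeline on a study-sized default cohort (17 subjects).

    Shared by the planted-effect statistics and blink-behaviour tests; this
    is the single most expensive fixture in the suite.
    """
    from blinkerp.pipeline import run_pipeline

    config = PipelineConfig(n_subjects=17, master_seed=17)
    return run_pipeline(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
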