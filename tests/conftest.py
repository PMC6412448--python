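import numpy as np
import pytest

from pulsebp.simulate import (
    BeatTemplateParams,
    SimulationConfig,
    beat_params_from_bp,
    generate_recording,
)

FS = 250.0


@pytest.fixture
def template_params() -> BeatTemplateParams:
    """A well-separated two-bump beat at typical mid-range pressures."""
    return beat_params_from_bp(118.0, 70.0, hr_bpm=75.0)


@pytest.fixture(scope="session")
def clean_recording():
    """One noise-free recording plus its ground truth (shared, read-only)."""
    cfg = SimulationConfig(noise_sd=0.0, baseline_amp=0.0, artifact_prob=0.0)
    return generate_recording(cfg, (118.0, 70.0), seed=42,
                              record_id="clean", subject_id="s00")


@pytest.fixture(scope="session")
def noisy_recording():
    """One recording at the default noise conditions (shared, read-only)."""
    cfg = SimulationConfig()
    return generate_recording(cfg, (118.0, 70.0), seed=42,
                              record_id="noisy", subject_id="s00")
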