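import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fitts_erp.config import GeneratorConfig
from fitts_erp.design import build_design
from fitts_erp.preprocess import EpochSet


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def small_design():
    return build_design(n_blocks=3)


@pytest.fixture
def small_config():
    """Two subjects, three blocks: every design cell once per subject."""
    return GeneratorConfig(n_subjects=2, n_blocks=3, seed=7)


@pytest.fixture(scope="session")
def subject_recording():
    """One default-noise subject with all 9 cells (3 blocks), cached."""
    from fitts_erp.simulate import simulate_behaviour, simulate_recording

    cfg = GeneratorConfig(n_subjects=1, n_blocks=3, seed=11)
    d = build_design(n_blocks=3)
    trials = simulate_behaviour(d, cfg)
    return cfg, d, trials, simulate_recording(d, trials, cfg)


def make_epochs(data, fs_hz=500.0, channels=None, conditions=None,
                window_ms=None, lock="cue"):
    """Hand-built EpochSet around a plain array (epochs x ch x samples)."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, n_s = data.shape
    channels = channels or [f"ch{i}" for i in range(n_ch)]
    conditions = conditions or ["a"] * n_ep
    window_ms = window_ms or (0.0, n_s * 1000.0 / fs_hz)
    return EpochSet(data=data, fs_hz=fs_hz, channel_labels=list(channels),
                    conditions=list(conditions), lock_event=lock,
                    window_ms=tuple(window_ms))
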