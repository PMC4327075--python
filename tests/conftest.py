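import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enose.device import CycleConfig, characterization_config, default_array
from enose.simulator import PhaseMarks, ResponseCurve

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def array():
    return default_array()


@pytest.fixture(scope="session")
def char_cycle():
    return characterization_config()


@pytest.fixture
def short_cycle():
    return CycleConfig(baseline_purge_s=10, sampling_s=10, purge_s=10)


def make_curve(values, n_baseline, n_sampling, rate_hz=15.0, sensor_id=1):
    """Hand-build a ResponseCurve from raw sample values and phase sizes."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    return ResponseCurve(
        sensor_id=sensor_id,
        times_s=np.arange(n) / rate_hz,
        values_v=values,
        phase_marks=PhaseMarks(0, n_baseline, n_baseline + n_sampling),
        sampling_rate_hz=rate_hz,
    )


@pytest.fixture
def make_curve_fn():
    return make_curve
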