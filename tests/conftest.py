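import numpy as np
import pytest

import capblink as cb


@pytest.fixture(scope="session")
def default_model() -> cb.EyeDielectricModel:
    return cb.EyeDielectricModel()


@pytest.fixture(scope="session")
def default_circuit() -> cb.CircuitParams:
    return cb.CircuitParams()


@pytest.fixture(scope="session")
def ten_blink_schedule() -> cb.BlinkSchedule:
    """The worked scenario: 10 blinks in 40 s at 4 s spacing."""
    return cb.regular_schedule(
        [2, 6, 10, 14, 18, 22, 26, 30, 34, 38],
        duration=40.0,
        closing=0.15,
        hold=0.08,
        opening=0.25,
    )


@pytest.fixture(scope="session")
def bench_recording(ten_blink_schedule, default_model, default_circuit):
    """Bench-noise recording of the 10-blink scenario, seed 42."""
    f_open, f_closed = cb.frequency_pair(default_circuit, default_model)
    noise = cb.noise_preset("bench", f_open - f_closed, seed=42)
    series, labels = cb.generate_recording(
        ten_blink_schedule, model=default_model, circuit=default_circuit, fs=100.0, noise=noise
    )
    return series, labels


def _run_detection_pipeline(series: cb.FrequencySeries, order: int = 128) -> list[cb.BlinkEvent]:
    """Interpolate -> band-pass -> differentiate -> detect with defaults."""
    uniform = cb.gaussian_interpolate(series, period=0.01)
    filtered = cb.bandpass(uniform, cb.FilterSpec(order=order, passband=(2.0, 5.5), fs=100.0))
    deriv = cb.differentiate(filtered)
    return cb.detect(deriv)


@pytest.fixture(scope="session")
def run_detection_pipeline():
    return _run_detection_pipeline


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20241129)
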