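"""Seeded synthetic recordings and feature datasets with known ground truth.

Stands in for the electrode / capacitance-to-frequency hardware and for
human-subject sessions: every recording is generated from an explicit blink
schedule, so downstream stages (interpolation, filtering, detection, feature
extraction, fatigue regression) can be scored against exact labels.

The signal model: the baseline is the open-eye resonance frequency of the
configured LC tank and dielectric stack; during each scheduled blink the
frequency ramps to the closed-eye value and back along raised-cosine lid
trajectories (smooth ramps keep the injected spectrum inside the blink band,
unlike a square edge). On top of that go white measurement noise, slow
sinusoidal baseline drift (frame slip, temperature) and per-sample timestamp
jitter emulating asynchronous acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .capacitance import CircuitParams, EyeDielectricModel, frequency_pair
from .fatigue import FatigueSample
from .series import FrequencySeries

__all__ = [
    "BlinkInterval",
    "BlinkSchedule",
    "NoiseSpec",
    "noise_preset",
    "FeatureScaleMap",
    "generate_recording",
    "generate_feature_dataset",
    "random_schedule",
    "regular_schedule",
]


@dataclass(frozen=True)
class BlinkInterval:
    """One scheduled blink: onset plus the three lid-motion phase durations (s)."""

    onset: float
    closing: float
    hold: float
    opening: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        for name in ("closing", "hold", "opening"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} duration must be > 0")

    @property
    def end(self) -> float:
        return self.onset + self.closing + self.hold + self.opening


@dataclass(frozen=True)
class BlinkSchedule:
    """Ground-truth blink events for one recording.

    Events must be sorted by onset, non-overlapping and contained in
    ``[0, duration]``.
    """

    events: tuple[BlinkInterval, ...]
    duration: float

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if not self.duration > 0:
            raise ValueError("recording duration must be > 0")
        prev_end = 0.0
        prev_onset = -math.inf
        for ev in events:
            if ev.onset < prev_onset:
                raise ValueError("events must be sorted by onset")
            if ev.onset < prev_end:
                raise ValueError(
                    f"event at t={ev.onset} overlaps the previous event (ends {prev_end})"
                )
            if ev.end > self.duration:
                raise ValueError(
                    f"event ending at t={ev.end} exceeds recording duration {self.duration}"
                )
            prev_onset, prev_end = ev.onset, ev.end

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class NoiseSpec:
    """Disturbance model for one recording.

    white_sd: broadband measurement noise, Hz rms. drift_amplitude/period:
    slow sinusoidal baseline wander, Hz / s. jitter_sd: timestamp jitter, s.
    """

    white_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 30.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("white_sd", "drift_amplitude", "drift_period", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Noise presets as fractions of the blink drop amplitude: (white, drift amp,
#: drift period s, jitter sd s). "bench" = subject sitting still at a desk;
#: "walking"/"driving" add the frame shake of a moving subject as larger,
#: faster baseline wander.
_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "none": (0.0, 0.0, 30.0, 0.0),
    "bench": (0.005, 0.05, 30.0, 5e-4),
    "driving": (0.02, 0.3, 5.0, 1e-3),
    "walking": (0.05, 0.8, 1.5, 1e-3),
}


def noise_preset(name: str, drop_amplitude: float, seed: int = 0) -> NoiseSpec:
    """Noise regime scaled to the blink drop amplitude of the configured model."""
    try:
        white, drift, period, jitter = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown noise preset {name!r}; choose from {sorted(_PRESETS)}")
    return NoiseSpec(
        white_sd=white * drop_amplitude,
        drift_amplitude=drift * drop_amplitude,
        drift_period=period,
        jitter_sd=jitter,
        seed=seed,
    )


def _lid_position(t: np.ndarray, ev: BlinkInterval) -> np.ndarray:
    """Lid closure fraction in [0, 1] over times ``t`` for one blink.

    Raised-cosine ramps: 0.5 (1 - cos(pi u)) rises smoothly from 0 to 1 with
    zero slope at both ends.
    """
    p = np.zeros_like(t)
    t0, t1 = ev.onset, ev.onset + ev.closing
    t2, t3 = t1 + ev.hold, ev.end
    closing = (t >= t0) & (t < t1)
    u = (t[closing] - t0) / ev.closing
    p[closing] = 0.5 * (1.0 - np.cos(np.pi * u))
    p[(t >= t1) & (t < t2)] = 1.0
    opening = (t >= t2) & (t < t3)
    u = (t[opening] - t2) / ev.opening
    p[opening] = 0.5 * (1.0 + np.cos(np.pi * u))
    return p


def generate_recording(
    schedule: BlinkSchedule,
    model: EyeDielectricModel | None = None,
    circuit: CircuitParams | None = None,
    fs: float = 100.0,
    noise: NoiseSpec | None = None,
) -> tuple[FrequencySeries, BlinkSchedule]:
    """Simulate one resonance-frequency recording; returns (series, labels).

    The labels are the schedule itself. With ``noise=None`` (or an all-zero
    spec) the output is the exact noiseless forward model, whose per-event
    drop equals the open/closed resonance-frequency difference.
    """
    model = model or EyeDielectricModel()
    circuit = circuit or CircuitParams()
    noise = noise or NoiseSpec()
    if fs < 20.0:
        raise ValueError(f"fs must be >= 20 Hz to resolve the blink band, got {fs}")

    rng = np.random.default_rng(noise.seed)
    n = int(round(schedule.duration * fs))
    base_times = np.arange(n) / fs
    times = base_times
    if noise.jitter_sd > 0:
        jitter = rng.normal(0.0, noise.jitter_sd, size=n)
        # keep timestamps strictly increasing
        np.clip(jitter, -0.45 / fs, 0.45 / fs, out=jitter)
        times = base_times + jitter
        times[0] = max(times[0], 0.0)

    f_open, f_closed = frequency_pair(circuit, model)
    closure = np.zeros(n)
    for ev in schedule.events:
        closure += _lid_position(times, ev)
    np.clip(closure, 0.0, 1.0, out=closure)
    values = f_open + (f_closed - f_open) * closure

    if noise.drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        values = values + noise.drift_amplitude * np.sin(
            2.0 * np.pi * times / noise.drift_period + phase
        )
    if noise.white_sd > 0:
        values = values + rng.normal(0.0, noise.white_sd, size=n)

    return FrequencySeries(times, values), schedule


def regular_schedule(
    onsets: "list[float] | np.ndarray",
    duration: float,
    closing: float = 0.15,
    hold: float = 0.08,
    opening: float = 0.25,
) -> BlinkSchedule:
    """Schedule with identical kinematics at the given onsets."""
    events = tuple(BlinkInterval(float(t), closing, hold, opening) for t in onsets)
    return BlinkSchedule(events=events, duration=duration)


def random_schedule(
    duration: float,
    n_events: int,
    seed: int = 0,
    closing_range: tuple[float, float] = (0.1, 0.2),
    hold_range: tuple[float, float] = (0.05, 0.1),
    opening_range: tuple[float, float] = (0.15, 0.3),
    min_gap: float = 1.0,
) -> BlinkSchedule:
    """Random non-overlapping blink schedule with physiological kinematics.

    Default phase ranges follow normal human blinks (total 0.2-0.4 s, the
    2.5-5 Hz band the band-pass filter targets).
    """
    rng = np.random.default_rng(seed)
    max_len = closing_range[1] + hold_range[1] + opening_range[1]
    usable = duration - n_events * (max_len + min_gap)
    if usable < 0:
        raise ValueError(f"cannot place {n_events} events with min_gap={min_gap} in {duration}s")
    # stick-breaking onsets: random slack split across the gaps
    slack = rng.dirichlet(np.ones(n_events + 1)) * usable
    events = []
    t = 0.5 * min_gap + slack[0]
    for i in range(n_events):
        ev = BlinkInterval(
            onset=float(t),
            closing=float(rng.uniform(*closing_range)),
            hold=float(rng.uniform(*hold_range)),
            opening=float(rng.uniform(*opening_range)),
        )
        events.append(ev)
        t = ev.end + min_gap + slack[i + 1]
    return BlinkSchedule(events=tuple(events), duration=duration)


@dataclass(frozen=True)
class FeatureScaleMap:
    """Affine blink-feature to fatigue-scale mapping used as generator ground truth.

    scale = clamp(intercept + w_closing*closing + w_opening*opening
                  + w_idle*idle, 10, 50)

    Fatigued drivers blink slower and less often, so the closing/opening
    weights are positive and the idle weight negative by default.
    """

    intercept: float = 10.0
    w_closing: float = 60.0
    w_opening: float = 40.0
    w_idle: float = -2.0

    def raw(self, closing: np.ndarray, opening: np.ndarray, idle: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + self.w_closing * closing
            + self.w_opening * opening
            + self.w_idle * idle
        )

    def __call__(self, closing: np.ndarray, opening: np.ndarray, idle: np.ndarray) -> np.ndarray:
        return np.clip(self.raw(closing, opening, idle), 10.0, 50.0)


def generate_feature_dataset(
    n: int,
    mapping: FeatureScaleMap | None = None,
    noise_sd: float = 1.5,
    seed: int = 0,
    closing_range: tuple[float, float] = (0.1, 0.5),
    opening_range: tuple[float, float] = (0.15, 0.6),
    idle_range: tuple[float, float] = (1.0, 10.0),
) -> list[FatigueSample]:
    """Labelled (closing, opening, idle) -> fatigue-scale samples.

    Features are drawn uniformly from physiological windows; the scale is the
    mapping output plus Gaussian self-report noise, clamped to the
    questionnaire range [10, 50].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mapping = mapping or FeatureScaleMap()
    rng = np.random.default_rng(seed)
    closing = rng.uniform(*closing_range, size=n)
    opening = rng.uniform(*opening_range, size=n)
    idle = rng.uniform(*idle_range, size=n)
    scale = mapping.raw(closing, opening, idle)
    if noise_sd > 0:
        scale = scale + rng.normal(0.0, noise_sd, size=n)
    scale = np.clip(scale, 10.0, 50.0)
    return [
        FatigueSample(
            closing=float(c), opening=float(o), idle=float(i), scale=float(s)
        )
        for c, o, i, s in zip(closing, opening, idle, scale)
    ]
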