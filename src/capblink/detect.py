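"""Threshold blink detection on the differentiated frequency trace.

The eye closing drives the resonance frequency down, the opening back up, so
one blink appears in the time derivative as a negative lobe followed by a
positive lobe. Detection proceeds frame by frame:

1. central-difference differentiation of the (filtered) series;
2. rescaling by a rolling robust noise scale so the threshold is
   dimensionless and transfers across hardware gains — 4.0 means "four
   robust noise scales";
3. supra-threshold runs of |d| are merged across short gaps (the closed-eye
   hold between the two lobes of one blink) into candidate events;
4. each candidate gets a fused confidence, the geometric mean of its
   amplitude excess (peak |d| / threshold) and duration excess
   (supra-threshold time / minimum duration); a blink is declared when the
   confidence exceeds 1.

Phase durations are read from the derivative's sign structure: the closing
time is the width of the negative lobe around the candidate's negative peak,
the opening time the width of the following positive lobe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import FrequencySeries

__all__ = [
    "DetectorConfig",
    "BlinkEvent",
    "BlinkFeatures",
    "differentiate",
    "detect",
    "extract_features",
    "sliding_windows",
]

#: Conversion from median absolute deviation to Gaussian-equivalent sigma.
MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class DetectorConfig:
    """Detection parameters.

    threshold: derivative magnitude in robust noise units (dimensionless).
    min_exceed_duration: supra-threshold time (s) at which the duration
    factor of the confidence reaches 1. refractory: maximum gap (s) merged
    into one candidate; it must exceed both the closed-eye hold separating
    the two lobes of one blink and the gaps between a blink and the decaying
    ringing echoes of the sharp band-pass, while staying below the minimum
    inter-blink interval (~1 s). scale_window: length (s)
    of the rolling window for the robust scale. amp_weight/dur_weight:
    exponents of the two confidence factors (0.5/0.5 = geometric mean).
    lobe_fraction: samples count toward a closing/opening lobe only while
    the derivative magnitude stays above ``lobe_fraction * threshold``,
    which keeps numerical dust and sub-noise flickers out of the phase
    durations. lobe_peak_fraction: within one candidate the earliest lobe
    whose peak reaches this fraction of the strongest lobe is taken as the
    phase lobe — the sharp band-pass rings after a blink, and a late echo
    can slightly exceed the true closing lobe, so picking the global
    extremum would date the onset at the echo.
    """

    threshold: float = 4.0
    min_exceed_duration: float = 0.05
    refractory: float = 0.45
    scale_window: float = 10.0
    amp_weight: float = 0.5
    dur_weight: float = 0.5
    lobe_fraction: float = 0.25
    lobe_peak_fraction: float = 0.7
    raw_units: bool = False

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        for name in ("min_exceed_duration", "refractory", "scale_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BlinkEvent:
    """One detected blink with its phase durations (s) and confidence."""

    onset: float
    closing: float
    opening: float
    confidence: float

    def __post_init__(self) -> None:
        if not (self.closing > 0 and self.opening > 0):
            raise ValueError("phase durations must be > 0")
        if not self.confidence > 1:
            raise ValueError("emitted events must have confidence > 1")

    @property
    def end(self) -> float:
        return self.onset + self.closing + self.opening


@dataclass(frozen=True)
class BlinkFeatures:
    """Per-window blink aggregates fed to the fatigue network."""

    window_start: float
    closing: float
    opening: float
    idle: float
    count: int

    def __post_init__(self) -> None:
        for name in ("closing", "opening", "idle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")

    @property
    def features(self) -> tuple[float, float, float]:
        return (self.closing, self.opening, self.idle)


def _rolling_robust_scale(d: np.ndarray, window: int) -> np.ndarray:
    """Rolling MAD-based sigma estimate with a floor against all-quiet windows."""
    window = max(3, min(window, d.size) | 1)  # odd, at most series length
    med = ndimage.median_filter(d, size=window, mode="reflect")
    mad = ndimage.median_filter(np.abs(d - med), size=window, mode="reflect")
    scale = MAD_TO_SIGMA * mad
    peak = float(np.max(np.abs(d))) if d.size else 0.0
    floor = max(1e-12, 1e-9 * peak)
    return np.maximum(scale, floor)


def differentiate(
    series: FrequencySeries, cfg: DetectorConfig | None = None, rescale: bool = True
) -> FrequencySeries:
    """Central-difference derivative, optionally in dimensionless detector units.

    With ``rescale`` (the default, unless ``cfg.raw_units`` is set) the
    derivative is divided by its rolling robust scale (MAD over
    ``cfg.scale_window`` seconds, Gaussian-calibrated), making the 4.0
    threshold meaningful regardless of the front end's Hz-per-blink gain.
    Without it the units are Hz/s.
    """
    cfg = cfg or DetectorConfig()
    if len(series) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d = np.gradient(series.values, series.times)
    if rescale and not cfg.raw_units:
        fs = series.sample_rate
        window = int(round(cfg.scale_window * fs))
        d = d / _rolling_robust_scale(d, window)
    return FrequencySeries(series.times, d)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def _first_strong_lobe(
    magnitude: np.ndarray, sign_ok: np.ndarray, start: int, stop: int, peak_fraction: float
) -> tuple[int, int] | None:
    """Earliest sign-consistent lobe in [start, stop) whose peak reaches
    ``peak_fraction`` of the strongest lobe there, as absolute [start, stop)
    indices; ``None`` when the range holds no lobe at all."""
    lobes = _runs(sign_ok[start:stop])
    if not lobes:
        return None
    peaks = [float(magnitude[start + a : start + b].max()) for a, b in lobes]
    cutoff = peak_fraction * max(peaks)
    for (a, b), peak in zip(lobes, peaks):
        if peak >= cutoff:
            return start + a, start + b
    return start + lobes[0][0], start + lobes[0][1]


def detect(deriv: FrequencySeries, cfg: DetectorConfig | None = None) -> list[BlinkEvent]:
    """Frame-by-frame threshold detection on a derivative series.

    Returns the emitted blink events (confidence > 1) sorted by onset. The
    onset is the start of the closing (negative-derivative) lobe.
    """
    cfg = cfg or DetectorConfig()
    d = deriv.values
    t = deriv.times
    dt = deriv.median_dt
    if dt <= 0:
        return []

    mask = np.abs(d) > cfg.threshold
    runs = _runs(mask)
    if not runs:
        return []

    # merge candidate runs separated by less than the refractory gap
    gap_limit = cfg.refractory
    merged: list[tuple[int, int]] = [runs[0]]
    for a, b in runs[1:]:
        if t[a] - t[merged[-1][1] - 1] < gap_limit:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    lobe_eps = cfg.lobe_fraction * cfg.threshold
    neg = d < -lobe_eps
    pos = d > lobe_eps
    events: list[BlinkEvent] = []
    for a, b in merged:
        seg = d[a:b]
        c_amp = float(np.max(np.abs(seg))) / cfg.threshold
        exceed_time = float(np.count_nonzero(np.abs(seg) > cfg.threshold)) * dt
        if cfg.min_exceed_duration > 0:
            c_dur = exceed_time / cfg.min_exceed_duration
        else:
            c_dur = 1.0
        confidence = (c_amp**cfg.amp_weight) * (c_dur**cfg.dur_weight)
        if not confidence > 1.0:
            continue

        # closing lobe: earliest strong negative lobe in the candidate
        closing_lobe = _first_strong_lobe(np.abs(d), neg, a, b, cfg.lobe_peak_fraction)
        if closing_lobe is not None:
            n0, n1 = closing_lobe
            while n0 > 0 and neg[n0 - 1]:  # lobe tails extend past the run edges
                n0 -= 1
            while n1 < d.size and neg[n1]:
                n1 += 1
        else:  # degenerate: no negative excursion; treat run start as onset
            n0, n1 = a, a + max(1, (b - a) // 2)
        # opening lobe: earliest strong positive lobe after the closing lobe
        j_max = int(np.searchsorted(t, t[min(n1, d.size - 1)] + 2.0 * gap_limit))
        opening_lobe = _first_strong_lobe(np.abs(d), pos, n1, j_max, cfg.lobe_peak_fraction)
        if opening_lobe is not None:
            p0, p1 = opening_lobe
            while p1 < d.size and pos[p1]:
                p1 += 1
        else:
            p0, p1 = n1, n1 + 1
        # central differencing widens each lobe by one sample per side
        closing = max(n1 - n0 - 2, 1) * dt
        opening = max(p1 - p0 - 2, 1) * dt
        events.append(
            BlinkEvent(
                onset=float(t[n0]),
                closing=closing,
                opening=opening,
                confidence=confidence,
            )
        )
    events.sort(key=lambda e: e.onset)
    return events


def extract_features(
    events: list[BlinkEvent], window: tuple[float, float]
) -> BlinkFeatures:
    """Aggregate blink features over one window (start, length).

    Means of closing and opening time over events whose onset falls in the
    window; idle time is the mean gap from the end of one blink's opening to
    the next blink's onset. Windows with fewer than two events have no gap,
    so the idle time falls back to the un-blinked span of the window (the
    full window length when there are no events at all).
    """
    start, length = window
    if length <= 0:
        raise ValueError("window length must be > 0")
    inside = [e for e in events if start <= e.onset < start + length]
    count = len(inside)
    if count == 0:
        return BlinkFeatures(window_start=start, closing=0.0, opening=0.0, idle=length, count=0)
    closing = float(np.mean([e.closing for e in inside]))
    opening = float(np.mean([e.opening for e in inside]))
    if count >= 2:
        gaps = [nxt.onset - prev.end for prev, nxt in zip(inside, inside[1:])]
        idle = float(np.mean(gaps))
    else:
        idle = max(length - (closing + opening) * count, 0.0)
    return BlinkFeatures(
        window_start=start, closing=closing, opening=opening, idle=idle, count=count
    )


def sliding_windows(
    series: FrequencySeries, window_s: float = 40.0, step_s: float = 2.0
) -> list[tuple[float, float]]:
    """(start, length) windows at starts 0, step, 2*step, ... fully inside the series.

    The series duration counts one trailing sample period, so a recording of
    exactly n/fs seconds yields its nominal window count.
    """
    if step_s <= 0:
        raise ValueError("step must be > 0")
    duration = series.duration
    t0 = float(series.times[0])
    windows = []
    k = 0
    while k * step_s + window_s <= duration + 1e-9:
        windows.append((t0 + k * step_s, window_s))
        k += 1
    return windows
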