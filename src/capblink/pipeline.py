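"""End-to-end pipeline: simulate (or load) -> preprocess -> detect -> score.

``run_pipeline`` mirrors the full recognition procedure: a recording is
simulated from the configured blink schedule (or supplied by the caller),
interpolated onto a uniform grid, band-pass filtered, differentiated and
thresholded into blink events; per-window blink features are extracted and,
if a fatigue model is available (one is trained on a synthetic feature
dataset by default), converted to a fatigue scale per window. Every stage
logs its parameters and output counts, and any stage failure is re-raised
with the stage name.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np

from . import fatigue as fg
from . import preprocess as pp
from . import synth
from .detect import (
    BlinkEvent,
    DetectorConfig,
    detect as run_detect,
    differentiate,
    extract_features,
    sliding_windows,
)
from .capacitance import CircuitParams, EyeDielectricModel, frequency_pair
from .config import PipelineConfig, stage_seed
from .series import FrequencySeries

__all__ = ["run_pipeline", "PipelineError", "build_models", "preprocess_series", "detect_events"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def build_models(config: PipelineConfig) -> tuple[EyeDielectricModel, CircuitParams]:
    cap = config.capacitance
    model = EyeDielectricModel(
        eps_air=cap.eps[0],
        eps_lid=cap.eps[1],
        eps_tissue=cap.eps[2],
        d_air=cap.d[0],
        d_lid=cap.d[1],
        d_tissue=cap.d[2],
        plate_area=cap.S,
        k=cap.k,
    )
    circuit = CircuitParams(inductance=cap.L, capacitance=cap.C)
    return model, circuit


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def simulate_recording(config: PipelineConfig) -> tuple[FrequencySeries, synth.BlinkSchedule]:
    model, circuit = build_models(config)
    sc = config.synth
    schedule = synth.regular_schedule(
        sc.onsets, duration=sc.duration, closing=sc.closing, hold=sc.hold, opening=sc.opening
    )
    f_open, f_closed = frequency_pair(circuit, model)
    noise = synth.noise_preset(
        sc.noise_preset, drop_amplitude=f_open - f_closed, seed=stage_seed(config.seed, "noise")
    )
    series, labels = synth.generate_recording(
        schedule, model=model, circuit=circuit, fs=sc.fs, noise=noise
    )
    logger.info(
        "simulate: %d samples, %d scheduled blinks, preset=%s", len(series), len(labels), sc.noise_preset
    )
    return series, labels


def preprocess_series(series: FrequencySeries, config: PipelineConfig) -> FrequencySeries:
    ic = config.interp
    uniform = pp.gaussian_interpolate(
        series, period=ic.T, sigma=ic.sigma, half_width=ic.half_width, unnormalized=ic.unnormalized
    )
    if np.isnan(uniform.values).any():
        filled = np.array(uniform.values)
        good = ~np.isnan(filled)
        filled[~good] = np.interp(uniform.times[~good], uniform.times[good], filled[good])
        uniform = FrequencySeries(uniform.times, filled)
    spec = pp.FilterSpec(order=config.filter.order, passband=config.filter.band, fs=1.0 / ic.T)
    filtered = pp.bandpass(uniform, spec)
    logger.info(
        "preprocess: T=%g s, band=%s Hz, order=%d, %d samples",
        ic.T, config.filter.band, config.filter.order, len(filtered),
    )
    return filtered


def detect_events(filtered: FrequencySeries, config: PipelineConfig) -> list[BlinkEvent]:
    dc = config.detector
    cfg = DetectorConfig(
        threshold=dc.threshold,
        min_exceed_duration=dc.min_exceed_duration,
        refractory=dc.refractory,
        scale_window=dc.scale_window,
        raw_units=dc.raw_units,
    )
    deriv = differentiate(filtered, cfg)
    events = run_detect(deriv, cfg)
    logger.info("detect: threshold=%g -> %d events", dc.threshold, len(events))
    return events


def run_pipeline(
    config: PipelineConfig | None = None,
    series: FrequencySeries | None = None,
    model: fg.FatigueNetwork | None = None,
    truth_scales: "list[float] | None" = None,
) -> dict[str, Any]:
    """Run the full recognition pipeline and return the report dict.

    Parameters
    ----------
    config:
        Validated pipeline configuration (defaults if omitted).
    series:
        Pre-recorded series; simulated from the config's schedule if omitted.
    model:
        Trained fatigue network; if omitted one is trained on a synthetic
        feature dataset derived from the config seed.
    truth_scales:
        Optional per-window true fatigue scales; when given, the report
        includes the relative-error accuracy of the window predictions.
    """
    config = config or PipelineConfig()
    labels = None
    if series is None:
        series, labels = _stage("simulate")(simulate_recording, config)
    filtered = _stage("preprocess")(preprocess_series, series, config)
    events = _stage("detect")(detect_events, filtered, config)

    windows = _stage("features")(
        sliding_windows, filtered, config.window.length, config.window.step
    )
    features = [extract_features(events, w) for w in windows]

    if model is None:
        tc = config.train
        samples = synth.generate_feature_dataset(
            n=tc.dataset_size, noise_sd=tc.noise_sd, seed=stage_seed(config.seed, "dataset")
        )
        model = _stage("train")(
            fg.train,
            samples,
            fg.TrainConfig(
                iterations=tc.iterations,
                learning_rate=tc.learning_rate,
                train_fraction=tc.train_fraction,
                seed=stage_seed(config.seed, "train"),
            ),
        )
    scales = [
        float(fg.predict(model, f.features)) if f.count > 0 else None for f in features
    ]

    report: dict[str, Any] = {
        "config": config.model_dump(),
        "n_samples": len(series),
        "events": [
            {
                "onset_s": e.onset,
                "closing_s": e.closing,
                "opening_s": e.opening,
                "confidence": e.confidence,
            }
            for e in events
        ],
        "n_events": len(events),
        "windows": [
            {
                "window_start_s": f.window_start,
                "closing_s": f.closing,
                "opening_s": f.opening,
                "idle_s": f.idle,
                "count": f.count,
                "fatigue_scale": s,
            }
            for f, s in zip(features, scales)
        ],
    }
    if labels is not None:
        report["scheduled_events"] = len(labels)
    if truth_scales is not None:
        preds = [s for s in scales if s is not None]
        truths = list(truth_scales)[: len(preds)]
        if preds and len(preds) == len(truths):
            report["accuracy_pct"] = fg.accuracy(preds, truths)
    return report
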