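"""Generate a labelled synthetic recording and detect every blink in it.

Ten blinks are scheduled over 40 s, the physics model turns the eyelid
motion into a resonance-frequency trace, and the bench noise preset adds
white noise, slow drift and timestamp jitter. The detection chain is
Gaussian resampling -> blink-band filtering -> differentiation ->
threshold/confidence detection.
"""

import capblink as cb

# --- synthesize -------------------------------------------------------------
schedule = cb.regular_schedule(
    [2, 6, 10, 14, 18, 22, 26, 30, 34, 38],
    duration=40.0, closing=0.15, hold=0.08, opening=0.25,
)
model, circuit = cb.EyeDielectricModel(), cb.CircuitParams()
f_open, f_closed = cb.frequency_pair(circuit, model)
noise = cb.noise_preset("bench", f_open - f_closed, seed=42)
series, labels = cb.generate_recording(
    schedule, model=model, circuit=circuit, fs=100.0, noise=noise
)
print(f"recording: {len(series)} samples, {series.duration:.2f} s, "
      f"{len(labels.events)} scheduled blinks")

# --- preprocess -------------------------------------------------------------
uniform = cb.gaussian_interpolate(series, period=0.01)
filtered = cb.bandpass(uniform, cb.FilterSpec(order=128, passband=(2.0, 5.5), fs=100.0))

# --- detect -----------------------------------------------------------------
events = cb.detect(cb.differentiate(filtered))
print(f"detected: {len(events)} events\n")
print(f"{'true onset':>10} {'onset':>7} {'closing':>8} {'opening':>8} {'confidence':>11}")
for true, got in zip(labels.events, events):
    print(f"{true.onset:>10.2f} {got.onset:>7.2f} {got.closing:>8.2f} "
          f"{got.opening:>8.2f} {got.confidence:>11.1f}")

# --- per-window features ----------------------------------------------------
feats = cb.extract_features(events, window=(0.0, 40.0))
print(f"\nwindow features: closing {feats.closing:.3f} s, opening {feats.opening:.3f} s, "
      f"idle {feats.idle:.2f} s, count {feats.count}")
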