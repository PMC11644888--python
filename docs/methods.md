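# Methods

This note records the models, algorithms and parameter choices implemented
in `capblink`, in the package's own terms.

## 1. Electrostatic and circuit model

The electrode–eye capacitor is a parallel-plate stack of homogeneous
dielectric layers. A single layer of permittivity ε, thickness d and plate
area S has capacitance

```
C = ε S / (4 π k d),      k = 8.99e9 N·m²/C² (Coulomb constant)
```

and layers in series combine as reciprocals. With the eye **closed** the
stack is air gap (ε₁, d₁) / eyelid (ε₂, d₂) / eye tissue (ε₃, d₃):

```
Cx_closed = S / (4 π k (d₁/ε₁ + d₂/ε₂ + d₃/ε₃))
```

With the eye **open** the eyelid retracts and its former position is filled
by air, so the first two layers merge into one air layer of thickness
d₁ + d₂:

```
Cx_open = S / (4 π k ((d₁ + d₂)/ε₁ + d₃/ε₃))
```

The sensed capacitance loads an LC tank; the oscillation frequency is

```
f = 1 / (2 π sqrt(L (C + Cx)))
```

so a blink (Cx up) is a frequency dip. Defaults: d = 5 / 1 / 50 mm,
ε = 1 / 100 / 100 (eyelid and tissue behave like moist biological tissue),
S = 2 cm² (a 25 mm × 8 mm frame electrode), L = 18 µH, C = 33 pF. These
give Cx_open = 0.2724 pF, Cx_closed = 0.3213 pF (ratio 1.1797 — the
closed-form ratio is (d₁/ε₁ + d₂/ε₂ + d₃/ε₃)⁻¹ · ((d₁+d₂)/ε₁ + d₃/ε₃) =
6.5/5.51 with the defaults), f_open = 6,503,424 Hz and a blink dip of
4,777 Hz. The defaults are the generator's *study conditions*; every value
is overridable through `EyeDielectricModel` / `CircuitParams`.

## 2. Synthetic signal generator

A blink is parameterized by onset, closing, hold and opening durations. The
lid position follows a raised-cosine ramp in each moving phase (smooth
start/stop, zero velocity at the endpoints), which interpolates the sensed
capacitance between its open and closed values; the frequency trace follows
from the circuit model. Scheduled kinematics default to closing 0.15 s,
hold 0.08 s, opening 0.25 s; `random_schedule` draws them uniformly from
0.10–0.20 / 0.05–0.10 / 0.15–0.30 s with at least 1 s between blinks.

Noise is scaled to the blink dip amplitude so presets transfer across
geometries:

| preset  | white noise sd | drift amplitude | drift period | time jitter |
|---------|----------------|-----------------|--------------|-------------|
| bench   | 0.5% of dip    | 5% of dip       | 30 s         | 0.5 ms      |
| driving | 2% of dip      | 30% of dip      | 5 s          | 1 ms        |
| walking | 5% of dip      | 80% of dip      | 1.5 s        | 1 ms        |

Timestamp jitter is clipped to ±0.45 sample periods so sample order is
preserved. The feature-dataset generator draws window features
closing ~ U(0.1, 0.5) s, opening ~ U(0.15, 0.6) s, idle ~ U(1, 10) s and
labels them with the monotone mapping

```
scale = clamp(10 + 60·closing + 40·opening − 2·idle + N(0, σ), 10, 50)
```

(slower blinks and shorter idle gaps = more fatigued; σ = 1.5 scale points
by default). Noise is added to the unclamped value and the result clamped
once, so boundary labels saturate the way a bounded questionnaire does.

## 3. Preprocessing

**Resampling.** Front-end samples arrive with timestamp jitter, so the
series is resampled onto the uniform grid t = nT by Gaussian-weighted
averaging: each grid point averages the samples within 3σ, weighted by
exp(−(tᵢ − nT)²/2σ²)/√(2π), with σ = T = 10 ms by default. Weights are
renormalized per grid point so the result is a proper weighted mean (a
constant signal is a fixed point); `unnormalized=True` skips the
renormalization, leaving a raw weighted sum that scales with local sample
density. Grid points with an empty neighborhood become NaN and are logged.
The grid covers points within T/2 of the data range, so jitter on the first
or last sample cannot shrink the nominal duration.

**Band-pass.** Blink energy lives at a few Hz; drift sits below and sensor
noise above. The filter is a Butterworth band-pass over [2.0, 5.5] Hz at
fs = 100 Hz, nominal overall order 128, applied forward-backward
(`sosfiltfilt`), which doubles the attenuation and cancels phase delay —
phase linearity matters because the detector reads durations off the
waveform. The design is built in second-order sections for numerical
stability (`butter(order/2, …, output="sos")`; order means overall filter
order, so 64 biquads). The section gains are validated against the expected
response at design time; if a pathological design slips through, the
implementation falls back to order 8 with a warning — at these band edges
the order-128 SOS design is stable, and the fallback is a safety net. The
series mean is removed before filtering: the MHz carrier offset is ~10³×
the blink amplitude, and removing it keeps the filter state well scaled.

## 4. Blink detection

The filtered series is differentiated (central differences) and divided by
a rolling robust noise scale — 1.4826 × the rolling median absolute
deviation over a 10 s window, with a small floor — so the detection
threshold is dimensionless and transfers across hardware gains. Detection
is frame-by-frame:

1. samples with |d| > 4.0 robust units form candidate runs;
2. runs separated by less than the **refractory gap, 0.45 s**, merge into
   one candidate. This gap must cover both the closed-eye hold between the
   closing and opening lobes of one blink (≤ ~0.1 s) and the decaying
   ringing echoes of the sharp band-pass, which were measured up to
   ~0.41 s after the main response; it stays well below the ≥ 1 s minimum
   inter-blink interval, so distinct blinks never merge;
3. each candidate's confidence is the geometric mean of its amplitude
   excess (peak |d| / threshold) and duration excess (supra-threshold time
   / 0.05 s); an event is emitted when confidence > 1. The fused score
   rejects both short spikes (high amplitude, no duration) and long
   low-level wobble;
4. phase durations come from the derivative's sign structure. Within a
   candidate, the closing lobe is the **earliest** negative lobe whose peak
   reaches 70% of the strongest one (`lobe_peak_fraction`) — the global
   minimum is not used because a post-opening ringing echo can slightly
   exceed the true closing lobe and would date the onset at the echo. The
   opening lobe is found the same way among positive lobes after the
   closing lobe. Samples count toward a lobe only while |d| stays above
   25% of the threshold (`lobe_fraction`), keeping numerical dust out of
   the durations, and one sample per side is subtracted to undo the
   widening introduced by central differencing. On noiseless synthetic
   schedules this recovers closing/opening durations within one sample
   period (10 ms).

Per 40 s window (2 s step), features are the means of closing time,
opening time and idle time (gap from the end of one blink's opening to the
next onset); windows with fewer than two events fall back to the
un-blinked span of the window.

## 5. Fatigue regression

Ground truth is a fatigue self-assessment questionnaire: ten statements
rated 1–5, summed to 10–50. The regressor is a fixed 3-5-1 multilayer
perceptron — three inputs (closing, opening, idle), five sigmoid hidden
units, one linear output — trained by full-batch gradient descent on mean
squared error for 2000 iterations at learning rate 0.5. Features are
z-scored and the target mapped to [0, 1] internally; predictions are mapped
back and clamped to [10, 50]. The per-iteration loss trajectory is stored
on the trained network (it flattens by ~1500 iterations on the synthetic
task). Training is deterministic given a seed and invariant to sample
order (full-batch gradients are sums). Reported accuracy is

```
r = (1 − mean |predicted − true| / true) · 100%
```

the mean absolute relative error subtracted from 100%; a `signed` variant
drops the absolute value so over- and under-predictions cancel. On 8,343
synthetic windows with 1.5-point label noise and an 80/20 split, hold-out
accuracy averages ≈ 95.7% over seeds (the irreducible part being the label
noise itself).

The training loop is hand-rolled in numpy because the fixed architecture,
training schedule and loss trajectory are part of the package's contract;
the test suite cross-checks it against scikit-learn's `MLPRegressor` on the
same task.

## 6. Reproducibility

All stochastic stages (synthesis noise, dataset generation, splits, weight
initialization) take explicit seeds; the pipeline derives per-stage seeds
from one master seed via `numpy.random.SeedSequence` spawning, so stages
are decorrelated but fully determined. `scripts/acceptance.py` recomputes
the two headline targets from a single `--seed` and is bit-identical across
reruns with the same seed.

## 7. Limitations

- The generator covers the dominant physics and stationary noise; real
  recordings add electrode drift with posture, motion artifacts correlated
  with blinks, and person-to-person geometry differences.
- The feature-to-scale mapping is an assumed monotone surrogate; accuracy
  numbers measure pipeline consistency on that surrogate, not validity of
  the fatigue construct.
- The detector is tuned for isolated blinks ≥ 1 s apart; blink flurries
  closer than the 0.45 s refractory gap would merge into one event.
- Window features need ≥ 2 events for a defined inter-blink idle time;
  sparse windows fall back to a coarser idle estimate.
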