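# Methods

## Scope and model

The package analyses tethered hexapod walking on an air-supported sphere
along three coordinated axes: (1) inter-leg timing from gait events, (2)
body kinematics from the sphere's motion, (3) muscle coordination from EMG.
All three share one statistical backbone — angles on the circle summarised
by the mean unit vector (direction θ̂, resultant length R) — because leg
touchdowns, burst timings and cross-spectrum phases are all cyclic
quantities defined relative to a gait period.

### Inter-leg phase

The phase of a target leg within reference cycle *i* is
φᵢ = 2π(t_TD(i)_tgt − t_TD(i)_ref)/T_period(i)_ref with
T_period(i) = t_TD(i+1)_ref − t_TD(i)_ref. Cycle pairing takes the first
target touchdown at or after the reference touchdown and before the next
one; this makes φ ∈ [0, 2π) by construction, and cycles with no target
event are skipped and counted rather than interpolated. The estimator is
invariant to common time shifts and dilations of both series (tested as a
property).

Touchdown and liftoff are velocity sign changes of the normalized
anterior–posterior leg trace: forward-to-backward = touchdown,
backward-to-forward = liftoff. Velocity comes from centered differences
after a 5-sample moving average (at 120 fps ≈ 42 ms), and a hysteresis band
of ±5% of the velocity amplitude suppresses chatter near the extremes;
event times are the interpolated zero crossings. Both settings are exposed
in `RunConfig`; they were chosen to suppress jitter comparable to the
~1.6 px pose-estimation error of the tracking stage and are not tuned per
dataset. A constant trace yields zero events with a warning.

### Circular statistics

`circular_summary` returns θ̂ = arg(mean eⁱᶿ) and R = |mean eⁱᶿ|; R ≈ 0
(below 1e-8) flags an undefined mean (e.g. two antipodal angles). The
circular KDE uses a von Mises kernel (default κ = 20, config-exposed) on a
360-point grid and integrates to 1 over the circle to 1e-6.

The Watson–Williams F test compares mean directions across k groups using
F = c·(N−k)(ΣRⱼ−R) / ((k−1)(N−ΣRⱼ)) with the small-concentration
correction c = 1 + 3/(8κ̂), κ̂ estimated from the weighted pooled resultant
by Fisher's piecewise approximation. The test assumes von Mises samples
with common concentration; results are flagged when the pooled R̄ < 0.45.
Monte-Carlo calibration (2000 two-group simulations, κ = 20, n = 30) puts
the empirical type-I error at α = 0.05 within ±0.02, and for tightly
concentrated samples the statistic agrees with one-way ANOVA on the
unwrapped angles (both tested).

### Kinematics

Sensor counts are logged per sample; they are converted to counts/s by the
50 Hz log rate *before* the angular-velocity equations, which fixes the
units of the calibration scale parameters σ (rad per count/s). The default
σ = 1 stands in for device calibration, which is an input, not something
estimated from data. The planar-velocity step uses only roll and pitch —
yaw (spinning in place) produces no translation — and speed is normalised
by body length to BL/s. Trajectory integration implements the explicit
Euler update with the rotated-frame sin/cos arrangement
(Δx = Δt(ẋ sinθ − ẏ cosθ), Δy = Δt(ẋ cosθ + ẏ sinθ)) exactly as the
recording convention defines it, initial position at the origin; velocity
and angle series must share a time grid (linear resampling at 50 Hz,
Δt = 0.02 s default). No smoothing is applied to ω before integration by
default. The body axis is defined posterior→anterior (Meta→Pro); the head
angle is measured relative to that axis. Clock synchronisation fits
t_cam = a·t_log + b by least squares (slope fixed to 1 with only two
events) and reports the residual RMS.

### EMG

Spike trains are 1 where |amplitude| exceeds the threshold (rectified
comparison, so both waveform lobes register). The default threshold is 3
robust standard deviations of the channel, with the robust sd the
normal-consistent scaled MAD (MAD/0.6745); for burst-sparse channels the
baseline is noise-dominated, so this sits ≈3σ above the noise floor and
keeps false crossings rare while plain unscaled MAD (≈2σ) would not.
Spectra are averaged modified periodograms (Hann window, mean removed per
segment, 50% overlap, segment 1.2 s ≈ 4 gait cycles); the gait frequency is
the density argmax in a 1–10 Hz band, ties resolved to the lowest
frequency. Cross-spectrum coherence and phase use the same segmentation;
the phase sign convention is **positive = second channel lags first**
(scipy's conj(X)·Y convention yields the opposite sign, so it is negated —
verified against constructed quarter-period lags). Phases at bins with
coherence below 0.3 (config) are flagged low-confidence. A walking trial
must span more than 5 gait periods. Phase analysis runs on spike trains by
default (raw-signal mode is a flag); the synchronisation index of an
average phase is I_sync = cos θ̂; the virtual antagonist phase adds π under
a quasi-anti-phase assumption. Significance criterion for condition
comparisons: p < 0.005.

## Synthetic generator: what it emulates and what it does not

The generator states the recording world once and is not adjusted to test
outcomes. Gait presets encode the observed coordination patterns:

| preset | f (Hz) | duty | key offsets (rad, vs LF) |
|---|---|---|---|
| tetrapod | 3.0 | 0.6 | LH 0.75π, contralateral π, LM 0.375π |
| quasi_tripod | 5.0 | 0.6 | LH 0.25π, contralateral π, LM π |
| trot | 3.5 | 0.5 | diagonal pairs in phase, contralateral π |
| amp_FTi_double_stance | 3.0 | 0.6 | tetrapod + second brief midleg contact |

The fore–middle lag has no reported value; the tetrapod preset places LM
halfway along the ipsilateral metachronal wave (0.375π) and the
quasi-tripod uses the strict-tripod midleg position (π). The trot preset
uses duty 0.5 so that anti-phase stances are exactly disjoint. The
double-stance preset adds a short (0.1 cycle) second contact 0.15 cycle
after each midleg liftoff, emulating a truncated femur that touches, fails
to support, and touches again. Touchdown jitter is von Mises on cycle phase
(keeping noise on the circle); its magnitude is not reported anywhere, so
the default κ = 50 (angular sd ≈ 8°) is a stated choice giving R ≈ 0.99 —
comparable to the tight phase histograms of real low-speed walking. Leg
traces are half-cosine ramps of amplitude 1 (+1 at touchdown, −1 at
liftoff): only event timing, not trace shape, carries information
downstream.

The sensor-log generator inverts the angular-velocity equations; the roll
equation is underdetermined (one equation, two unknowns dy₁, dy₂), resolved
by the symmetric split −σ_y₁dy₁ = σ_y₂dy₂ = ω_roll — any split satisfying
the equation is analysis-equivalent. EMG channels are inhomogeneous point
processes: rate 300 Hz inside the burst window (levator bursts pre-swing,
retractor bursts early stance), zero outside, each spike a biphasic
Gaussian-derivative waveform (0.5 ms width) with ±20% amplitude
variability, plus white Gaussian noise (sd 0.05 vs spike amplitude 1). The
returned ground-truth pair phases are *empirical* — computed from the
jittered burst centers with the same cycle-pairing rule — so recovery tests
compare like with like.

Not emulated: pose-estimation outliers and identity swaps, sensor slippage
and nonlinearity, motion artifacts and crosstalk in EMG, body dynamics,
non-stationary gait frequency within a trial. A green recovery test
therefore establishes correctness of the estimators under the assumed
signal structure, not robustness to these real-data failure modes.

## Numerical choices

- Angles wrapped to [0, 2π) for phases, (−π, π] for relative timings; the
  modulo edge case (tiny negative inputs rounding to exactly 2π) is
  handled explicitly.
- Undefined circular mean: R < 1e-8.
- Peak-frequency ties break to the lowest frequency.
- Stratification boundaries: |yaw| = 1.0 rad/s belongs to Straight; speed
  bins are left-closed, the last unbounded.
- Euler trajectory error is O(Δt); the closed-loop test budgets 20·Δt·v.
- Clock fit with exactly two events fixes the slope at 1.

## Known limitations

- Event detection assumes a roughly alternating trace; highly irregular
  gaits (frequent missed cycles) are reported via skip counts, not
  corrected.
- No gap filling of low-likelihood pose frames; they are masked and can
  shorten usable cycles.
- The Watson–Williams test is a mean-direction test only; it does not
  detect dispersion differences between conditions.
- Calibration σ must come from the instrument; the package does not
  estimate it from data.
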