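# cricketgait

Analysis tools for insect walking recorded on a spherical treadmill:
inter-leg coordination from gait events, walking kinematics from dual
optical-flow sensors, and muscle-synchrony analysis from multichannel EMG.
Built for neuroethologists and biomechanists studying hexapod gait — in
particular how coordination reorganises after leg loss — and validated end
to end against a synthetic-data generator with known ground truth.

## What it computes

**Inter-leg phase.** For each cycle *i* of a reference leg, the phase of a
target leg's touchdown is

φᵢ = 2π (t_TD(i)_tgt − t_TD(i)_ref) / (t_TD(i+1)_ref − t_TD(i)_ref) ∈ [0, 2π)

Touchdowns are the forward-to-backward velocity sign changes of each leg's
normalized anterior–posterior trace (120 fps pose tracking), found with
smoothing plus hysteresis. Phase samples are summarised by the circular mean
θ̂ and resultant length R (the mean unit vector), visualised with von Mises
kernel density estimates, and stratified by body-rotation class
(Straight = −1 to 1 rad/s) and walking-speed bin (0–3, 3–6, 6– BL/s).

**Treadmill kinematics.** Two optical-flow sensors (45° mounts, 90° apart)
reading (dx₁,dy₁,dx₂,dy₂) at 50 Hz give the sphere's angular velocities

ω_yaw = −(σₓ₁dx₁ + σₓ₂dx₂)cos45°, ω_roll = ½(−σ_y₁dy₁ + σ_y₂dy₂),
ω_pitch = (σₓ₁dx₁ − σₓ₂dx₂)sin45°

from which planar velocity (ẋ = l_s ω_roll, ẏ = l_s ω_pitch, sphere radius
l_s = 50 mm), body-length-normalised speed, and the explicit-Euler
dead-reckoned trajectory with the tracked body angle follow. LED blink
events synchronise the camera and logger clocks by least squares.

**EMG synchrony.** Channels are binarised to spike trains by a robust
amplitude threshold, the gait frequency is found from the averaged
periodogram (Welch), and each channel pair's magnitude-squared coherence and
cross-spectrum phase at that frequency gives the relative activation timing.
An average phase θ̂ maps to the synchronisation index **I_sync = cos θ̂**
(+1 in-phase, −1 anti-phase); condition differences are tested with the
Watson–Williams F test (significance criterion p < 0.005).

**Synthetic generator.** Gait presets (`tetrapod`, `quasi_tripod`, `trot`,
`amp_FTi_double_stance`) produce phase-coupled touchdown series with von
Mises jitter, leg traces, pose tables, sensor logs from prescribed ball
motion, phase-locked EMG, and clock-sync events — each with a ground-truth
sidecar so every analysis stage is checked by parameter recovery.

## Worked example

```python
import numpy as np
from cricketgait.synth import GaitConfig, generate_gait
from cricketgait.gait import phase_differences, circular_summary
from cricketgait.emg import sync_index

events, traces, truth = generate_gait(
    GaitConfig("tetrapod", n_cycles=100, jitter_kappa=50.0, seed=1)
)
for pair in (("LF", "LH"), ("LF", "RF"), ("LM", "RM")):
    samples, skipped = phase_differences(events[pair[0]], events[pair[1]])
    s = circular_summary([x.phi for x in samples])
    print(f"{pair[0]}-{pair[1]}: theta_hat = {s.theta_hat/np.pi:.3f} pi, "
          f"R = {s.R:.3f}, n = {s.n}, I_sync = {sync_index(s).value:+.3f}")
```

prints

```
LF-LH: theta_hat = 0.747 pi, R = 0.986, n = 99, I_sync = -0.700
LF-RF: theta_hat = 1.001 pi, R = 0.987, n = 99, I_sync = -1.000
LM-RM: theta_hat = 0.996 pi, R = 0.986, n = 99, I_sync = -1.000
```

The low-speed tetrapod pattern is recovered from jittered events: the
fore–hind phase lag sits at ≈0.75π with tight concentration (R ≈ 0.99 over
99 cycles), while contralateral pairs are anti-phase (θ̂ ≈ π, I_sync ≈ −1).

A CLI wraps the same pipeline:

```sh
cricketgait simulate --preset tetrapod --n-cycles 100 --seed 1 --out-dir run/
cricketgait report --in-dir run/ --out-dir run/results/
```

writing `phases.csv`, `summary.csv`, `velocity.csv`, `trajectory.csv`,
`emg_phases.csv` and a run log.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the analytic synchronisation-index values at
anti-phase and in-phase average phase, and the fore–hind circular means
recovered by the phase pipeline from the low-speed (tetrapod, 3 Hz) and
high-speed (quasi-tripod, 5 Hz) presets — 100 cycles each with von Mises
touchdown jitter (κ = 50) — reported in units of π.
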