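"""Synthetic recordings with known ground truth.

Emulates the statistical structure of tethered-insect treadmill recordings:

* phase-coupled per-leg touchdown/liftoff sequences at 3-5 Hz, with von
  Mises timing jitter on the cycle phase, plus smooth normalized leg traces
  at the video rate (120 fps);
* dual optical-flow sensor logs at 50 Hz consistent with a prescribed ball
  motion (the forward model inverts the yaw/roll/pitch reconstruction);
* burst-structured EMG at 5 kHz, phase-locked to the owning leg's cycle,
  built from biphasic spike waveforms plus Gaussian noise;
* paired LED blink events on two unsynchronised clocks.

Every generator returns the ground truth needed for parameter-recovery
tests alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circular_summary, wrap_to_pi, wrap_to_2pi
from .gait import LEGS, TouchdownSeries
from .kinematics import CalibrationParams

__all__ = [
    "GaitConfig",
    "GaitTruth",
    "BallMotionProfile",
    "EMGChannelSpec",
    "EMGSynthSpec",
    "GAIT_PRESETS",
    "MUSCLE_LEG",
    "generate_gait",
    "generate_ball_sensor_log",
    "generate_emg",
    "generate_sync_events",
    "generate_pose_table",
    "emg_condition_offsets",
]

_PI = np.pi

# Per-leg touchdown phase offsets (rad) relative to the reference leg LF.
# tetrapod: low-speed intact pattern, fore-hind 0.75*pi, contralateral pi;
#   the fore-middle lag (no printed value) is placed halfway along the
#   ipsilateral metachronal wave.
# quasi_tripod: high-speed pattern, fore-hind 0.25*pi, middle legs at the
#   strict-tripod position (anti-phase to the ipsilateral fore leg).
# trot: diagonal pairs in phase after midleg loss; remaining femora anti-phase.
# amp_FTi_double_stance: tetrapod timing, but each middle leg's truncated
#   femur makes a second brief ground contact per cycle.
GAIT_PRESETS: dict[str, dict] = {
    "tetrapod": {
        "cycle_frequency": 3.0,
        "leg_offsets": {"LF": 0.0, "LM": 0.375 * _PI, "LH": 0.75 * _PI,
                        "RF": _PI, "RM": 1.375 * _PI, "RH": 1.75 * _PI},
    },
    "quasi_tripod": {
        "cycle_frequency": 5.0,
        "leg_offsets": {"LF": 0.0, "LM": _PI, "LH": 0.25 * _PI,
                        "RF": _PI, "RM": 0.0, "RH": 1.25 * _PI},
    },
    "trot": {
        "cycle_frequency": 3.5,
        "duty_factor": 0.5,  # anti-phase stances are disjoint at duty <= 1/2
        "leg_offsets": {"LF": 0.0, "LM": _PI, "LH": _PI,
                        "RF": _PI, "RM": 0.0, "RH": 0.0},
    },
    "amp_FTi_double_stance": {
        "cycle_frequency": 3.0,
        "leg_offsets": {"LF": 0.0, "LM": 0.375 * _PI, "LH": 0.75 * _PI,
                        "RF": _PI, "RM": 1.375 * _PI, "RH": 1.75 * _PI},
        "double_stance_legs": ("LM", "RM"),
    },
}

MUSCLE_LEG = {"LM_levator": "LM", "RM_levator": "RM", "RH_retractor": "RH"}


@dataclass
class GaitConfig:
    """Generative gait preset.

    ``leg_offsets`` maps leg id to touchdown phase offset in [0, 2*pi)
    relative to the reference leg LF (whose offset is 0).  ``jitter_kappa``
    is the von Mises concentration of the touchdown-phase noise
    (``inf`` = noise-free).
    """

    preset_name: str = "tetrapod"
    cycle_frequency: float | None = None  # Hz; None -> preset default
    duty_factor: float | None = None  # None -> preset default (0.6 unless stated)
    leg_offsets: dict | None = None  # None -> preset offsets
    jitter_kappa: float = 50.0
    n_cycles: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.preset_name not in GAIT_PRESETS:
            raise ValueError(
                f"unknown preset '{self.preset_name}'; "
                f"choose from {sorted(GAIT_PRESETS)}"
            )
        preset = GAIT_PRESETS[self.preset_name]
        if self.cycle_frequency is None:
            self.cycle_frequency = preset["cycle_frequency"]
        if self.duty_factor is None:
            self.duty_factor = preset.get("duty_factor", 0.6)
        if self.leg_offsets is None:
            self.leg_offsets = dict(preset["leg_offsets"])
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.cycle_frequency <= 0:
            raise ValueError("cycle_frequency must be positive")
        if self.leg_offsets.get("LF", 0.0) != 0.0:
            raise ValueError("reference leg LF must have zero offset")
        self.leg_offsets = {k: float(wrap_to_2pi(v)) for k, v in self.leg_offsets.items()}
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3 for phase statistics")


@dataclass
class GaitTruth:
    """Ground truth accompanying a generated gait."""

    leg_offsets: dict
    cycle_frequency: float
    duty_factor: float
    preset_name: str


def generate_gait(config: GaitConfig, fps: float = 120.0):
    """Generate per-leg touchdown/liftoff series and smooth leg traces.

    Touchdown i of a leg with offset ``d`` falls at ``(i + d/2pi)/f`` plus
    von Mises phase jitter; liftoff follows ``duty_factor/f`` later.  The
    anterior-posterior trace runs +1 (anterior extreme, touchdown) to -1
    (posterior extreme, liftoff) as half-cosine ramps, sampled at ``fps``.

    Returns
    -------
    events : dict leg -> TouchdownSeries
    traces : DataFrame with column 't' and one column per leg
    truth : GaitTruth
    """
    rng = np.random.default_rng(config.seed)
    f = config.cycle_frequency
    duty = config.duty_factor
    preset = GAIT_PRESETS[config.preset_name]
    double_legs = preset.get("double_stance_legs", ())

    events: dict[str, TouchdownSeries] = {}
    stance_lists: dict[str, np.ndarray] = {}
    for leg, offset in config.leg_offsets.items():
        idx = np.arange(config.n_cycles)
        base = (idx + offset / (2.0 * _PI)) / f
        if np.isinf(config.jitter_kappa):
            jitter = np.zeros_like(base)
        else:
            jitter = rng.vonmises(0.0, config.jitter_kappa, size=base.size) / (2.0 * _PI * f)
        td = np.sort(base + jitter)
        lo = td + duty / f
        stances = np.column_stack([td, lo])
        if leg in double_legs:
            # truncated femur: brief second contact mid-swing
            td2 = td + (duty + 0.15) / f
            lo2 = td2 + 0.1 / f
            stances = np.vstack([stances, np.column_stack([td2, lo2])])
            order = np.argsort(stances[:, 0])
            stances = stances[order]
        stance_lists[leg] = stances
        all_td = stances[:, 0]
        all_lo = stances[:, 1]
        events[leg] = TouchdownSeries(leg=leg, touchdowns=all_td, liftoffs=all_lo)

    duration = (config.n_cycles + 1) / f
    t = np.arange(0.0, duration, 1.0 / fps)
    traces = {"t": t}
    for leg, stances in stance_lists.items():
        traces[leg] = _trace_from_stances(t, stances)
    truth = GaitTruth(
        leg_offsets=dict(config.leg_offsets),
        cycle_frequency=f,
        duty_factor=duty,
        preset_name=config.preset_name,
    )
    return events, pd.DataFrame(traces), truth


def _trace_from_stances(t: np.ndarray, stances: np.ndarray) -> np.ndarray:
    """Piecewise half-cosine trace: +1 at touchdown, -1 at liftoff."""
    # breakpoints alternate td, lo, td, lo ...
    breaks = stances.ravel()
    pos = np.empty_like(t)
    idx = np.searchsorted(breaks, t, side="right") - 1
    for k in range(t.size):
        i = idx[k]
        if i < 0:
            # before the first touchdown: tail of a swing ending at breaks[0]
            td0 = breaks[0]
            swing = max(td0 - (stances[0, 1] - stances[0, 0]), td0 - 0.5)
            frac = np.clip(1.0 - (td0 - t[k]) / max(td0 - swing, 1e-9), 0.0, 1.0)
            pos[k] = -np.cos(_PI * frac)
        elif i >= breaks.size - 1:
            # after the last liftoff: swing back toward +1
            lo_last = breaks[-1]
            dur = stances[-1, 1] - stances[-1, 0]
            frac = np.clip((t[k] - lo_last) / max(dur, 1e-9), 0.0, 1.0)
            pos[k] = -np.cos(_PI * frac)
        elif i % 2 == 0:  # stance [td, lo): +1 -> -1
            frac = (t[k] - breaks[i]) / (breaks[i + 1] - breaks[i])
            pos[k] = np.cos(_PI * frac)
        else:  # swing [lo, next td): -1 -> +1
            frac = (t[k] - breaks[i]) / (breaks[i + 1] - breaks[i])
            pos[k] = -np.cos(_PI * frac)
    return pos


@dataclass
class BallMotionProfile:
    """Prescribed sphere angular velocities on a time grid."""

    t: np.ndarray
    omega_yaw: np.ndarray
    omega_roll: np.ndarray
    omega_pitch: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("omega_yaw", "omega_roll", "omega_pitch"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), self.t.shape
            ).copy()
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)


def generate_ball_sensor_log(
    profile: BallMotionProfile,
    calib: CalibrationParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Optical-flow sensor log (50 Hz) consistent with a ball-motion profile.

    Inverts the angular-velocity reconstruction: dx1/dx2 solve the 2x2
    linear system given by the yaw and pitch equations; the roll equation is
    underdetermined (one equation, two unknowns) and is resolved with the
    symmetric split ``-sy1*dy1 = sy2*dy2 = omega_roll``.  Counts are per
    sample at the log rate; Gaussian noise of sd ``noise_sd`` is added to
    each reading.
    """
    calib = calib or CalibrationParams()
    rate = calib.log_rate_hz
    rng = np.random.default_rng(seed)
    t = np.arange(profile.t[0], profile.t[-1] + 0.5 / rate, 1.0 / rate)
    wy = np.interp(t, profile.t, profile.omega_yaw)
    wr = np.interp(t, profile.t, profile.omega_roll)
    wp = np.interp(t, profile.t, profile.omega_pitch)
    c = np.cos(_PI / 4.0)
    s = np.sin(_PI / 4.0)
    # per-second counts solving the yaw/pitch system
    dx1 = ((-wy / c) + (wp / s)) / 2.0 / calib.sigma_x1
    dx2 = ((-wy / c) - (wp / s)) / 2.0 / calib.sigma_x2
    dy1 = -wr / calib.sigma_y1
    dy2 = wr / calib.sigma_y2
    frame = pd.DataFrame(
        {
            "t": t,
            "dx1": dx1 / rate,
            "dy1": dy1 / rate,
            "dx2": dx2 / rate,
            "dy2": dy2 / rate,
        }
    )
    if noise_sd > 0:
        for col in ("dx1", "dy1", "dx2", "dy2"):
            frame[col] += rng.normal(0.0, noise_sd, size=len(frame))
    return frame


@dataclass
class EMGChannelSpec:
    """One synthetic EMG channel locked to its owning leg's cycle.

    ``burst_phase`` is where in the leg cycle (rad after touchdown) the
    burst begins; levators fire pre-swing, retractors in early stance.
    """

    muscle: str
    burst_phase: float
    burst_duty: float = 0.15
    spike_rate_hz: float = 300.0
    spike_amp: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.muscle not in MUSCLE_LEG:
            raise ValueError(f"unknown muscle '{self.muscle}'")
        if not 0.0 < self.burst_duty < 1.0:
            raise ValueError("burst_duty must be in (0, 1)")

    @property
    def leg(self) -> str:
        return MUSCLE_LEG[self.muscle]


@dataclass
class EMGSynthSpec:
    """Channel set plus acquisition parameters for synthetic EMG."""

    channels: list
    fs: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        # biphasic spike waveform bandwidth ~ 1/(2*pi*0.5ms) ~ 320 Hz
        if self.fs < 2 * 320.0:
            raise ValueError("sampling rate below twice the spike-waveform bandwidth")


def _spike_waveform(fs: float, width_s: float = 0.0005) -> np.ndarray:
    """Biphasic action-potential-like waveform (Gaussian derivative)."""
    half = int(round(3 * width_s * fs))
    tt = np.arange(-half, half + 1) / fs
    w = -tt / width_s * np.exp(0.5 - 0.5 * (tt / width_s) ** 2)
    return w


def generate_emg(gait: dict, spec: EMGSynthSpec):
    """Burst-structured EMG channels locked to the gait, plus a phase table.

    Each channel is an inhomogeneous point process: spike rate
    ``spike_rate_hz`` inside its burst window (placed at ``burst_phase`` of
    the owning leg's cycle, lasting ``burst_duty`` of the cycle) and zero
    outside, convolved with a biphasic waveform, plus Gaussian noise.

    Returns
    -------
    records : dict muscle -> EMGRecord
    truth : dict (muscle_a, muscle_b) -> phase (rad, (-pi, pi]; positive
        means channel b's bursts lag channel a's)
    """
    from .emg import EMGRecord

    rng = np.random.default_rng(spec.seed)
    for ch in spec.channels:
        if ch.leg not in gait:
            raise ValueError(f"channel {ch.muscle} references leg {ch.leg} absent from gait")
    t_end = max(s.touchdowns[-1] for s in gait.values())
    n = int(np.ceil(t_end * spec.fs))
    wave = _spike_waveform(spec.fs)

    records: dict = {}
    burst_centers: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        td = gait[ch.leg].touchdowns
        sig = np.zeros(n)
        centers = []
        for i in range(td.size - 1):
            T = td[i + 1] - td[i]
            start = td[i] + (ch.burst_phase / (2.0 * _PI)) * T
            dur = ch.burst_duty * T
            centers.append(start + dur / 2.0)
            n_spk = rng.poisson(ch.spike_rate_hz * dur)
            times = start + rng.random(n_spk) * dur
            amps = ch.spike_amp * (0.8 + 0.4 * rng.random(n_spk))
            for ts, a in zip(times, amps):
                k = int(round(ts * spec.fs))
                lo, hi = k - wave.size // 2, k + wave.size // 2 + 1
                wl, wh = max(0, -lo), wave.size - max(0, hi - n)
                lo, hi = max(lo, 0), min(hi, n)
                if lo < hi:
                    sig[lo:hi] += a * wave[wl:wh]
        if ch.noise_sd > 0:
            sig += rng.normal(0.0, ch.noise_sd, size=n)
        records[ch.muscle] = EMGRecord(muscle=ch.muscle, fs=spec.fs, samples=sig)
        burst_centers[ch.muscle] = np.asarray(centers)

    truth: dict = {}
    muscles = [ch.muscle for ch in spec.channels]
    for i, ma in enumerate(muscles):
        for mb in muscles[i + 1 :]:
            truth[(ma, mb)] = _pair_phase(burst_centers[ma], burst_centers[mb])
    return records, truth


def _pair_phase(centers_a: np.ndarray, centers_b: np.ndarray) -> float:
    """Circular-mean phase of b's burst centers within a's burst cycles."""
    phases = []
    j = 0
    for i in range(centers_a.size - 1):
        u0, u1 = centers_a[i], centers_a[i + 1]
        while j < centers_b.size and centers_b[j] < u0:
            j += 1
        if j >= centers_b.size or centers_b[j] >= u1:
            continue
        phases.append(2.0 * _PI * (centers_b[j] - u0) / (u1 - u0))
    summ = circular_summary(np.asarray(phases))
    return float(wrap_to_pi(summ.theta_hat))


def emg_condition_offsets(condition: str) -> tuple[str, dict]:
    """Gait preset name and leg-offset override emulating an EMG condition.

    ``intact``: tetrapod timing, contralateral midleg muscles anti-phase.
    ``amp_CTr_both``: trot-frequency timing with both midleg drives in
    phase (the in-phase synchrony seen after complete midleg loss).
    """
    if condition == "intact":
        return "tetrapod", dict(GAIT_PRESETS["tetrapod"]["leg_offsets"])
    if condition == "amp_CTr_both":
        offsets = dict(GAIT_PRESETS["trot"]["leg_offsets"])
        offsets["LM"] = 0.0
        offsets["RM"] = 0.0
        return "trot", offsets
    raise ValueError(f"unknown EMG condition '{condition}'")


def generate_sync_events(
    true_offset: float, drift: float, n_events: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired LED blink events in camera clock and logger clock.

    logger = camera * (1 + drift) + true_offset.
    """
    if n_events < 2:
        raise ValueError("need at least two events")
    rng = np.random.default_rng(seed)
    camera = np.sort(rng.uniform(0.0, 60.0, size=n_events))
    logger = camera * (1.0 + drift) + true_offset
    return camera, logger


# ---------------------------------------------------------------------------
# pose table synthesis (camera-pixel marker positions from gait + heading)

POSE_MARKERS = (
    "Head", "Pro", "Meso", "Meta",
    "LF1", "LF2", "LM1", "LM2", "LH1", "LH2",
    "RF1", "RF2", "RM1", "RM2", "RH1", "RH2",
    "Bar", "Axis", "Fix", "LED1", "LED2",
)

_LEG_BASES = {
    "LF": (20.0, 15.0), "LM": (0.0, 18.0), "LH": (-20.0, 15.0),
    "RF": (20.0, -15.0), "RM": (0.0, -18.0), "RH": (-20.0, -15.0),
}


def generate_pose_table(
    traces: pd.DataFrame,
    heading=0.0,
    head_angle=0.0,
    center=(320.0, 240.0),
    step_px: float = 10.0,
    scorer: str = "synthetic",
    likelihood_dropout: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Marker table in the pose-estimation CSV dialect from leg traces.

    The tethered body sits at ``center`` with orientation ``heading``
    (constant or a callable of time); leg-tip markers oscillate along the
    body axis by ``step_px`` times the normalized trace.  ``likelihood_dropout``
    randomly assigns low likelihood (0.1) to that fraction of frames.
    """
    rng = np.random.default_rng(seed)
    t = traces["t"].to_numpy()
    th = np.array([heading(ti) for ti in t]) if callable(heading) else np.full(t.size, heading)
    ax = np.column_stack([np.cos(th), np.sin(th)])  # body axis, anterior
    perp = np.column_stack([-np.sin(th), np.cos(th)])
    cx, cy = center

    cols: dict = {}

    def put(marker, xy, like=None):
        if like is None:
            like = np.ones(t.size)
        cols[(scorer, marker, "x")] = xy[:, 0]
        cols[(scorer, marker, "y")] = xy[:, 1]
        cols[(scorer, marker, "likelihood")] = like

    meta = np.column_stack([np.full(t.size, cx), np.full(t.size, cy)]) - 25.0 * ax
    pro = meta + 50.0 * ax
    meso = meta + 25.0 * ax
    head_dir = np.column_stack(
        [np.cos(th + head_angle), np.sin(th + head_angle)]
    )
    head = pro + 15.0 * head_dir
    put("Meta", meta)
    put("Pro", pro)
    put("Meso", meso)
    put("Head", head)
    for leg, (bx, by) in _LEG_BASES.items():
        base = meso + bx * ax + by * perp
        put(f"{leg}1", base)
        tip_off = traces[leg].to_numpy() if leg in traces else np.zeros(t.size)
        like = np.ones(t.size)
        if likelihood_dropout > 0:
            like[rng.random(t.size) < likelihood_dropout] = 0.1
        put(f"{leg}2", base + (step_px * tip_off)[:, None] * ax + 8.0 * np.sign(by) * perp, like)
    for marker, (mx, my) in {
        "Bar": (600.0, 50.0), "Axis": (600.0, 240.0), "Fix": (600.0, 430.0),
        "LED1": (30.0, 30.0), "LED2": (30.0, 60.0),
    }.items():
        put(marker, np.column_stack([np.full(t.size, mx), np.full(t.size, my)]))

    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["scorer", "bodyparts", "coords"]
    )
    table.index.name = None
    return table
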