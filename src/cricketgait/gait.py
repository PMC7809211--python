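"""Gait-event detection and inter-leg phase analysis.

A leg's normalized anterior-posterior trace alternates between a forward
swing (recovery stroke) and a backward stance (power stroke); touchdown is
the swing-to-stance transition, i.e. the forward-to-backward velocity sign
change at the anterior extreme.  Phase differences between legs are computed
per reference cycle as

    phi_i = 2*pi * (t_TD(i)_target - t_TD(i)_ref) / T_period(i)_ref

and summarised with circular statistics, optionally stratified by body
rotation class and walking-speed bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import CircularSummary, circular_kde, circular_summary, wrap_to_2pi

__all__ = [
    "TouchdownSeries",
    "GaitDiagram",
    "PhaseSample",
    "GaitCycleStats",
    "detect_gait_events",
    "phase_differences",
    "stratify_samples",
    "gait_cycle_stats",
    "circular_summary",
    "circular_kde",
    "LEGS",
]

LEGS = ("LF", "LM", "LH", "RF", "RM", "RH")

SPEED_BIN_EDGES = (0.0, 3.0, 6.0)  # BL/s, left-closed; last bin unbounded
YAW_STRAIGHT_BAND = 1.0  # rad/s, |omega| <= band -> Straight (inclusive)


@dataclass
class TouchdownSeries:
    """Ordered gait-event times for one leg.

    ``touchdowns`` are strictly increasing; ``liftoffs`` (optional) interleave
    so that each liftoff lies between consecutive touchdowns.
    """

    leg: str
    touchdowns: np.ndarray
    liftoffs: np.ndarray | None = None

    def __post_init__(self):
        self.touchdowns = np.asarray(self.touchdowns, dtype=float)
        if self.touchdowns.size > 1 and not np.all(np.diff(self.touchdowns) > 0):
            raise ValueError("touchdown times must be strictly increasing")
        if self.liftoffs is not None:
            self.liftoffs = np.asarray(self.liftoffs, dtype=float)


@dataclass
class GaitDiagram:
    """Per-leg stance intervals [touchdown, liftoff)."""

    stances: dict  # leg -> (n, 2) array of [touchdown, liftoff)


@dataclass(frozen=True)
class PhaseSample:
    """One inter-leg phase observation with its locomotor context."""

    pair: str
    cycle: int
    phi: float  # rad, [0, 2*pi)
    speed: float = np.nan  # BL/s
    yaw_rate: float = np.nan  # rad/s


@dataclass
class GaitCycleStats:
    """Per-leg cycle periods/frequencies and stance/swing durations."""

    leg: str
    periods: np.ndarray  # s
    frequencies: np.ndarray  # Hz
    stance_durations: np.ndarray  # s
    swing_durations: np.ndarray  # s


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")
    return out[pad : pad + x.size] if pad else out


def detect_gait_events(
    trace,
    fps: float = 120.0,
    leg: str = "LF",
    smooth_window: int = 5,
    hysteresis_frac: float = 0.05,
) -> TouchdownSeries:
    """Detect touchdowns and liftoffs from a leg's anterior-posterior trace.

    Velocity is estimated by centered differences after moving-average
    smoothing.  A hysteresis band of ``hysteresis_frac`` times the velocity
    amplitude suppresses chatter: the leg is declared swinging only once the
    velocity exceeds +h and in stance only once it falls below -h; the event
    time is the interpolated zero crossing preceding the band exit.

    Parameters
    ----------
    trace : array-like
        Uniformly sampled normalized leg position (anterior positive).
    fps : float
        Sampling rate of the trace.

    Returns
    -------
    TouchdownSeries with interleaved liftoffs.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < max(smooth_window, 3):
        raise ValueError("trace shorter than the smoothing window")
    xs = _moving_average(x, smooth_window)
    v = np.gradient(xs) * fps
    vmax = np.max(np.abs(v))
    if vmax == 0.0:
        warnings.warn("constant trace: no gait events detected", stacklevel=2)
        return TouchdownSeries(leg=leg, touchdowns=np.array([]), liftoffs=np.array([]))
    h = hysteresis_frac * vmax
    t = np.arange(x.size) / fps

    touchdowns, liftoffs = [], []
    state = 0  # +1 swinging, -1 stance, 0 unknown
    last_cross = None  # candidate zero-crossing time since leaving the band
    for i in range(1, v.size):
        if v[i - 1] >= 0 > v[i] or v[i - 1] > 0 >= v[i]:
            # forward-to-backward crossing (candidate touchdown)
            frac = v[i - 1] / (v[i - 1] - v[i]) if v[i - 1] != v[i] else 0.0
            last_cross = ("td", t[i - 1] + frac / fps)
        elif v[i - 1] <= 0 < v[i] or v[i - 1] < 0 <= v[i]:
            frac = -v[i - 1] / (v[i] - v[i - 1]) if v[i - 1] != v[i] else 0.0
            last_cross = ("lo", t[i - 1] + frac / fps)
        if v[i] < -h and state != -1:
            if state == 1 and last_cross is not None and last_cross[0] == "td":
                touchdowns.append(last_cross[1])
            state = -1
        elif v[i] > h and state != 1:
            if state == -1 and last_cross is not None and last_cross[0] == "lo":
                liftoffs.append(last_cross[1])
            state = 1
    return TouchdownSeries(
        leg=leg, touchdowns=np.asarray(touchdowns), liftoffs=np.asarray(liftoffs)
    )


def phase_differences(
    ref: TouchdownSeries,
    tgt: TouchdownSeries,
    speed=None,
    yaw_rate=None,
) -> tuple[list[PhaseSample], int]:
    """Per-cycle phase of ``tgt`` touchdowns within ``ref`` cycles.

    For each reference cycle [t_i, t_{i+1}) the first target touchdown in the
    cycle defines phi_i = 2*pi*(t_tgt - t_i)/(t_{i+1} - t_i), wrapped to
    [0, 2*pi).  Cycles containing no target touchdown are skipped and
    counted.

    ``speed`` and ``yaw_rate`` are optional callables or constants giving
    the locomotor context at a cycle's start time.

    Returns
    -------
    (samples, n_skipped)
    """
    td_ref = ref.touchdowns
    td_tgt = tgt.touchdowns
    if td_ref.size < 2 or td_tgt.size < 1:
        raise ValueError("reference needs >= 2 touchdowns and target >= 1")
    pair = f"{ref.leg}-{tgt.leg}"

    def _ctx(fn, t0):
        if fn is None:
            return np.nan
        return float(fn(t0)) if callable(fn) else float(fn)

    samples: list[PhaseSample] = []
    skipped = 0
    j = 0
    for i in range(td_ref.size - 1):
        t0, t1 = td_ref[i], td_ref[i + 1]
        while j < td_tgt.size and td_tgt[j] < t0:
            j += 1
        if j >= td_tgt.size or td_tgt[j] >= t1:
            skipped += 1
            continue
        phi = float(wrap_to_2pi(2.0 * np.pi * (td_tgt[j] - t0) / (t1 - t0)))
        samples.append(
            PhaseSample(pair=pair, cycle=i, phi=phi,
                        speed=_ctx(speed, t0), yaw_rate=_ctx(yaw_rate, t0))
        )
    return samples, skipped


def _rotation_class(yaw: float) -> str:
    if -YAW_STRAIGHT_BAND <= yaw <= YAW_STRAIGHT_BAND:
        return "Straight"
    return "Left" if yaw > YAW_STRAIGHT_BAND else "Right"


def _speed_bin(speed: float) -> str:
    edges = SPEED_BIN_EDGES
    if speed < edges[1]:
        return f"[{edges[0]:g},{edges[1]:g})"
    if speed < edges[2]:
        return f"[{edges[1]:g},{edges[2]:g})"
    return f"[{edges[2]:g},inf)"


def stratify_samples(samples) -> dict:
    """Group phase samples by rotation class and speed bin.

    Rotation: Straight for |yaw| <= 1 rad/s (boundaries inclusive), Left for
    yaw > 1, Right for yaw < -1.  Speed bins (BL/s): [0,3), [3,6), [6,inf).
    """
    groups: dict[tuple[str, str], list[PhaseSample]] = {}
    for s in samples:
        key = (_rotation_class(s.yaw_rate), _speed_bin(s.speed))
        groups.setdefault(key, []).append(s)
    return groups


def gait_cycle_stats(diagram: GaitDiagram) -> dict:
    """Cycle period, frequency and stance/swing durations per leg.

    period_i = touchdown_{i+1} - touchdown_i; swing_i = touchdown_{i+1} -
    liftoff_i.  Legs with a single stance interval yield empty period lists
    with a warning.
    """
    out: dict[str, GaitCycleStats] = {}
    for leg, stances in diagram.stances.items():
        st = np.asarray(stances, dtype=float).reshape(-1, 2)
        tds, los = st[:, 0], st[:, 1]
        if tds.size < 2:
            warnings.warn(f"leg {leg}: fewer than two stance intervals", stacklevel=2)
            out[leg] = GaitCycleStats(
                leg=leg,
                periods=np.array([]),
                frequencies=np.array([]),
                stance_durations=los - tds,
                swing_durations=np.array([]),
            )
            continue
        periods = np.diff(tds)
        out[leg] = GaitCycleStats(
            leg=leg,
            periods=periods,
            frequencies=1.0 / periods,
            stance_durations=los - tds,
            swing_durations=tds[1:] - los[:-1],
        )
    return out


def phase_samples_to_frame(samples) -> pd.DataFrame:
    """Tidy DataFrame of phase samples (pair, cycle, phi_rad, speed_BLs, yaw_rads)."""
    return pd.DataFrame(
        [
            {"pair": s.pair, "cycle": s.cycle, "phi_rad": s.phi,
             "speed_BLs": s.speed, "yaw_rads": s.yaw_rate}
            for s in samples
        ]
    )
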