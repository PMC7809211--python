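"""End-to-end orchestration: clock sync -> gait -> kinematics -> EMG -> stats.

``run_pipeline`` consumes a bundle of input files (pose table, sensor log,
EMG log, LED sync events), runs every requested stage, and writes tidy CSV
outputs plus a run log of decisions (masked frames, skipped cycles, sensor
gaps).  Any stage failure aborts with a stage-tagged message.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import gait as gait_mod
from . import io as io_mod
from . import kinematics as kin_mod
from .circular import circular_summary, wrap_to_2pi
from .config import RunConfig

__all__ = ["PipelineError", "run_pipeline", "watson_williams_table", "PHASE_PAIRS"]

# the inter-leg pairs shown in the study's phase panels
PHASE_PAIRS = (
    ("LF", "LM"), ("LF", "LH"), ("LF", "RF"), ("LM", "RM"),
    ("LH", "RH"), ("RF", "RM"), ("RF", "RH"),
)


class PipelineError(RuntimeError):
    """A stage failure; the message carries a [stage] tag."""


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag any stage failure
        raise PipelineError(f"[{name}] {exc}") from exc


def _leg_trace(pose: pd.DataFrame, leg: str, theta_body: np.ndarray) -> np.ndarray:
    """Anterior-posterior tip coordinate of one leg, normalized to ~[-1, 1]."""
    tip_x = pose[(f"{leg}2", "x")].to_numpy(float)
    tip_y = pose[(f"{leg}2", "y")].to_numpy(float)
    base_x = pose[(f"{leg}1", "x")].to_numpy(float)
    base_y = pose[(f"{leg}1", "y")].to_numpy(float)
    ap = (tip_x - base_x) * np.cos(theta_body) + (tip_y - base_y) * np.sin(theta_body)
    ap = ap - np.nanmean(ap)
    amp = np.nanmax(np.abs(ap))
    if amp > 0:
        ap = ap / amp
    return np.nan_to_num(ap, nan=0.0)


def run_pipeline(config: RunConfig, inputs: dict, out_dir, stages=None) -> dict:
    """Run the requested stages over one recording bundle.

    Parameters
    ----------
    config : RunConfig
    inputs : dict
        Paths keyed by 'pose', 'sensor', 'emg', 'sync' (each optional, but a
        requested stage whose input is absent is an error).
    out_dir : path
        Output directory for result CSVs and the run log.
    stages : iterable of str, optional
        Subset of {'sync', 'gait', 'kinematics', 'emg'}; defaults to the
        stages whose inputs are present.

    Returns
    -------
    dict of in-memory results per stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = [s for s, k in (("sync", "sync"), ("gait", "pose"),
                                 ("kinematics", "sensor"), ("emg", "emg"))
                  if k in inputs]
    stages = list(stages)
    required_input = {"sync": "sync", "gait": "pose", "kinematics": "sensor", "emg": "emg"}
    for s in stages:
        if s not in required_input:
            raise PipelineError(f"[{s}] unknown stage")
        if required_input[s] not in inputs:
            raise PipelineError(f"[{s}] missing required input '{required_input[s]}'")

    results: dict = {}
    log_lines: list[str] = []

    clock_map = None
    if "sync" in stages:
        def _sync():
            ev = json.loads(Path(inputs["sync"]).read_text())
            return kin_mod.synchronize_clocks(ev["camera_events"], ev["logger_events"])

        clock_map = _stage("sync", _sync)
        results["clock_map"] = clock_map
        log_lines.append(
            f"sync: slope={clock_map.slope:.8f} offset={clock_map.offset:.6f} "
            f"residual_rms={clock_map.residual_rms:.3e}"
        )

    pose_angles = None
    events = {}
    if "gait" in stages:
        def _gait():
            table = io_mod.read_pose_table(
                inputs["pose"], likelihood_floor=config.likelihood_floor
            )
            angles = kin_mod.pose_angles(table.data)
            angles = kin_mod.PoseAngles(
                t=np.arange(len(table.data)) / table.fps,
                theta_body_cam=angles.theta_body_cam,
                theta_head_cricket=angles.theta_head_cricket,
            )
            evs = {}
            for leg in gait_mod.LEGS:
                trace = _leg_trace(table.data, leg, angles.theta_body_cam)
                evs[leg] = gait_mod.detect_gait_events(
                    trace, fps=table.fps, leg=leg,
                    smooth_window=config.smooth_window,
                    hysteresis_frac=config.hysteresis_frac,
                )
            return table, angles, evs

        table, pose_angles, events = _stage("gait", _gait)
        results["pose_angles"] = pose_angles
        results["events"] = events
        masked_total = sum(table.n_masked.values())
        log_lines.append(f"gait: masked frames per marker total={masked_total}")

    speed_fn = yaw_fn = None
    if "kinematics" in stages:
        def _kin():
            frame, gaps = io_mod.read_sensor_log(inputs["sensor"])
            if clock_map is not None:
                frame = frame.assign(t=clock_map(frame["t"].to_numpy()))
            state = kin_mod.angular_velocities(frame, config.calibration)
            vel = kin_mod.planar_velocity(state, config.calibration)
            v_bl = kin_mod.normalize_body_length(vel.v_cam, config.body_length_mm)
            vel_df = pd.DataFrame(
                {"t": state.t, "v_BLs": v_bl, "omega_yaw": state.omega_yaw}
            )
            traj = None
            if pose_angles is not None:
                theta = np.interp(state.t, pose_angles.t, pose_angles.theta_body_cam)
                ang = kin_mod.PoseAngles(
                    t=state.t, theta_body_cam=theta,
                    theta_head_cricket=np.zeros_like(state.t),
                )
                traj = kin_mod.integrate_trajectory(vel, ang)
            return frame, gaps, state, vel_df, traj

        frame, gaps, state, vel_df, traj = _stage("kinematics", _kin)
        results["velocity"] = vel_df
        vel_df.to_csv(out_dir / "velocity.csv", index=False)
        if traj is not None:
            bl = config.body_length_mm
            traj_df = pd.DataFrame(
                {"t": traj.t, "x_BL": traj.x / bl, "y_BL": traj.y / bl}
            )
            traj_df.to_csv(out_dir / "trajectory.csv", index=False)
            results["trajectory"] = traj_df
        log_lines.append(f"kinematics: {len(gaps)} gaps > 3 samples in sensor log")
        t_arr = vel_df["t"].to_numpy()
        speed_fn = lambda t0: np.interp(t0, t_arr, vel_df["v_BLs"].to_numpy())  # noqa: E731
        yaw_fn = lambda t0: np.interp(t0, t_arr, vel_df["omega_yaw"].to_numpy())  # noqa: E731

    if "gait" in stages:
        def _phases():
            samples = []
            skipped_total = 0
            for ref_leg, tgt_leg in PHASE_PAIRS:
                ref, tgt = events[ref_leg], events[tgt_leg]
                if ref.touchdowns.size < 2 or tgt.touchdowns.size < 1:
                    skipped_total += 1
                    continue
                smp, skipped = gait_mod.phase_differences(
                    ref, tgt, speed=speed_fn, yaw_rate=yaw_fn
                )
                samples.extend(smp)
                skipped_total += skipped
            return samples, skipped_total

        samples, skipped = _stage("phases", _phases)
        results["phase_samples"] = samples
        log_lines.append(f"phases: {len(samples)} samples, {skipped} cycles skipped")
        gait_mod.phase_samples_to_frame(samples).to_csv(
            out_dir / "phases.csv", index=False
        )
        rows = []
        by_pair: dict[str, list] = {}
        for s in samples:
            by_pair.setdefault(s.pair, []).append(s)
        for pair, smp in by_pair.items():
            groups = {"all": smp}
            if speed_fn is not None:
                groups.update(
                    {f"{rot}|{spd}": g for (rot, spd), g in
                     gait_mod.stratify_samples(smp).items()}
                )
            for stratum, grp in groups.items():
                summ = circular_summary([g.phi for g in grp])
                rows.append(
                    {"pair": pair, "stratum": stratum,
                     "theta_hat": summ.theta_hat, "R": summ.R, "n": summ.n}
                )
        summary_df = pd.DataFrame(rows)
        summary_df.to_csv(out_dir / "summary.csv", index=False)
        results["summary"] = summary_df

    if "emg" in stages:
        def _emg():
            records, gaps = io_mod.read_emg_log(inputs["emg"])
            if len(records) < 2:
                raise ValueError("need at least two EMG channels for phase analysis")
            trains = {
                name: emg_mod.extract_spike_train(rec)
                for name, rec in records.items()
            }
            first = next(iter(trains.values()))
            spec = emg_mod.power_spectrum(
                first.values.astype(float), first.fs,
                segment_s=config.segment_s, overlap=config.overlap,
            )
            f_peak = emg_mod.select_peak_frequency(spec, band=config.peak_band_hz)
            duration = first.values.size / first.fs
            if duration * f_peak < emg_mod.MIN_TRIAL_CYCLES:
                raise ValueError(
                    f"recording spans {duration * f_peak:.1f} gait cycles; "
                    f"a trial needs more than {emg_mod.MIN_TRIAL_CYCLES}"
                )
            rows = []
            names = list(trains)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    coh, phase, low = emg_mod.cross_spectrum_phase(
                        trains[a].values.astype(float),
                        trains[b].values.astype(float),
                        first.fs, f_peak,
                        segment_s=config.segment_s, overlap=config.overlap,
                        coherence_floor=config.coherence_floor,
                    )
                    rows.append(
                        {"pair": f"{a}-{b}", "f_peak_Hz": f_peak,
                         "coherence": coh, "phase_rad": phase,
                         "I_sync": float(np.cos(phase)), "low_confidence": low}
                    )
            return pd.DataFrame(rows), gaps

        emg_df, emg_gaps = _stage("emg", _emg)
        emg_df.to_csv(out_dir / "emg_phases.csv", index=False)
        results["emg_phases"] = emg_df
        log_lines.append(f"emg: {len(emg_df)} channel pairs, {len(emg_gaps)} log gaps")

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


def watson_williams_table(groups: dict, alpha: float = 0.005) -> pd.DataFrame:
    """Pairwise Watson-Williams tests between named angle groups.

    ``groups`` maps condition name -> array of angles (rad).  Returns one
    row per condition pair with F, degrees of freedom, p-value and whether
    p < alpha.
    """
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = emg_mod.watson_williams(groups[a], groups[b])
            rows.append(
                {"condition_A": a, "condition_B": b, "F": res.F,
                 "df1": res.df1, "df2": res.df2, "p": res.p_value,
                 "significant": res.p_value < alpha,
                 "assumption_ok": res.assumption_ok}
            )
    return pd.DataFrame(rows)
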