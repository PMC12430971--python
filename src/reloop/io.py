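"""Plain-text readers and writers for the toolkit's file dialects.

* sEMG CSV: columns ``t_s,flexor_mv,extensor_mv`` with a JSON sidecar
  ``{subject_id, phase, sample_rate_hz}`` (same stem, ``.json`` extension).
* IMU CSV: ``t_s,ax_g,ay_g,az_g,gx_dps,gy_dps,gz_dps`` with sidecar
  ``{joint, task_id, sample_rate_hz}``.
* RMS CSV: ``window_start_s,channel,rms_mv``.
* Threshold JSON: ``{flexion_on_mv, extension_on_mv, hysteresis_ratio}``.
* Command stream CSV: ``t_s,command``.
* Trial log CSV: ``day,trial,coins,score,deaths``.
* Trials CSV: ``subject,task,difficulty,trial,ct_s,blocks``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import control as ctl
from . import emg_pipeline as ep
from . import kinematics as kin
from ._errors import InputError


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_emg_csv(rec: ep.EmgRecording, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "t_s": rec.times,
            "flexor_mv": rec.channels["wrist_flexor"],
            "extensor_mv": rec.channels["wrist_extensor"],
        }
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {
                "subject_id": rec.subject_id,
                "phase": rec.phase,
                "sample_rate_hz": rec.sample_rate_hz,
            }
        )
    )


def load_emg_csv(path) -> ep.EmgRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("t_s", "flexor_mv", "extensor_mv"):
        if col not in frame.columns:
            raise InputError(f"sEMG CSV missing column {col!r}")
    meta = json.loads(_sidecar(path).read_text())
    rec = ep.EmgRecording(
        subject_id=str(meta["subject_id"]),
        phase=str(meta["phase"]),
        channels={
            "wrist_flexor": frame["flexor_mv"].to_numpy(dtype=float),
            "wrist_extensor": frame["extensor_mv"].to_numpy(dtype=float),
        },
        sample_rate_hz=float(meta["sample_rate_hz"]),
        start_time_s=float(frame["t_s"].iloc[0]) if len(frame) else 0.0,
    )
    return rec


def save_rms_csv(series_by_channel: dict, path) -> None:
    rows = []
    for channel, series in series_by_channel.items():
        for t, r in zip(series.window_start_s, series.rms_mv):
            rows.append({"window_start_s": t, "channel": channel, "rms_mv": r})
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def save_thresholds(thr: ctl.ThresholdPair, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "flexion_on_mv": thr.flexion_on_mv,
                "extension_on_mv": thr.extension_on_mv,
                "hysteresis_ratio": thr.hysteresis_ratio,
            },
            indent=2,
        )
    )


def load_thresholds(path) -> ctl.ThresholdPair:
    d = json.loads(Path(path).read_text())
    return ctl.ThresholdPair(
        flexion_on_mv=float(d["flexion_on_mv"]),
        extension_on_mv=float(d["extension_on_mv"]),
        hysteresis_ratio=float(d.get("hysteresis_ratio", 0.8)),
    )


def save_commands_csv(commands, path) -> None:
    pd.DataFrame(
        {"t_s": [c.time_s for c in commands], "command": [c.value.value for c in commands]}
    ).to_csv(Path(path), index=False)


def save_imu_csv(rec: kin.ImuRecording, path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([rec.times, rec.accel_g, rec.gyro_dps]),
        columns=["t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"],
    )
    frame.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {
                "joint": rec.joint,
                "task_id": rec.task_id,
                "sample_rate_hz": rec.sample_rate_hz,
            }
        )
    )


def load_imu_csv(path) -> kin.ImuRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return kin.ImuRecording(
        joint=str(meta["joint"]),
        accel_g=frame[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        gyro_dps=frame[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        task_id=str(meta.get("task_id", "")),
    )


def save_trials_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(Path(path), index=False)


def load_trials_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path))
    required = {"subject", "task", "trial"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"trials CSV missing columns {sorted(missing)}")
    return frame


def save_trial_log_csv(results, path) -> None:
    pd.DataFrame(
        {
            "day": [r.day_index for r in results],
            "trial": [r.trial_index for r in results],
            "coins": [r.coins for r in results],
            "score": [r.score for r in results],
            "deaths": [r.deaths for r in results],
        }
    ).to_csv(Path(path), index=False)


def save_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
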