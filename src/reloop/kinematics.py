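"""IMU kinematics: movement smoothness and range of motion for shoulder/elbow.

Six-axis recordings (3-axis accelerometer in g, ±2 g; 3-axis gyroscope in
deg/s, ±2000 deg/s) sampled at 125 Hz are low-pass filtered at 5 Hz, then
summarised by

* the rate of change of acceleration (jerk, g/s) per axis,
* the plane-curve curvature of the (t, a(t)) graph,
  kappa = |a''| / (1 + a'^2)^(3/2), per axis, and
* range of motion (max - min) per axis and per Euler angle, with a
  plausibility flag against joint bounds (shoulder 200 deg, elbow 180 deg).

Orientation is estimated with a complementary filter (gyro integration
blended with the accelerometer gravity direction for pitch/roll; yaw is
gyro-only), intrinsic Z-Y-X Euler convention, angles unwrapped before ROM.
Derivatives use central differences (one-sided at the endpoints), which are
second-order accurate on the interior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._errors import ConfigurationError, InputError

JOINT_ROM_BOUNDS_DEG = {"shoulder": 200.0, "elbow": 180.0}

ACCEL_RANGE_G = 2.0
GYRO_RANGE_DPS = 2000.0

AXES = ("x", "y", "z")
ANGLES = ("pitch", "roll", "yaw")


@dataclass
class ImuRecording:
    """Six-axis joint recording: acceleration in g, angular rate in deg/s."""

    joint: str
    accel_g: np.ndarray  # (N, 3)
    gyro_dps: np.ndarray  # (N, 3)
    sample_rate_hz: float = 125.0
    task_id: str = ""

    def __post_init__(self):
        self.accel_g = np.asarray(self.accel_g, dtype=float)
        self.gyro_dps = np.asarray(self.gyro_dps, dtype=float)
        if self.joint not in JOINT_ROM_BOUNDS_DEG:
            raise InputError(f"unknown joint {self.joint!r}")
        for name, arr in (("accel_g", self.accel_g), ("gyro_dps", self.gyro_dps)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InputError(f"{name} must have shape (N, 3)")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"{name} contains NaN/Inf")
        if self.accel_g.shape[0] != self.gyro_dps.shape[0]:
            raise InputError("accel and gyro lengths differ")
        if np.max(np.abs(self.accel_g), initial=0.0) > ACCEL_RANGE_G * (1 + 1e-9):
            raise InputError(f"acceleration outside the ±{ACCEL_RANGE_G} g sensor range")
        if np.max(np.abs(self.gyro_dps), initial=0.0) > GYRO_RANGE_DPS * (1 + 1e-9):
            raise InputError(
                f"angular rate outside the ±{GYRO_RANGE_DPS} deg/s sensor range"
            )
        if self.sample_rate_hz <= 0:
            raise InputError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.accel_g.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class SmoothnessProfile:
    """Jerk and curvature tracks plus scalar summaries."""

    jerk: np.ndarray  # (N, 3), g/s
    curvature: np.ndarray  # (N, 3), curvature of the (t, a) graph
    summary: dict  # jerk_peak, jerk_rms, curvature_peak


@dataclass
class RomResult:
    """Per-entry range of motion with plausibility flags (never clipped)."""

    joint: str
    rom_deg: dict  # entry -> max - min
    valid: dict  # entry -> bool


def lowpass_imu(rec: ImuRecording, cutoff_hz: float = 5.0, order: int = 4) -> ImuRecording:
    """Zero-phase Butterworth low-pass on all six axes (default 5 Hz)."""
    nyq = rec.sample_rate_hz / 2.0
    if not (0.0 < cutoff_hz < nyq):
        raise ConfigurationError(f"cutoff {cutoff_hz} Hz must be in (0, {nyq})")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate_hz, output="sos")
    padlen = min(rec.n_samples - 1, int(round(rec.sample_rate_hz)))
    try:
        accel = signal.sosfiltfilt(sos, rec.accel_g, axis=0, padtype="odd", padlen=padlen)
        gyro = signal.sosfiltfilt(sos, rec.gyro_dps, axis=0, padtype="odd", padlen=padlen)
    except ValueError as exc:
        raise InputError(f"recording too short for filtering: {exc}") from exc
    # filtering may overshoot the hard sensor range by a whisker; keep as-is
    out = dataclasses.replace(rec)
    out.accel_g = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    out.gyro_dps = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return out


def _require_min_samples(rec: ImuRecording, n: int = 3) -> None:
    if rec.n_samples < n:
        raise InputError(f"need at least {n} samples")


def jerk_series(rec: ImuRecording) -> np.ndarray:
    """Rate of change of acceleration, g/s, per axis (central differences)."""
    _require_min_samples(rec)
    return np.gradient(rec.accel_g, rec.dt, axis=0)


def curvature_series(rec: ImuRecording) -> np.ndarray:
    """Curvature of the graph (t, a(t)) per axis: |a''| / (1 + a'^2)^(3/2).

    t is in seconds and a in g, both unscaled.
    """
    _require_min_samples(rec)
    da = np.gradient(rec.accel_g, rec.dt, axis=0)
    d2a = np.gradient(da, rec.dt, axis=0)
    return np.abs(d2a) / np.power(1.0 + np.square(da), 1.5)


def smoothness_profile(rec: ImuRecording) -> SmoothnessProfile:
    jerk = jerk_series(rec)
    curv = curvature_series(rec)
    return SmoothnessProfile(
        jerk=jerk,
        curvature=curv,
        summary={
            "jerk_peak": float(np.max(np.abs(jerk))),
            "jerk_rms": float(np.sqrt(np.mean(np.square(jerk)))),
            "curvature_peak": float(np.max(curv)),
        },
    )


def _accel_pitch_roll(accel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ax, ay, az = accel[:, 0], accel[:, 1], accel[:, 2]
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    roll = np.arctan2(ay, az)
    return pitch, roll


def estimate_orientation(rec: ImuRecording, blend: float = 0.98) -> dict:
    """Complementary-filter Euler angles in degrees (intrinsic Z-Y-X).

    Pitch and roll integrate the gyro and are pulled toward the
    accelerometer's gravity direction with weight ``1 - blend`` per sample;
    yaw is pure gyro integration (no magnetometer). ``blend=1`` gives pure
    gyro dead-reckoning. Angles are unwrapped, so sweeps beyond 180 deg are
    not aliased. Initial pitch/roll come from the first accelerometer sample;
    yaw starts at zero.
    """
    _require_min_samples(rec, 2)
    if not (0.0 <= blend <= 1.0):
        raise ConfigurationError("blend must be in [0, 1]")
    dt = rec.dt
    gyro = np.deg2rad(rec.gyro_dps)
    acc_pitch, acc_roll = _accel_pitch_roll(rec.accel_g)
    n = rec.n_samples
    pitch = np.empty(n)
    roll = np.empty(n)
    yaw = np.empty(n)
    pitch[0], roll[0], yaw[0] = acc_pitch[0], acc_roll[0], 0.0
    for i in range(1, n):
        p, q, r = gyro[i]  # body rates: roll, pitch, yaw axes
        gyro_roll = roll[i - 1] + p * dt
        gyro_pitch = pitch[i - 1] + q * dt
        roll[i] = blend * gyro_roll + (1.0 - blend) * acc_roll[i]
        pitch[i] = blend * gyro_pitch + (1.0 - blend) * acc_pitch[i]
        yaw[i] = yaw[i - 1] + r * dt
    return {
        "pitch": np.rad2deg(np.unwrap(pitch)),
        "roll": np.rad2deg(np.unwrap(roll)),
        "yaw": np.rad2deg(np.unwrap(yaw)),
    }


def rom(series) -> float:
    """Range of motion of a sequence: max - min (same unit as the input)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("empty series has no ROM")
    return float(np.max(series) - np.min(series))


def validate_rom(rom_by_entry: dict, joint: str) -> RomResult:
    """Flag ROM entries exceeding the joint's plausibility bound.

    Bounds: shoulder 200 deg, elbow 180 deg. Violations are flagged
    (``valid=False``), never clipped.
    """
    if joint not in JOINT_ROM_BOUNDS_DEG:
        raise InputError(f"unknown joint {joint!r}")
    bound = JOINT_ROM_BOUNDS_DEG[joint]
    roms = {k: float(v) for k, v in rom_by_entry.items()}
    if any(v < 0 for v in roms.values()):
        raise InputError("ROM values must be non-negative")
    valid = {k: v <= bound for k, v in roms.items()}
    return RomResult(joint=joint, rom_deg=roms, valid=valid)


def rom_report(rec: ImuRecording, blend: float = 0.98) -> RomResult:
    """Per-axis gyro-angle and per-Euler-angle ROM with plausibility flags."""
    angles = estimate_orientation(rec, blend=blend)
    roms = {name: rom(series) for name, series in angles.items()}
    # per-axis ROM of the integrated gyro angle about each sensor axis
    integrated = np.cumsum(rec.gyro_dps, axis=0) * rec.dt
    for i, axis in enumerate(AXES):
        roms[axis] = rom(integrated[:, i])
    return validate_rom(roms, rec.joint)
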