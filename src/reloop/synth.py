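"""Synthetic data generators with known ground truth.

No raw recordings ship with the toolkit, so every pipeline stage is exercised
on synthetic data whose generating parameters are the ground truth:

* **sEMG** — a band-limited Gaussian carrier (20–150 Hz) amplitude-modulated
  by the intent envelope (rest / flexion / extension blocks with 100 ms
  rise/fall), plus white noise at a configurable SNR and an optional 50 Hz
  power-line sinusoid. The carrier is normalised so an active burst of
  amplitude A has RMS A/sqrt(2), like a sinusoid of that amplitude. This is
  a feature-level surrogate, not a physiological motor-unit model.
* **IMU** — minimum-jerk joint-angle trajectories between waypoints,
  differentiated analytically to body angular rates and projected to the
  gravity direction for the accelerometer, plus sensor noise and an optional
  slow compensatory drift.
* **Sessions** — a full paired pre/post battery (task trials, BBT counts,
  questionnaires, sEMG-derived RMS features, IMU reaches) for n subjects
  with programmed effects: multiplicative completion-time change, additive
  BBT change, multiplicative sEMG RMS gain.

All generators draw from named sub-streams of one root seed, so the same
seed always reproduces the same dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import emg_pipeline as ep
from . import kinematics as kin
from ._errors import InputError
from ._rng import stream_rng

# ---------------------------------------------------------------------------
# sEMG
# ---------------------------------------------------------------------------

#: default burst amplitudes (mV) per muscle for a trans-radial stump
DEFAULT_BURST_MV = {"wrist_flexor": 0.45, "wrist_extensor": 0.40}

INTENT_TO_CHANNEL = {"flexion": "wrist_flexor", "extension": "wrist_extensor"}


@dataclass(frozen=True)
class EmgScenario:
    """Intent timeline plus signal-model parameters for one recording."""

    intent_timeline: tuple = (("rest", 2.0), ("flexion", 3.0), ("rest", 2.0))
    burst_amplitude_mv: dict = field(default_factory=lambda: dict(DEFAULT_BURST_MV))
    snr_db: float = 20.0
    session_gain: float = 1.0
    powerline_amp_mv: float = 0.05
    rng_seed: int = 0
    sample_rate_hz: float = 1000.0
    rise_fall_s: float = 0.1
    subject_id: str = "synthetic"
    phase: str = "pre"

    def __post_init__(self):
        if not self.intent_timeline:
            raise InputError("intent_timeline must not be empty")
        for label, dur in self.intent_timeline:
            if label not in ("rest", "flexion", "extension"):
                raise InputError(f"unknown intent label {label!r}")
            if dur <= 0:
                raise InputError("timeline durations must be positive")
        if not np.isfinite(self.snr_db):
            raise InputError("snr_db must be finite")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.intent_timeline)

    @property
    def transition_times_s(self) -> tuple:
        edges = np.cumsum([d for _, d in self.intent_timeline])[:-1]
        return tuple(float(t) for t in edges)


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-amplitude carrier: band-passed white noise with RMS 1/sqrt(2)."""
    sos = signal.butter(4, [20.0, 150.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]
    rms = np.sqrt(np.mean(np.square(x)))
    return x / (rms * np.sqrt(2.0))


def _smooth_envelope(mask: np.ndarray, fs: float, rise_fall_s: float) -> np.ndarray:
    w = max(1, int(round(rise_fall_s * fs)))
    kernel = np.hanning(w + 2)[1:-1]
    kernel /= kernel.sum()
    return np.convolve(mask.astype(float), kernel, mode="same")


def generate_emg(scn: EmgScenario) -> tuple[ep.EmgRecording, np.ndarray]:
    """Synthesize a two-channel recording plus per-sample intent labels."""
    fs = scn.sample_rate_hz
    seg_n = [int(round(d * fs)) for _, d in scn.intent_timeline]
    n = sum(seg_n)
    labels = np.empty(n, dtype="<U9")
    pos = 0
    for (label, _), k in zip(scn.intent_timeline, seg_n):
        labels[pos : pos + k] = label
        pos += k
    t = np.arange(n) / fs
    channels = {}
    for channel in ep.CHANNELS:
        rng = stream_rng(scn.rng_seed, "emg", channel)
        amp = scn.burst_amplitude_mv[channel]
        mask = np.array([INTENT_TO_CHANNEL.get(l) == channel for l in labels])
        envelope = _smooth_envelope(mask, fs, scn.rise_fall_s)
        carrier = _bandlimited_carrier(rng, n, fs)
        burst = scn.session_gain * amp * envelope * carrier
        noise_rms = (amp / np.sqrt(2.0)) / (10.0 ** (scn.snr_db / 20.0))
        noise = noise_rms * rng.standard_normal(n)
        powerline = scn.powerline_amp_mv * np.sin(2.0 * np.pi * 50.0 * t)
        channels[channel] = burst + noise + powerline
    rec = ep.EmgRecording(
        subject_id=scn.subject_id,
        phase=scn.phase,
        channels=channels,
        sample_rate_hz=fs,
    )
    return rec, labels


def generate_calibration_set(
    rng_seed: int = 0,
    snr_db: float = 20.0,
    duration_s: float = 6.0,
    burst_amplitude_mv: dict | None = None,
    session_gain: float = 1.0,
):
    """Rest / flexion-hold / extension-hold recordings for threshold calibration."""
    kw = dict(
        snr_db=snr_db,
        session_gain=session_gain,
        burst_amplitude_mv=dict(burst_amplitude_mv or DEFAULT_BURST_MV),
    )
    rest, _ = generate_emg(
        EmgScenario(intent_timeline=(("rest", duration_s),), rng_seed=rng_seed, **kw)
    )
    flex, _ = generate_emg(
        EmgScenario(
            intent_timeline=(("flexion", duration_s),), rng_seed=rng_seed + 1, **kw
        )
    )
    ext, _ = generate_emg(
        EmgScenario(
            intent_timeline=(("extension", duration_s),), rng_seed=rng_seed + 2, **kw
        )
    )
    return rest, flex, ext


# ---------------------------------------------------------------------------
# IMU
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImuScenario:
    """Reach trajectory (Euler waypoints, degrees) plus sensor noise levels."""

    waypoints_deg: tuple = ((0.0, 0.0, 0.0), (60.0, 0.0, 0.0))  # (pitch, roll, yaw)
    movement_duration_s: float = 2.0
    pre_rest_s: float = 1.0
    post_rest_s: float = 0.5
    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 0.5
    compensation_amplitude_deg: float = 0.0
    joint: str = "shoulder"
    task_id: str = "reach"
    rng_seed: int = 0
    sample_rate_hz: float = 125.0

    def __post_init__(self):
        if len(self.waypoints_deg) < 2:
            raise InputError("need at least two waypoints")
        if self.movement_duration_s <= 0:
            raise InputError("movement_duration_s must be positive")


def _min_jerk(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position profile s(u) and its derivative ds/du on [0, 1]."""
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = 30 * u**2 - 60 * u**3 + 30 * u**4
    return s, ds


def _trajectory(scn: ImuScenario) -> tuple[np.ndarray, np.ndarray]:
    """Euler angles (N, 3) in radians and their analytic rates (rad/s)."""
    fs = scn.sample_rate_hz
    wp = np.deg2rad(np.asarray(scn.waypoints_deg, dtype=float))  # (pitch, roll, yaw)
    n_seg = len(wp) - 1
    seg_T = scn.movement_duration_s / n_seg
    parts_a, parts_r = [], []
    n_pre = int(round(scn.pre_rest_s * fs))
    parts_a.append(np.tile(wp[0], (n_pre, 1)))
    parts_r.append(np.zeros((n_pre, 3)))
    for i in range(n_seg):
        k = int(round(seg_T * fs))
        u = np.arange(k) / (seg_T * fs)
        s, ds = _min_jerk(u)
        delta = wp[i + 1] - wp[i]
        parts_a.append(wp[i] + np.outer(s, delta))
        parts_r.append(np.outer(ds / seg_T, delta))
    n_post = int(round(scn.post_rest_s * fs))
    parts_a.append(np.tile(wp[-1], (n_post, 1)))
    parts_r.append(np.zeros((n_post, 3)))
    return np.vstack(parts_a), np.vstack(parts_r)


def generate_imu_reach(scn: ImuScenario) -> tuple[kin.ImuRecording, dict]:
    """Six-axis streams at 125 Hz plus the true Euler angle series (degrees)."""
    rng = stream_rng(scn.rng_seed, "imu", scn.joint, scn.task_id)
    angles, rates = _trajectory(scn)
    n = angles.shape[0]
    t = np.arange(n) / scn.sample_rate_hz
    if scn.compensation_amplitude_deg:
        # slow compensatory trunk/shoulder drift superposed on roll
        drift = np.deg2rad(scn.compensation_amplitude_deg) * np.sin(
            np.pi * t / t[-1]
        )
        angles = angles.copy()
        angles[:, 1] += drift
        rates = rates.copy()
        rates[:, 1] += np.deg2rad(scn.compensation_amplitude_deg) * (
            np.pi / t[-1]
        ) * np.cos(np.pi * t / t[-1])
    pitch, roll, yaw = angles[:, 0], angles[:, 1], angles[:, 2]
    dpitch, droll, dyaw = rates[:, 0], rates[:, 1], rates[:, 2]
    # body angular rates from Euler (Z-Y-X) angle rates
    p = droll - dyaw * np.sin(pitch)
    q = dpitch * np.cos(roll) + dyaw * np.cos(pitch) * np.sin(roll)
    r = -dpitch * np.sin(roll) + dyaw * np.cos(pitch) * np.cos(roll)
    gyro = np.rad2deg(np.column_stack([p, q, r]))
    # gravity direction in the body frame (specific force, g units); the slow
    # reach makes linear acceleration negligible relative to gravity
    accel = np.column_stack(
        [
            -np.sin(pitch),
            np.cos(pitch) * np.sin(roll),
            np.cos(pitch) * np.cos(roll),
        ]
    )
    accel = accel + scn.accel_noise_g * rng.standard_normal(accel.shape)
    gyro = gyro + scn.gyro_noise_dps * rng.standard_normal(gyro.shape)
    accel = np.clip(accel, -kin.ACCEL_RANGE_G, kin.ACCEL_RANGE_G)
    gyro = np.clip(gyro, -kin.GYRO_RANGE_DPS, kin.GYRO_RANGE_DPS)
    rec = kin.ImuRecording(
        joint=scn.joint,
        accel_g=accel,
        gyro_dps=gyro,
        sample_rate_hz=scn.sample_rate_hz,
        task_id=scn.task_id,
    )
    truth = {
        "pitch": np.rad2deg(pitch),
        "roll": np.rad2deg(roll),
        "yaw": np.rad2deg(yaw),
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Full pre/post sessions
# ---------------------------------------------------------------------------

#: baseline completion times (s) for a typical trans-radial prosthesis user:
#: wooden-peg placing/submitting take minutes, ADL items ~12 s (simple) or
#: ~20 s (complex), giving a pre-training ADL group mean near 15 s
TASK_BASELINES_S = {
    "placing": 150.0,
    "submitting": 90.0,
    **{f"adl_{i}": 12.0 for i in range(1, 7)},
    **{f"adl_{i}": 20.0 for i in range(7, 11)},
}
BBT_BASELINE_BLOCKS = 16.0
TRIALS_PER_TASK = {"placing": 3, "submitting": 3, **{f"adl_{i}": 1 for i in range(1, 11)}}
BBT_TRIALS = 5


@dataclass(frozen=True)
class EffectProfile:
    """Programmed pre-to-post effects and noise levels for a synthetic study."""

    ct_change_pct: float = 0.0  # signed; -35 means post CTs are 35% shorter
    bbt_delta_blocks: float = 0.0
    rms_gain: float = 1.0  # multiplicative sEMG amplitude gain (1.048 = +4.8%)
    ct_noise_cv: float = 0.10  # trial-to-trial lognormal CV of CTs
    bbt_noise_sd: float = 1.0  # blocks
    between_subject_sd: float = 0.2  # lognormal sd of subject ability
    snr_db: float = 20.0


@dataclass
class SessionDataset:
    pre_trials: pd.DataFrame
    post_trials: pd.DataFrame
    questionnaires: pd.DataFrame
    rms_pre: dict  # subject -> muscle -> mean RMS (mV)
    rms_post: dict
    imu: dict | None  # (phase, subject) -> (ImuRecording, truth)
    profile: EffectProfile
    seed: int


def _measured_rms(subject: str, phase: str, amp: dict, gain: float,
                  snr_db: float, seed: int, duration_s: float) -> dict:
    """Mean RMS per muscle measured through the full offline pipeline."""
    out = {}
    for intent, muscle in INTENT_TO_CHANNEL.items():
        scn = EmgScenario(
            intent_timeline=((intent, duration_s),),
            burst_amplitude_mv=amp,
            snr_db=snr_db,
            session_gain=gain,
            rng_seed=seed + (0 if intent == "flexion" else 1),
            subject_id=subject,
            phase=phase,
        )
        rec, _ = generate_emg(scn)
        series = ep.rms_series(ep.preprocess(rec))
        out[muscle] = ep.mean_rms(series[muscle])
    return out


def generate_session_dataset(
    profile: EffectProfile = EffectProfile(),
    n_subjects: int = 6,
    seed: int = 0,
    include_signals: bool = True,
    emg_duration_s: float = 30.0,
) -> SessionDataset:
    """Paired pre/post battery for ``n_subjects`` with the programmed effects.

    With ``include_signals`` the per-subject RMS features are measured by
    running synthetic hold recordings through the full sEMG pipeline and one
    IMU reach per subject/session is generated; without it the RMS features
    are drawn directly from the signal model's expected values (cheap mode
    for large statistical simulations over completion times).
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    ct_factor = 1.0 + profile.ct_change_pct / 100.0
    if ct_factor <= 0:
        raise InputError("ct_change_pct must keep completion times positive")
    trial_rows = {"pre": [], "post": []}
    q_rows = []
    rms_pre: dict = {}
    rms_post: dict = {}
    imu: dict = {}
    for s_idx in range(n_subjects):
        sid = f"S{s_idx + 1:02d}"
        rng = stream_rng(seed, "session", sid)
        ability = float(np.exp(rng.normal(0.0, profile.between_subject_sd)))
        for session, factor in (("pre", 1.0), ("post", ct_factor)):
            for task, n_trials in TRIALS_PER_TASK.items():
                base = TASK_BASELINES_S[task] * ability
                for trial in range(n_trials):
                    noise = float(np.exp(rng.normal(0.0, profile.ct_noise_cv)))
                    trial_rows[session].append(
                        {
                            "subject": sid,
                            "task": task,
                            "difficulty": "n/a",
                            "trial": trial,
                            "ct_s": base * factor * noise,
                            "blocks": None,
                        }
                    )
            bbt_base = BBT_BASELINE_BLOCKS * ability
            for trial in range(BBT_TRIALS):
                mean = bbt_base + (profile.bbt_delta_blocks if session == "post" else 0.0)
                blocks = max(0, int(round(rng.normal(mean, profile.bbt_noise_sd))))
                trial_rows[session].append(
                    {
                        "subject": sid,
                        "task": "bbt",
                        "difficulty": "n/a",
                        "trial": trial,
                        "ct_s": None,
                        "blocks": blocks,
                    }
                )
        # sEMG RMS features
        amp_factor = float(np.exp(rng.normal(0.0, 0.15)))
        amp = {m: a * amp_factor for m, a in DEFAULT_BURST_MV.items()}
        if include_signals:
            emg_seed = int(stream_rng(seed, "emg-seeds", sid).integers(0, 2**31 - 64))
            rms_pre[sid] = _measured_rms(
                sid, "pre", amp, 1.0, profile.snr_db, emg_seed, emg_duration_s
            )
            rms_post[sid] = _measured_rms(
                sid, "post_day1", amp, profile.rms_gain, profile.snr_db,
                emg_seed + 32, emg_duration_s,
            )
            for session in ("pre", "post"):
                scn = ImuScenario(
                    rng_seed=int(stream_rng(seed, "imu-seeds", sid, session).integers(0, 2**31 - 1)),
                    task_id=f"{session}-reach",
                )
                imu[(session, sid)] = generate_imu_reach(scn)
        else:
            meas = float(np.exp(rng.normal(0.0, 0.01)))
            rms_pre[sid] = {
                m: a / np.sqrt(2.0) * meas for m, a in amp.items()
            }
            meas_post = float(np.exp(rng.normal(0.0, 0.01)))
            rms_post[sid] = {
                m: a / np.sqrt(2.0) * profile.rms_gain * meas_post for m, a in amp.items()
            }
        # questionnaires (one response per instrument, post session)
        qrng = stream_rng(seed, "questionnaires", sid)
        for instrument, lo, hi in (
            ("user_q", 4, 5),
            ("imi", 5, 7),
            ("nasa_tlx", 2, 9),
            ("task_prosthesis_q", 1, 3),
        ):
            from .assessment import INSTRUMENTS

            n_items = INSTRUMENTS[instrument].n_items
            for item, score in enumerate(qrng.integers(lo, hi + 1, size=n_items)):
                q_rows.append(
                    {
                        "subject": sid,
                        "instrument": instrument,
                        "item": item,
                        "score": int(score),
                    }
                )
    return SessionDataset(
        pre_trials=pd.DataFrame(trial_rows["pre"]),
        post_trials=pd.DataFrame(trial_rows["post"]),
        questionnaires=pd.DataFrame(q_rows),
        rms_pre=rms_pre,
        rms_post=rms_post,
        imu=imu or None,
        profile=profile,
        seed=seed,
    )
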