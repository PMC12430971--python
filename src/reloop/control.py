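"""Threshold-based two-channel myoelectric control.

Wrist-flexion sEMG drives the game character LEFT, wrist-extension sEMG drives
it RIGHT. Each muscle has an RMS on-threshold calibrated between its rest and
active levels; a hysteresis off-threshold (a fixed fraction of the
on-threshold) prevents chatter at the boundary. Co-activation of both muscles
is treated as NEUTRAL — the safest interpretation of an ambiguous command.

The online decoder evaluates short sliding RMS windows (default 0.2 s window,
0.05 s step), much shorter than the 5 s offline feature windows, because a
playable game needs sub-second command latency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import emg_pipeline as ep
from ._errors import CalibrationError, InputError


class Command(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class ControlCommand:
    """One decoded intent at one decision tick."""

    value: Command
    time_s: float


@dataclass(frozen=True)
class ThresholdPair:
    """Per-muscle RMS on-thresholds (mV) with a shared hysteresis ratio.

    The off-threshold for leaving the active state is
    ``hysteresis_ratio * on_threshold``.
    """

    flexion_on_mv: float
    extension_on_mv: float
    hysteresis_ratio: float = 0.8

    def __post_init__(self):
        if self.flexion_on_mv <= 0 or self.extension_on_mv <= 0:
            raise InputError("on-thresholds must be positive")
        if not (0.0 < self.hysteresis_ratio <= 1.0):
            raise InputError("hysteresis_ratio must be in (0, 1]")

    @property
    def flexion_off_mv(self) -> float:
        return self.hysteresis_ratio * self.flexion_on_mv

    @property
    def extension_off_mv(self) -> float:
        return self.hysteresis_ratio * self.extension_on_mv


@dataclass(frozen=True)
class DecoderConfig:
    decision_window_s: float = 0.2
    decision_step_s: float = 0.05
    calibration_gain_k: float = 0.4

    def __post_init__(self):
        if self.decision_window_s <= 0 or self.decision_step_s <= 0:
            raise InputError("decision window/step must be positive")
        if self.decision_step_s > self.decision_window_s:
            raise InputError("decision_step_s must not exceed decision_window_s")
        if not (0.0 < self.calibration_gain_k <= 1.0):
            raise InputError("calibration_gain_k must be in (0, 1]")


def _mean_decision_rms(rec: ep.EmgRecording, channel: str, cfg: DecoderConfig) -> float:
    blocks = ep.segment_array(
        rec.channels[channel], rec.sample_rate_hz, cfg.decision_window_s, cfg.decision_step_s
    )
    return float(np.mean(np.sqrt(np.mean(np.square(blocks), axis=1))))


def calibrate_thresholds(
    rest: ep.EmgRecording,
    flexion_trials: ep.EmgRecording,
    extension_trials: ep.EmgRecording,
    cfg: DecoderConfig = DecoderConfig(),
    hysteresis_ratio: float = 0.8,
) -> ThresholdPair:
    """Set per-muscle thresholds between rest and active mean RMS.

    threshold = rest_mean + k * (active_mean - rest_mean), per channel, with
    the flexor calibrated from the flexion trials and the extensor from the
    extension trials. Raises CalibrationError when a muscle's active RMS does
    not exceed its rest RMS (the signals are indistinguishable).
    """
    k = cfg.calibration_gain_k
    thresholds = {}
    for channel, active_rec in (
        ("wrist_flexor", flexion_trials),
        ("wrist_extensor", extension_trials),
    ):
        rest_rms = _mean_decision_rms(rest, channel, cfg)
        active_rms = _mean_decision_rms(active_rec, channel, cfg)
        if active_rms <= rest_rms:
            raise CalibrationError(
                f"{channel}: active mean RMS ({active_rms:.4g} mV) does not exceed "
                f"rest mean RMS ({rest_rms:.4g} mV)"
            )
        thresholds[channel] = rest_rms + k * (active_rms - rest_rms)
    return ThresholdPair(
        flexion_on_mv=thresholds["wrist_flexor"],
        extension_on_mv=thresholds["wrist_extensor"],
        hysteresis_ratio=hysteresis_ratio,
    )


def _update_active(rms: float, on: float, off: float, was_active: bool) -> bool:
    return rms >= (off if was_active else on)


def decode_tick(
    flexion_rms: float,
    extension_rms: float,
    thr: ThresholdPair,
    prev: ControlCommand | None = None,
    time_s: float = 0.0,
) -> ControlCommand:
    """Decode one decision tick from the two channel RMS values.

    Activation enters at the on-threshold and leaves at the hysteresis
    off-threshold; previous per-channel activity is inferred from ``prev``.
    LEFT iff only flexion is active, RIGHT iff only extension is active,
    NEUTRAL otherwise (rest or co-activation).
    """
    if flexion_rms < 0 or extension_rms < 0:
        raise InputError("RMS values must be non-negative")
    prev_value = prev.value if prev is not None else Command.NEUTRAL
    flex = _update_active(
        flexion_rms, thr.flexion_on_mv, thr.flexion_off_mv, prev_value == Command.LEFT
    )
    ext = _update_active(
        extension_rms,
        thr.extension_on_mv,
        thr.extension_off_mv,
        prev_value == Command.RIGHT,
    )
    if flex and not ext:
        value = Command.LEFT
    elif ext and not flex:
        value = Command.RIGHT
    else:
        value = Command.NEUTRAL
    return ControlCommand(value, time_s)


def sliding_rms(
    x: np.ndarray, sample_rate_hz: float, window_s: float, step_s: float
) -> np.ndarray:
    """RMS over a sliding window; one value per step, windows fully inside."""
    blocks = ep.segment_array(x, sample_rate_hz, window_s, step_s)
    return np.sqrt(np.mean(np.square(blocks), axis=1))


def run_decoder_stream(
    rec: ep.EmgRecording,
    thr: ThresholdPair,
    cfg: DecoderConfig = DecoderConfig(),
) -> list[ControlCommand]:
    """Decode a whole recording into a command per decision step.

    Each command is stamped with the end time of its decision window. The
    decoder keeps independent per-channel hysteresis state, so co-activation
    episodes are tracked correctly even while the emitted command is NEUTRAL.
    """
    w = int(round(cfg.decision_window_s * rec.sample_rate_hz))
    if rec.n_samples < w:
        raise InputError("recording shorter than one decision window")
    flex_rms = sliding_rms(
        rec.channels["wrist_flexor"], rec.sample_rate_hz, cfg.decision_window_s, cfg.decision_step_s
    )
    ext_rms = sliding_rms(
        rec.channels["wrist_extensor"], rec.sample_rate_hz, cfg.decision_window_s, cfg.decision_step_s
    )
    times = (
        rec.start_time_s
        + cfg.decision_window_s
        + np.arange(flex_rms.size) * cfg.decision_step_s
    )
    commands: list[ControlCommand] = []
    flex_active = ext_active = False
    for f, e, t in zip(flex_rms, ext_rms, times):
        flex_active = _update_active(
            f, thr.flexion_on_mv, thr.flexion_off_mv, flex_active
        )
        ext_active = _update_active(
            e, thr.extension_on_mv, thr.extension_off_mv, ext_active
        )
        if flex_active and not ext_active:
            value = Command.LEFT
        elif ext_active and not flex_active:
            value = Command.RIGHT
        else:
            value = Command.NEUTRAL
        commands.append(ControlCommand(value, float(t)))
    return commands


#: ground-truth intent label -> expected decoder command
LABEL_TO_COMMAND = {
    "rest": Command.NEUTRAL,
    "flexion": Command.LEFT,
    "extension": Command.RIGHT,
}


def label_agreement(
    commands: list[ControlCommand],
    labels: np.ndarray,
    sample_rate_hz: float,
    transition_times_s=(),
    margin_s: float = 0.2,
    start_time_s: float = 0.0,
) -> float:
    """Fraction of decision ticks whose command matches the intent label.

    ``labels`` is the per-sample ground-truth intent; ticks within
    ``margin_s`` of any labelled transition are excluded from scoring.
    """
    transition_times_s = np.asarray(list(transition_times_s), dtype=float)
    hits = total = 0
    n = len(labels)
    for cmd in commands:
        t = cmd.time_s
        if transition_times_s.size and np.min(np.abs(transition_times_s - t)) <= margin_s:
            continue
        idx = min(n - 1, max(0, int(round((t - start_time_s) * sample_rate_hz)) - 1))
        expected = LABEL_TO_COMMAND[str(labels[idx])]
        hits += cmd.value == expected
        total += 1
    if total == 0:
        raise InputError("no scorable ticks outside transition margins")
    return hits / total
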