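"""Headless, seed-deterministic endless-runner training game.

The player character occupies one of ``n_lanes`` lanes; LEFT/RIGHT commands
(decoded from sEMG) shift it one lane per decision tick. Coins and obstacles
spawn as independent Poisson processes from a seeded generator and arrive at
fixed times; a coin collected in the current lane increments the coin count
and the score, an obstacle in the current lane increments the death counter
(the trial continues — deaths are tallied, not terminal). A training trial
lasts 10 min and the weekly schedule is 4 trials per day with 5 min rests.

Everything is a pure function of (seed, config, command log), so a trial can
be replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from . import control as ctl
from ._errors import InputError, StateError


@dataclass(frozen=True)
class GameConfig:
    n_lanes: int = 3
    tick_s: float = 0.05
    trial_duration_s: float = 600.0
    coin_rate_per_s: float = 0.5
    obstacle_rate_per_s: float = 0.2
    coin_score: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_lanes < 1:
            raise InputError("need at least one lane")
        if self.tick_s <= 0 or self.trial_duration_s <= 0:
            raise InputError("tick_s and trial_duration_s must be positive")
        if self.coin_rate_per_s < 0 or self.obstacle_rate_per_s < 0:
            raise InputError("spawn rates must be non-negative")

    @property
    def n_ticks(self) -> int:
        return int(round(self.trial_duration_s / self.tick_s))


@dataclass(frozen=True)
class GameObject:
    kind: str  # "coin" | "obstacle"
    lane: int
    arrival_s: float
    tick_idx: int


@dataclass(frozen=True)
class GameState:
    lane: int
    tick: int
    coins: int = 0
    score: int = 0
    deaths: int = 0
    coins_missed: int = 0
    pending_objects: tuple = ()
    cursor: int = 0  # index of the first unresolved object in pending_objects

    def elapsed(self, cfg: GameConfig) -> float:
        return self.tick * cfg.tick_s


@dataclass(frozen=True)
class TrialResult:
    coins: int
    score: int
    deaths: int
    day_index: int = 0
    trial_index: int = 0
    coins_spawned: int = 0
    coins_missed: int = 0
    obstacles_spawned: int = 0


def _spawn_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    # Poisson process: exponential inter-arrival gaps, truncated at the horizon.
    n_guess = max(16, int(rate * duration * 2 + 10))
    gaps = rng.exponential(1.0 / rate, size=n_guess)
    t = np.cumsum(gaps)
    while t[-1] < duration:
        gaps = rng.exponential(1.0 / rate, size=n_guess)
        t = np.append(t, t[-1] + np.cumsum(gaps))
    return t[t < duration]


def spawn_layout(cfg: GameConfig) -> tuple:
    """Generate the seeded object layout for a trial (sorted by arrival)."""
    rng = np.random.default_rng(cfg.rng_seed)
    objects = []
    for kind, rate in (("coin", cfg.coin_rate_per_s), ("obstacle", cfg.obstacle_rate_per_s)):
        times = _spawn_times(rng, rate, cfg.trial_duration_s)
        lanes = rng.integers(0, cfg.n_lanes, size=times.size)
        for t, lane in zip(times, lanes):
            # arrival in (i*tick, (i+1)*tick] resolves during tick i
            idx = min(cfg.n_ticks - 1, max(0, math.ceil(t / cfg.tick_s) - 1))
            objects.append(GameObject(kind, int(lane), float(t), idx))
    objects.sort(key=lambda o: (o.tick_idx, o.arrival_s, o.kind, o.lane))
    return tuple(objects)


def new_trial_state(cfg: GameConfig, start_lane: int | None = None) -> GameState:
    lane = cfg.n_lanes // 2 if start_lane is None else start_lane
    if not (0 <= lane < cfg.n_lanes):
        raise InputError("start lane out of range")
    return GameState(lane=lane, tick=0, pending_objects=spawn_layout(cfg))


def step_game(state: GameState, cmd, cfg: GameConfig) -> GameState:
    """Advance the simulation by one tick; pure function of its inputs.

    The lane move is applied first, then every object arriving within the
    tick is resolved at the post-move lane.
    """
    if state.tick >= cfg.n_ticks:
        raise StateError("trial already finished")
    value = cmd.value if isinstance(cmd, ctl.ControlCommand) else ctl.Command(cmd)
    lane = state.lane
    if value == ctl.Command.LEFT:
        lane = max(0, lane - 1)
    elif value == ctl.Command.RIGHT:
        lane = min(cfg.n_lanes - 1, lane + 1)
    coins, score, deaths, missed = state.coins, state.score, state.deaths, state.coins_missed
    cursor = state.cursor
    pending = state.pending_objects
    while cursor < len(pending) and pending[cursor].tick_idx == state.tick:
        obj = pending[cursor]
        if obj.kind == "coin":
            if obj.lane == lane:
                coins += 1
                score += cfg.coin_score
            else:
                missed += 1
        elif obj.lane == lane:
            deaths += 1
        cursor += 1
    return dataclasses.replace(
        state,
        lane=lane,
        tick=state.tick + 1,
        coins=coins,
        score=score,
        deaths=deaths,
        coins_missed=missed,
        cursor=cursor,
    )


def _command_provider(source, cfg: GameConfig, thr=None):
    """Normalise a command source into a callable (state) -> command value."""
    from . import emg_pipeline as ep  # local import to avoid cycle at module load

    if isinstance(source, ep.EmgRecording):
        if thr is None:
            raise InputError("decoding an EmgRecording requires thresholds")
        decoded = ctl.run_decoder_stream(source, thr)
        values = {}
        for c in decoded:
            idx = int(round((c.time_s - source.start_time_s) / cfg.tick_s))
            values[idx] = c.value
        if not values or max(values) < cfg.n_ticks - 1:
            raise InputError("recording does not cover the trial duration")
        last = [ctl.Command.NEUTRAL]

        def provider(state):
            last[0] = values.get(state.tick, last[0])
            return last[0]

        return provider
    if callable(source):
        return source
    seq = list(source)
    if len(seq) < cfg.n_ticks:
        raise InputError(
            f"command source has {len(seq)} ticks, trial needs {cfg.n_ticks}"
        )

    return lambda state: seq[state.tick]


def run_trial(
    source,
    cfg: GameConfig,
    thr=None,
    day_index: int = 0,
    trial_index: int = 0,
) -> TrialResult:
    """Simulate one full training trial and return its totals.

    ``source`` may be a sequence of commands (one per tick), a policy callable
    ``state -> command``, or an EmgRecording (decoded with ``thr``).
    """
    provider = _command_provider(source, cfg, thr)
    state = new_trial_state(cfg)
    for _ in range(cfg.n_ticks):
        state = step_game(state, provider(state), cfg)
    n_coins = sum(1 for o in state.pending_objects if o.kind == "coin")
    n_obs = len(state.pending_objects) - n_coins
    return TrialResult(
        coins=state.coins,
        score=state.score,
        deaths=state.deaths,
        day_index=day_index,
        trial_index=trial_index,
        coins_spawned=n_coins,
        coins_missed=state.coins_missed,
        obstacles_spawned=n_obs,
    )


def plan_optimal_commands(cfg: GameConfig) -> list:
    """Omniscient player: command sequence maximising coins, then avoiding deaths.

    Dynamic programming backward over (tick, lane) on the seeded layout; ties
    are broken toward staying, then moving left.
    """
    layout = spawn_layout(cfg)
    n_ticks, n_lanes = cfg.n_ticks, cfg.n_lanes
    coin_gain = np.zeros((n_ticks, n_lanes))
    death_cost = np.zeros((n_ticks, n_lanes))
    for obj in layout:
        if obj.kind == "coin":
            coin_gain[obj.tick_idx, obj.lane] += 1.0
        else:
            death_cost[obj.tick_idx, obj.lane] += 1.0
    gain = coin_gain - 1e-6 * death_cost
    value = np.zeros((n_ticks + 1, n_lanes))
    for t in range(n_ticks - 1, -1, -1):
        for lane in range(n_lanes):
            best = -np.inf
            for nxt in (lane, max(0, lane - 1), min(n_lanes - 1, lane + 1)):
                cand = gain[t, nxt] + value[t + 1, nxt]
                if cand > best + 1e-12:
                    best = cand
            value[t, lane] = best
    commands = []
    lane = n_lanes // 2
    for t in range(n_ticks):
        options = [
            (ctl.Command.NEUTRAL, lane),
            (ctl.Command.LEFT, max(0, lane - 1)),
            (ctl.Command.RIGHT, min(n_lanes - 1, lane + 1)),
        ]
        best_cmd, best_lane, best_val = None, lane, -np.inf
        for cmd, nxt in options:
            cand = gain[t, nxt] + value[t + 1, nxt]
            if cand > best_val + 1e-12:
                best_cmd, best_lane, best_val = cmd, nxt, cand
        commands.append(best_cmd)
        lane = best_lane
    return commands


@dataclass(frozen=True)
class ReachAttempt:
    target: ctl.Command
    success: bool
    latency_s: float | None


@dataclass(frozen=True)
class LearningLog:
    attempts: tuple

    @property
    def n_success(self) -> int:
        return sum(a.success for a in self.attempts)


def run_learning_phase(
    source, cfg: GameConfig, timeout_s: float = 10.0
) -> LearningLog:
    """Pre-game practice: reach LEFT x10, RIGHT x10, then RIGHT x10 more.

    ``source`` is a callable (target_command, t_s) -> command; an attempt
    succeeds at the first tick whose command matches the target, and times
    out after ``timeout_s``.
    """
    targets = (
        [ctl.Command.LEFT] * 10 + [ctl.Command.RIGHT] * 10 + [ctl.Command.RIGHT] * 10
    )
    attempts = []
    n_ticks = int(round(timeout_s / cfg.tick_s))
    for target in targets:
        latency = None
        for i in range(1, n_ticks + 1):
            t = i * cfg.tick_s
            cmd = source(target, t)
            value = cmd.value if isinstance(cmd, ctl.ControlCommand) else ctl.Command(cmd)
            if value == target:
                latency = t
                break
        attempts.append(ReachAttempt(target, latency is not None, latency))
    return LearningLog(tuple(attempts))


@dataclass(frozen=True)
class TrialSlot:
    day: int
    trial: int
    start_s: float  # within-day time of trial start
    duration_s: float


@dataclass(frozen=True)
class SessionPlan:
    trials: tuple
    rest_s: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_on_day(self, day: int) -> list:
        return [t for t in self.trials if t.day == day]

    @property
    def active_s_per_day(self) -> float:
        day0 = self.trials_on_day(self.trials[0].day)
        return sum(t.duration_s for t in day0)


def schedule_sessions(
    n_days: int, cfg: GameConfig, trials_per_day: int = 4, rest_s: float = 300.0
) -> SessionPlan:
    """Weekly schedule: 4 trials of 10 min per day with 5 min rests between."""
    if n_days < 1:
        raise InputError("n_days must be >= 1")
    slots = []
    for day in range(n_days):
        for i in range(trials_per_day):
            start = i * (cfg.trial_duration_s + rest_s)
            slots.append(TrialSlot(day, i, start, cfg.trial_duration_s))
    return SessionPlan(tuple(slots), rest_s)
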