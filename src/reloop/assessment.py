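"""Assessment-battery scoring: clinical fit, task times, BBT, questionnaires.

The battery mirrors a standard upper-limb prosthesis evaluation:

* clinical fit checks (length difference ≤ 1 cm, weight ≤ 0.5 kg, socket
  traction displacement ≤ 2 cm without skin discoloration; bounds inclusive),
* completion times (CT, seconds) for placing/submitting trials and ten
  activities of daily living, grouped by task or by difficulty,
* Box and Block Test counts (blocks moved per 60 s),
* yardstick comparison against nationally standardised reference times
  (supplied through configuration, never hard-coded),
* four questionnaire instruments: an 11-item task/prosthesis questionnaire
  (5-point Likert), NASA-TLX (six subscales, scored as unweighted raw
  subscale values — the RTLX convention — on a 0–20 item scale), the
  Intrinsic Motivation Inventory (7-point, five subscales: interest/fun,
  cognitive ability, tension/stress, cognitive choice, value/utility), and
  a 6-item user questionnaire (5-point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, InputError

ADL_TASKS = tuple(f"adl_{i}" for i in range(1, 11))
CT_TASKS = ("placing", "submitting") + ADL_TASKS
ALL_TASKS = CT_TASKS + ("bbt",)

#: default difficulty split of the ten ADL tasks (configurable per deployment)
DEFAULT_ADL_DIFFICULTY = {
    **{f"adl_{i}": "simple" for i in range(1, 7)},
    **{f"adl_{i}": "complex" for i in range(7, 11)},
}


@dataclass(frozen=True)
class TaskTrial:
    subject_id: str
    task: str
    trial_index: int
    ct_s: float | None = None
    blocks_moved: int | None = None
    difficulty: str = "n/a"

    def __post_init__(self):
        if self.task not in ALL_TASKS:
            raise InputError(f"unknown task {self.task!r}")
        if self.task == "bbt":
            if self.blocks_moved is None or self.blocks_moved < 0:
                raise InputError("bbt trials need blocks_moved >= 0")
        else:
            if self.ct_s is None or self.ct_s <= 0:
                raise InputError("timed trials need ct_s > 0")


def trials_to_frame(trials) -> pd.DataFrame:
    """Convert TaskTrial records (or pass through a DataFrame) to the trial table."""
    if isinstance(trials, pd.DataFrame):
        return trials.copy()
    return pd.DataFrame(
        {
            "subject": [t.subject_id for t in trials],
            "task": [t.task for t in trials],
            "difficulty": [t.difficulty for t in trials],
            "trial": [t.trial_index for t in trials],
            "ct_s": [t.ct_s for t in trials],
            "blocks": [t.blocks_moved for t in trials],
        }
    )


@dataclass(frozen=True)
class ClinicalFit:
    length_diff_cm: float
    weight_kg: float
    traction_displacement_cm: float
    skin_discoloration: bool = False

    def __post_init__(self):
        if min(self.length_diff_cm, self.weight_kg, self.traction_displacement_cm) < 0:
            raise InputError("clinical fit measurements must be non-negative")


#: inclusive pass bounds for the clinical fit criteria
FIT_LIMITS = {"length_diff_cm": 1.0, "weight_kg": 0.5, "traction_displacement_cm": 2.0}


def clinical_fit_check(fit: ClinicalFit) -> dict:
    """Pass/fail per clinical criterion (inclusive bounds).

    ``stability`` passes when traction displacement is within 2 cm *and* no
    skin discoloration occurred.
    """
    return {
        "length": fit.length_diff_cm <= FIT_LIMITS["length_diff_cm"],
        "weight": fit.weight_kg <= FIT_LIMITS["weight_kg"],
        "stability": (
            fit.traction_displacement_cm <= FIT_LIMITS["traction_displacement_cm"]
            and not fit.skin_discoloration
        ),
    }


def assign_difficulty(frame: pd.DataFrame, adl_difficulty: dict | None = None) -> pd.DataFrame:
    """Fill the difficulty column for ADL rows from the configured split."""
    mapping = dict(DEFAULT_ADL_DIFFICULTY if adl_difficulty is None else adl_difficulty)
    out = frame.copy()
    out["difficulty"] = out["task"].map(mapping).fillna(out.get("difficulty", "n/a"))
    return out


def completion_time_summary(
    trials, group_by: str = "task", expected_groups=None
) -> pd.DataFrame:
    """Grouped descriptive statistics of completion times.

    Returns one row per group with n, mean, sd (sample sd; 0 for n=1, with an
    ``n1`` flag) and the per-trial values. Groups listed in
    ``expected_groups`` but absent from the data are omitted with a warning.
    """
    frame = trials_to_frame(trials)
    frame = frame[frame["task"] != "bbt"].dropna(subset=["ct_s"])
    if group_by not in frame.columns:
        raise ConfigurationError(f"cannot group by {group_by!r}")
    if frame.empty:
        raise InputError("no timed trials to summarise")
    rows = []
    for key, grp in frame.groupby(group_by, sort=True):
        vals = grp["ct_s"].to_numpy(dtype=float)
        rows.append(
            {
                group_by: key,
                "n": vals.size,
                "mean_ct_s": float(np.mean(vals)),
                "sd_ct_s": 0.0 if vals.size == 1 else float(np.std(vals, ddof=1)),
                "n1": vals.size == 1,
                "values": list(vals),
            }
        )
    summary = pd.DataFrame(rows).set_index(group_by)
    if expected_groups is not None:
        for g in expected_groups:
            if g not in summary.index:
                warnings.warn(f"group {g!r} has no trials; omitted", stacklevel=2)
    return summary


def yardstick_compare(summary: pd.DataFrame, yardstick_s: dict) -> pd.DataFrame:
    """Flag whether each task's mean CT meets its yardstick time (inclusive).

    ``yardstick_s`` maps task -> reference seconds from the applicable
    standard; a task without an entry is a configuration error.
    """
    out = summary.copy()
    flags = []
    for task, row in out.iterrows():
        if task not in yardstick_s:
            raise ConfigurationError(f"no yardstick configured for task {task!r}")
        flags.append(row["mean_ct_s"] <= yardstick_s[task])
    out["meets_yardstick"] = flags
    return out


@dataclass(frozen=True)
class BbtSummary:
    per_trial_blocks: tuple
    mean_blocks: float


def bbt_summary(trials) -> BbtSummary:
    """Blocks moved per 60 s trial plus the across-trial mean."""
    frame = trials_to_frame(trials)
    if frame.empty:
        raise InputError("no BBT trials")
    if (frame["task"] != "bbt").any():
        raise InputError("bbt_summary accepts BBT trials only")
    blocks = frame.sort_values("trial")["blocks"].to_numpy(dtype=float)
    return BbtSummary(tuple(int(b) for b in blocks), float(np.mean(blocks)))


def bbt_delta(pre: BbtSummary, post: BbtSummary) -> float:
    """Change in mean blocks per 60 s between sessions (post - pre)."""
    return post.mean_blocks - pre.mean_blocks


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    n_items: int
    scale: tuple  # (min, max) inclusive item bounds
    subscale_map: dict | None = None  # item index (0-based) -> subscale name
    reverse_items: tuple = ()


def _one_per_item(names) -> dict:
    return {i: name for i, name in enumerate(names)}


NASA_TLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)

IMI_SUBSCALES = (
    "interest_fun",
    "cognitive_ability",
    "tension_stress",
    "cognitive_choice",
    "value_utility",
)

INSTRUMENTS = {
    "task_prosthesis_q": InstrumentSpec("task_prosthesis_q", 11, (1, 5)),
    "nasa_tlx": InstrumentSpec(
        "nasa_tlx", 6, (0, 20), _one_per_item(NASA_TLX_SUBSCALES)
    ),
    # four items per subscale, grouped in subscale order
    "imi": InstrumentSpec(
        "imi",
        20,
        (1, 7),
        {i: IMI_SUBSCALES[i // 4] for i in range(20)},
    ),
    "user_q": InstrumentSpec("user_q", 6, (1, 5)),
}

#: labels for 5-point agreement items
LIKERT5_LABELS = {
    1: "strongly disagree",
    2: "disagree",
    3: "neutral",
    4: "agree",
    5: "strongly agree",
}


@dataclass
class QuestionnaireResponse:
    instrument: str
    item_scores: tuple
    subscale_map: dict | None = None  # overrides the instrument default
    reverse_items: tuple = ()

    def spec(self) -> InstrumentSpec:
        if self.instrument not in INSTRUMENTS:
            raise InputError(f"unknown instrument {self.instrument!r}")
        return INSTRUMENTS[self.instrument]


@dataclass(frozen=True)
class QuestionnaireScores:
    instrument: str
    subscale_means: dict
    total: float
    item_labels: tuple = ()


def score_questionnaire(resp: QuestionnaireResponse) -> QuestionnaireScores:
    """Per-subscale means (after reverse-scoring) and the overall item mean.

    Incomplete responses and out-of-range items are input errors. Instruments
    without subscales report a single ``overall`` subscale.
    """
    spec = resp.spec()
    scores = np.asarray(resp.item_scores, dtype=float)
    if scores.size != spec.n_items:
        raise InputError(
            f"{spec.name} expects {spec.n_items} items, got {scores.size}"
        )
    lo, hi = spec.scale
    if np.any(scores < lo) or np.any(scores > hi):
        raise InputError(f"{spec.name} items must lie in [{lo}, {hi}]")
    reverse = set(resp.reverse_items or spec.reverse_items)
    adj = scores.copy()
    for i in reverse:
        adj[i] = lo + hi - adj[i]
    mapping = resp.subscale_map or spec.subscale_map
    if mapping:
        subscales: dict = {}
        for i, value in enumerate(adj):
            subscales.setdefault(mapping[i], []).append(value)
        means = {k: float(np.mean(v)) for k, v in subscales.items()}
    else:
        means = {"overall": float(np.mean(adj))}
    labels = ()
    if (lo, hi) == (1, 5):
        labels = tuple(LIKERT5_LABELS[int(round(s))] for s in scores)
    return QuestionnaireScores(spec.name, means, float(np.mean(adj)), labels)
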