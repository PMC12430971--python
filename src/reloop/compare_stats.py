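"""Pre/post outcome comparison: percent changes, Wilcoxon tests, reports.

The assessment–training–reassessment loop is closed by comparing the pre- and
post-training batteries: completion-time reductions per subject and task,
Box-and-Block deltas, sEMG RMS changes per muscle, Wilcoxon signed-rank tests
at alpha = 0.05, and an assembled machine-readable report.

The signed-rank test uses the exact null distribution (enumeration of the
2^n sign patterns, realised as a subset-sum convolution over the ranks of
|d|, average ranks for ties) up to n = 25, and the tie-corrected normal
approximation with continuity correction above. Zero differences are dropped
by default (Wilcoxon's convention); Pratt's method (rank zeros, then drop) is
available. Reductions are reported as positive percentages of the pre value;
signed values are kept in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import assessment as am
from . import emg_pipeline as ep
from ._errors import AlignmentError, DegenerateSampleError, InputError

ALPHA_DEFAULT = 0.05
EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedSample:
    labels: tuple
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pre", np.asarray(self.pre, dtype=float))
        object.__setattr__(self, "post", np.asarray(self.post, dtype=float))
        if self.pre.size != self.post.size or self.pre.size < 1:
            raise InputError("pre and post must be aligned and non-empty")
        if len(self.labels) != self.pre.size:
            raise InputError("labels must align with the sample")


def percent_change(pre: float, post: float) -> float:
    """Reduction as a positive percent of the pre value: (pre-post)/pre*100."""
    if not math.isfinite(pre) or pre <= 0:
        raise InputError("pre value must be positive")
    return (pre - post) / pre * 100.0


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # differences entering the test after zero handling
    method: str  # "exact" | "approx"


def _exact_tail_counts(doubled_ranks: list[int]) -> list[int]:
    """Number of sign patterns attaining each doubled W+ value (exact ints)."""
    total = sum(doubled_ranks)
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in doubled_ranks:
        for s in range(total, r - 1, -1):
            counts[s] += counts[s - r]
    return counts


def wilcoxon_signed_rank(
    sample,
    post=None,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired data.

    Accepts a PairedSample or two aligned arrays. Differences are
    ``post - pre``; ``alternative='greater'`` tests for post > pre. The
    statistic is W+, the rank sum of positive differences.

    ``mode='exact'`` (default for n <= 25) enumerates the null distribution;
    ties get average ranks and the enumeration handles the resulting
    half-integer ranks exactly. ``mode='approx'`` uses the normal
    approximation with tie correction and 0.5 continuity correction.
    """
    if isinstance(sample, PairedSample):
        pre, post_arr = sample.pre, sample.post
    else:
        if post is None:
            raise InputError("need a PairedSample or two arrays")
        pre = np.asarray(sample, dtype=float)
        post_arr = np.asarray(post, dtype=float)
        if pre.size != post_arr.size:
            raise InputError("pre and post lengths differ")
    d = post_arr - pre
    if zero_method not in ("wilcox", "pratt"):
        raise InputError("zero_method must be 'wilcox' or 'pratt'")
    if np.all(d == 0):
        raise DegenerateSampleError("all paired differences are zero")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    else:  # pratt: rank |d| including zeros, then drop the zeros' ranks
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n = d.size
    w_plus = float(np.sum(ranks[d > 0]))
    if alternative not in ("two-sided", "greater", "less"):
        raise InputError("alternative must be two-sided, greater or less")
    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "approx"
    if mode == "exact":
        doubled = [int(round(2 * r)) for r in ranks]
        counts = _exact_tail_counts(doubled)
        total_patterns = 2 ** n
        w2 = int(round(2 * w_plus))
        p_ge = sum(counts[w2:]) / total_patterns
        p_le = sum(counts[: w2 + 1]) / total_patterns
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w_plus, p, n, "exact")
    # normal approximation with tie correction and continuity correction
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise DegenerateSampleError("zero variance after tie correction")
    sd = math.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf((w_plus - mu - 0.5) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((w_plus - mu + 0.5) / sd)
    else:
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sd
        p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(min(1.0, p)), n, "approx")


def association_slope(x, y) -> tuple[float, float]:
    """Least-squares line through (x, y); returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InputError("need at least two aligned points")
    if np.unique(x).size < 2:
        raise InputError("x must contain at least two distinct values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@dataclass
class AssessmentReport:
    """Assembled pre/post comparison; ``data`` is the JSON-ready payload."""

    data: dict
    schema_version: str = "1"

    def to_dict(self) -> dict:
        return {"schema_version": self.schema_version, **self.data}

    def to_markdown(self) -> str:
        lines = ["# Pre/post assessment report", ""]
        tasks = self.data.get("tasks", {})
        if tasks:
            lines += [
                "| task | pre mean | post mean | reduction % | p | significant |",
                "|---|---|---|---|---|---|",
            ]
            for task, entry in tasks.items():
                p = entry.get("pvalue")
                lines.append(
                    f"| {task} | {entry['pre_mean']:.2f} | {entry['post_mean']:.2f} "
                    f"| {entry['reduction_percent']:.2f} "
                    f"| {'-' if p is None else format(p, '.4f')} "
                    f"| {entry['significant']} |"
                )
            lines.append("")
        bbt = self.data.get("bbt")
        if bbt:
            lines.append(
                f"BBT: {bbt['pre_mean']:.2f} -> {bbt['post_mean']:.2f} blocks/60 s "
                f"(delta {bbt['delta_blocks']:+.2f})"
            )
            lines.append("")
        rms = self.data.get("rms", {})
        for muscle, entry in rms.items():
            lines.append(
                f"RMS {muscle}: {entry['pre_mean_mv']:.4f} -> "
                f"{entry['post_mean_mv']:.4f} mV ({entry['change_percent']:+.2f}%)"
            )
        return "\n".join(lines)


def _subject_task_means(frame: pd.DataFrame) -> pd.DataFrame:
    timed = frame[frame["task"] != "bbt"].dropna(subset=["ct_s"])
    return timed.groupby(["subject", "task"], sort=True)["ct_s"].mean()


def _check_alignment(pre: pd.DataFrame, post: pd.DataFrame) -> None:
    pre_keys = set(map(tuple, pre[["subject", "task"]].drop_duplicates().to_numpy()))
    post_keys = set(map(tuple, post[["subject", "task"]].drop_duplicates().to_numpy()))
    offenders = [("post", s, t) for (s, t) in sorted(pre_keys - post_keys)]
    offenders += [("pre", s, t) for (s, t) in sorted(post_keys - pre_keys)]
    if offenders:
        names = ", ".join(f"{side} missing {s}/{t}" for side, s, t in offenders)
        raise AlignmentError(f"pre/post batteries misaligned: {names}", offenders)


def _task_section(pre: pd.DataFrame, post: pd.DataFrame, alpha: float,
                  yardsticks: dict | None, zero_method: str) -> dict:
    pre_means = _subject_task_means(pre)
    post_means = _subject_task_means(post)
    tasks = sorted(pre_means.index.get_level_values("task").unique())
    section = {}
    for task in tasks:
        p_pre = pre_means.xs(task, level="task").sort_index()
        p_post = post_means.xs(task, level="task").sort_index()
        subjects = sorted(set(p_pre.index) & set(p_post.index))
        a = p_pre.loc[subjects].to_numpy()
        b = p_post.loc[subjects].to_numpy()
        entry = {
            "pre_mean": float(np.mean(a)),
            "post_mean": float(np.mean(b)),
            "reduction_percent": percent_change(float(np.mean(a)), float(np.mean(b))),
            "signed_change_percent": -percent_change(float(np.mean(a)), float(np.mean(b))),
            "per_subject": {
                s: {
                    "pre_mean": float(pa),
                    "post_mean": float(pb),
                    "reduction_percent": percent_change(float(pa), float(pb)),
                }
                for s, pa, pb in zip(subjects, a, b)
            },
        }
        try:
            res = wilcoxon_signed_rank(a, b, zero_method=zero_method)
            entry.update(
                statistic=res.statistic,
                pvalue=res.pvalue,
                significant=bool(res.pvalue < alpha),
                test_n=res.n_used,
            )
        except DegenerateSampleError:
            entry.update(statistic=None, pvalue=None, significant=False, test_n=0)
        if yardsticks is not None and task in yardsticks:
            entry["meets_yardstick"] = entry["post_mean"] <= yardsticks[task]
        section[task] = entry
    return section


def _bbt_section(pre: pd.DataFrame, post: pd.DataFrame, alpha: float,
                 zero_method: str) -> dict | None:
    pre_bbt = pre[pre["task"] == "bbt"]
    post_bbt = post[post["task"] == "bbt"]
    if pre_bbt.empty or post_bbt.empty:
        return None
    a = pre_bbt.groupby("subject")["blocks"].mean().sort_index()
    b = post_bbt.groupby("subject")["blocks"].mean().sort_index()
    subjects = sorted(set(a.index) & set(b.index))
    av = a.loc[subjects].to_numpy()
    bv = b.loc[subjects].to_numpy()
    entry = {
        "pre_mean": float(np.mean(av)),
        "post_mean": float(np.mean(bv)),
        "delta_blocks": float(np.mean(bv) - np.mean(av)),
        "per_subject": {
            s: {"pre_mean": float(x), "post_mean": float(y), "delta_blocks": float(y - x)}
            for s, x, y in zip(subjects, av, bv)
        },
    }
    try:
        res = wilcoxon_signed_rank(av, bv, zero_method=zero_method)
        entry.update(
            statistic=res.statistic,
            pvalue=res.pvalue,
            significant=bool(res.pvalue < alpha),
        )
    except DegenerateSampleError:
        entry.update(statistic=None, pvalue=None, significant=False)
    return entry


def _rms_section(rms_pre: dict, rms_post: dict, alpha: float, zero_method: str) -> dict:
    # accepts {subject: {muscle: mv}} or a flat {muscle: mv}
    def normalise(d):
        if d and all(isinstance(v, dict) for v in d.values()):
            return d
        return {"_all": dict(d)}

    pre_n = normalise(rms_pre)
    post_n = normalise(rms_post)
    subjects = sorted(set(pre_n) & set(post_n))
    muscles = sorted({m for s in subjects for m in pre_n[s]})
    section = {}
    for muscle in muscles:
        a = np.array([pre_n[s][muscle] for s in subjects])
        b = np.array([post_n[s][muscle] for s in subjects])
        entry = {
            "pre_mean_mv": float(np.mean(a)),
            "post_mean_mv": float(np.mean(b)),
            "change_percent": ep.rms_change_percent(float(np.mean(a)), float(np.mean(b))),
            "per_subject": {
                s: ep.rms_change_percent(float(x), float(y))
                for s, x, y in zip(subjects, a, b)
            },
        }
        if len(subjects) > 1:
            try:
                res = wilcoxon_signed_rank(a, b, zero_method=zero_method)
                entry.update(pvalue=res.pvalue, significant=bool(res.pvalue < alpha))
            except DegenerateSampleError:
                entry.update(pvalue=None, significant=False)
        section[muscle] = entry
    return section


def build_report(
    pre_battery,
    post_battery,
    rms_pre: dict | None = None,
    rms_post: dict | None = None,
    trial_logs: pd.DataFrame | None = None,
    alpha: float = ALPHA_DEFAULT,
    yardsticks: dict | None = None,
    zero_method: str = "wilcox",
) -> AssessmentReport:
    """Assemble the full pre/post comparison report.

    ``pre_battery``/``post_battery`` are trial tables (DataFrame or TaskTrial
    records); ``rms_pre``/``rms_post`` map subject -> muscle -> mean RMS in
    mV; ``trial_logs`` is the optional game-trial log (day, trial, coins,
    score, deaths). Subject/task misalignment raises AlignmentError naming
    the offenders. Output is deterministic and independent of row order.
    """
    pre = am.trials_to_frame(pre_battery)
    post = am.trials_to_frame(post_battery)
    _check_alignment(pre, post)
    data: dict = {
        "alpha": alpha,
        "tasks": _task_section(pre, post, alpha, yardsticks, zero_method),
    }
    bbt = _bbt_section(pre, post, alpha, zero_method)
    if bbt is not None:
        data["bbt"] = bbt
    if rms_pre is not None and rms_post is not None:
        data["rms"] = _rms_section(rms_pre, rms_post, alpha, zero_method)
    if trial_logs is not None and len(trial_logs):
        logs = trial_logs.sort_values(["day", "trial"])
        by_day = logs.groupby("day")[["coins", "score", "deaths"]].sum()
        data["training"] = {
            "per_day": {
                int(day): {k: int(v) for k, v in row.items()}
                for day, row in by_day.iterrows()
            },
            "score_trend_slope": (
                association_slope(by_day.index.to_numpy(), by_day["score"].to_numpy())[0]
                if len(by_day) > 1
                else None
            ),
        }
    return AssessmentReport(data)
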