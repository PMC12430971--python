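"""Tests for percent changes, the Wilcoxon signed-rank test, and reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reloop import AlignmentError, DegenerateSampleError, InputError
from reloop import compare_stats as cs


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(100.0, 50.0, 50.0), (10.0, 10.0, 0.0), (10.0, 13.0, -30.0)],
    )
    def test_reduction_arithmetic(self, pre, post, expected):
        assert cs.percent_change(pre, post) == pytest.approx(expected)

    def test_printed_group_means(self):
        """ADL group means 15.17 s -> 9.97 s correspond to a 34.28% reduction."""
        assert cs.percent_change(15.17, 9.97) == pytest.approx(34.28, abs=0.01)

    @pytest.mark.parametrize("pre", [0.0, -3.0])
    def test_nonpositive_pre_rejected(self, pre):
        with pytest.raises(InputError):
            cs.percent_change(pre, 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        pre=st.floats(0.01, 1e4),
        post=st.floats(0.0, 1e4),
    )
    def test_reduction_identity(self, pre, post):
        """post == pre * (1 - reduction/100) to machine precision."""
        red = cs.percent_change(pre, post)
        assert post == pytest.approx(pre * (1 - red / 100.0), abs=1e-12 * max(1, pre))


def brute_wilcoxon(pre, post, alternative="two-sided", zero_method="wilcox"):
    """Independent oracle: enumerate all 2^n sign patterns of the ranks."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    else:
        ranks_all = stats.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    n = d.size
    w = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        ws = sum(r for r, s in zip(ranks, signs) if s)
        ge += ws >= w - 1e-9
        le += ws <= w + 1e-9
    p_ge, p_le = ge / 2**n, le / 2**n
    if alternative == "greater":
        return w, p_ge
    if alternative == "less":
        return w, p_le
    return w, min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_positive_n5_one_sided(self):
        """Five positive differences: W+ = 15, exact one-sided p = 1/32."""
        res = cs.wilcoxon_signed_rank(
            [0, 0, 0, 0, 0], [1, 2, 3, 4, 5], alternative="greater"
        )
        assert res.statistic == 15.0
        assert res.pvalue == pytest.approx(1 / 32)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            cs.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    @pytest.mark.parametrize("case", range(25))
    def test_exact_p_matches_enumeration(self, alternative, case):
        """Exact p equals the 2^n enumeration for random samples with ties."""
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(3, 11))
        pre = rng.integers(0, 6, n).astype(float)
        post = rng.integers(0, 6, n).astype(float)
        if np.all(pre == post):
            post[0] += 1
        res = cs.wilcoxon_signed_rank(pre, post, alternative=alternative)
        w, p = brute_wilcoxon(pre, post, alternative)
        assert res.statistic == pytest.approx(w)
        assert res.pvalue == pytest.approx(p, rel=1e-12)

    def test_matches_scipy_on_tie_free_samples(self):
        """Cross-check against scipy's exact method where it applies."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            pre = rng.normal(size=12)
            post = rng.normal(size=12)
            mine = cs.wilcoxon_signed_rank(pre, post)
            ref = stats.wilcoxon(post - pre, method="exact", alternative="two-sided")
            assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pratt_zero_handling(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([1.0, 4.0, 1.0, 9.0])
        res = cs.wilcoxon_signed_rank(pre, post, zero_method="pratt")
        w, p = brute_wilcoxon(pre, post, zero_method="pratt")
        assert res.statistic == pytest.approx(w)
        assert res.pvalue == pytest.approx(p, rel=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(9)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.4, 1.0, size=40)
        res = cs.wilcoxon_signed_rank(pre, post)
        ref = stats.wilcoxon(
            post - pre, method="approx", correction=True, alternative="two-sided"
        )
        assert res.method == "approx"
        assert res.pvalue == pytest.approx(ref.pvalue, rel=0.02)


class TestAssociationSlope:
    @pytest.mark.parametrize(
        "x, y, slope, intercept",
        [([1, 2, 3], [1, 2, 3], 1.0, 0.0), ([1, 2, 3], [2, 4, 6], 2.0, 0.0)],
    )
    def test_exact_fits(self, x, y, slope, intercept):
        s, b = cs.association_slope(x, y)
        assert s == pytest.approx(slope, abs=1e-12)
        assert b == pytest.approx(intercept, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 15)
        y = rng.uniform(0, 10, 15)
        s, b = cs.association_slope(x, y)
        # closed-form normal equations
        sx, sy = x.sum(), y.sum()
        n = x.size
        slope = (n * (x * y).sum() - sx * sy) / (n * (x**2).sum() - sx**2)
        intercept = (sy - slope * sx) / n
        assert s == pytest.approx(slope, abs=1e-9)
        assert b == pytest.approx(intercept, abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            cs.association_slope([2, 2, 2], [1, 2, 3])


def _battery(subjects=("A1", "A3", "A4"), scale=1.0, rng=None):
    rows = []
    for i, s in enumerate(subjects):
        for task, base in (("placing", 100.0), ("submitting", 80.0), ("adl_1", 15.0)):
            for trial in range(3):
                noise = 1.0 if rng is None else float(np.exp(rng.normal(0, 0.01)))
                rows.append(
                    {
                        "subject": s,
                        "task": task,
                        "difficulty": "n/a",
                        "trial": trial,
                        "ct_s": base * (1 + 0.1 * i) * scale * noise,
                        "blocks": None,
                    }
                )
        for trial in range(3):
            rows.append(
                {
                    "subject": s,
                    "task": "bbt",
                    "difficulty": "n/a",
                    "trial": trial,
                    "ct_s": None,
                    "blocks": 14 + i,
                }
            )
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_identical_batteries_show_no_change(self):
        pre = _battery()
        report = cs.build_report(pre, pre.copy()).to_dict()
        for entry in report["tasks"].values():
            assert entry["reduction_percent"] == pytest.approx(0.0)
            assert entry["significant"] is False
        assert report["bbt"]["delta_blocks"] == pytest.approx(0.0)

    def test_improver_scenario_recovers_programmed_effect(self):
        """Post CTs scaled down 35% and RMS up 5% appear as ~35% / ~+5%."""
        rng = np.random.default_rng(11)
        pre = _battery(rng=rng)
        post = _battery(scale=0.65, rng=rng)
        rms_pre = {"A1": {"wrist_flexor": 0.30}, "A3": {"wrist_flexor": 0.35}, "A4": {"wrist_flexor": 0.32}}
        rms_post = {s: {"wrist_flexor": v["wrist_flexor"] * 1.05} for s, v in rms_pre.items()}
        report = cs.build_report(pre, post, rms_pre, rms_post).to_dict()
        for entry in report["tasks"].values():
            assert entry["reduction_percent"] == pytest.approx(35.0, abs=1.0)
        assert report["rms"]["wrist_flexor"]["change_percent"] == pytest.approx(5.0, abs=0.01)

    def test_missing_post_task_names_offender(self):
        pre = _battery()
        post = _battery()
        post = post[~((post["subject"] == "A3") & (post["task"] == "placing"))]
        with pytest.raises(AlignmentError, match="A3/placing"):
            cs.build_report(pre, post)

    def test_row_order_independence(self):
        rng = np.random.default_rng(2)
        pre, post = _battery(rng=rng), _battery(scale=0.8, rng=rng)
        a = cs.build_report(pre, post).to_dict()
        b = cs.build_report(
            pre.sample(frac=1.0, random_state=5), post.sample(frac=1.0, random_state=6)
        ).to_dict()
        assert a == b

    def test_trial_log_summary(self):
        logs = pd.DataFrame(
            {
                "day": [0, 0, 1, 1],
                "trial": [0, 1, 0, 1],
                "coins": [5, 7, 9, 11],
                "score": [50, 70, 90, 110],
                "deaths": [3, 2, 1, 1],
            }
        )
        report = cs.build_report(_battery(), _battery(), trial_logs=logs).to_dict()
        assert report["training"]["per_day"][0]["coins"] == 12
        assert report["training"]["score_trend_slope"] == pytest.approx(80.0)

    def test_markdown_rendering_mentions_tasks(self):
        text = cs.build_report(_battery(), _battery()).to_markdown()
        assert "placing" in text and "BBT" in text
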