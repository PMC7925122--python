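import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfblind.scales import (
    COGNITIVE_TASKS,
    ScaleDescriptor,
    change_from_baseline,
    compute_cps,
    get_scale,
    load_registry,
    lsd_equivalent,
    mushroom_to_lsd_equiv,
    scale_range,
    scales_in_class,
)


class TestRegistry:
    def test_rpwb_total_range(self):
        assert scale_range(get_scale("rpwb")) == (0, 252)

    def test_outcome_class_counts(self):
        # 7 acute + 4 post-acute self-report scales enter the strata counts
        assert len(scales_in_class("acute")) == 7
        assert len(scales_in_class("post_acute")) == 4
        assert len(scales_in_class("accumulative")) == 9

    def test_unknown_scale(self):
        with pytest.raises(KeyError):
            get_scale("nope")

    def test_single_item_scale(self):
        desc = ScaleDescriptor("x", "x", 1, 0, 6, "higher_better", "acute")
        assert scale_range(desc) == (0, 6)

    def test_degenerate_item_range_rejected(self):
        with pytest.raises(ValueError):
            ScaleDescriptor("x", "x", 3, 5, 5, "higher_better", "acute")

    @settings(max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 60),
        lo=st.integers(-5, 5),
        width=st.integers(1, 10),
    )
    def test_range_equals_per_item_enumeration(self, n, lo, width):
        desc = ScaleDescriptor("x", "x", n, lo, lo + width, "higher_better", "acute")
        # brute force: sum of per-item extremes
        assert scale_range(desc) == (sum([lo] * n), sum([lo + width] * n))


class TestDoseConversion:
    def test_printed_anchor(self):
        assert mushroom_to_lsd_equiv(0.1) == pytest.approx(4.6)

    def test_zero(self):
        assert mushroom_to_lsd_equiv(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mushroom_to_lsd_equiv(-0.1)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(0, 2), b=st.floats(0, 2))
    def test_linear_and_monotone(self, a, b):
        assert mushroom_to_lsd_equiv(a + b) == pytest.approx(
            mushroom_to_lsd_equiv(a) + mushroom_to_lsd_equiv(b)
        )
        if a < b:
            assert mushroom_to_lsd_equiv(a) < mushroom_to_lsd_equiv(b)

    def test_substance_dispatch(self):
        assert lsd_equivalent("mushroom", 0.2) == pytest.approx(9.2)
        assert lsd_equivalent("lsd", 13.0) == 13.0


def _task_frame(n_subj=40, n_sessions=5, seed=0, learning=None, md_sessions=()):
    rng = np.random.default_rng(seed)
    learning = learning if learning is not None else np.zeros(n_sessions)
    rows = []
    for i in range(n_subj):
        ability = rng.normal(0, 1)
        for s in range(n_sessions):
            for t in COGNITIVE_TASKS:
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "session": s,
                        "task": t,
                        "value": 10 + ability + learning[s] + rng.normal(0, 1),
                        "condition": "MD" if s in md_sessions else "PL",
                    }
                )
    return pd.DataFrame(rows)


class TestCps:
    def test_repeat_of_baseline_scores_preserves_composite(self):
        rows = [
            {"participant_id": f"p{i}", "session": s, "task": t,
             "value": 10.0 + (i % 2) * 2 - 1, "condition": "PL"}
            for i in range(6)
            for s in (0, 1)
            for t in COGNITIVE_TASKS
        ]
        cps = compute_cps(pd.DataFrame(rows))
        # every participant repeats their baseline score exactly, so no
        # learning offset and z = constant per participant; composite at
        # session 1 equals the session-0 composite
        wide = cps.pivot(index="participant_id", columns="session", values="cps")
        assert np.allclose(wide[0], wide[1])

    def test_invariant_to_per_session_constant(self):
        base = _task_frame(seed=1)
        cps0 = compute_cps(base)
        shifted = base.copy()
        shifted.loc[shifted["session"] == 2, "value"] += 7.5
        cps1 = compute_cps(shifted)
        pd.testing.assert_frame_equal(cps0, cps1)

    def test_one_task_one_sd_up_gives_one_sixth(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(200):
            for t in COGNITIVE_TASKS:
                rows.append(
                    {"participant_id": f"p{i}", "session": 0, "task": t,
                     "value": rng.normal(10, 2), "condition": "PL"}
                )
        frame = pd.DataFrame(rows)
        ref = (
            frame.groupby("task")["value"].agg(["mean", "std"]).reset_index()
        ).rename(columns={"std": "sd"})
        probe = pd.DataFrame(
            [
                {"participant_id": "q", "session": 0, "task": t,
                 "value": ref.set_index("task").loc[t, "mean"]
                 + (ref.set_index("task").loc[t, "sd"] if k == 0 else 0.0),
                 "condition": "PL"}
                for k, t in enumerate(COGNITIVE_TASKS)
            ]
        )
        cps = compute_cps(pd.concat([frame, probe]), reference=ref)
        q = cps[cps["participant_id"] == "q"]["cps"].iloc[0]
        assert q == pytest.approx(1 / 6, abs=1e-9)

    def test_zero_baseline_sd_rejected(self):
        rows = [
            {"participant_id": f"p{i}", "session": 0, "task": t, "value": 5.0,
             "condition": "PL"}
            for i in range(4)
            for t in COGNITIVE_TASKS
        ]
        with pytest.raises(ValueError, match="SD"):
            compute_cps(pd.DataFrame(rows))

    def test_too_few_tasks_gives_nan(self):
        base = _task_frame(n_subj=10, n_sessions=1, seed=4)
        probe = base[
            base["task"].isin(COGNITIVE_TASKS[:3])
            & (base["participant_id"] == "p0")
        ].copy()
        probe["participant_id"] = "sparse"
        probe["session"] = 0
        cps = compute_cps(pd.concat([base, probe]))
        sparse = cps[cps["participant_id"] == "sparse"]
        assert sparse["cps"].isna().all()

    def test_md_sessions_excluded_from_learning_estimate(self):
        # a drug effect confined to MD sessions must not contaminate the
        # learning curve estimated from microdose-free rows
        frame = _task_frame(seed=5, md_sessions=(2,))
        boosted = frame.copy()
        boosted.loc[boosted["condition"] == "MD", "value"] += 50.0
        eff_plain = compute_cps(frame)
        eff_boost = compute_cps(boosted)
        clean = eff_plain[eff_plain["session"] != 2].reset_index(drop=True)
        clean_b = eff_boost[eff_boost["session"] != 2].reset_index(drop=True)
        pd.testing.assert_frame_equal(clean, clean_b)


class TestChangeFromBaseline:
    @staticmethod
    def _scores(values):
        return pd.DataFrame(
            [
                {"participant_id": p, "scale_id": "rpwb", "timepoint": tp, "value": v}
                for p, tp, v in values
            ]
        )

    def test_equal_values_give_zero(self):
        scores = self._scores([("a", "baseline", 100.0), ("a", "week5", 100.0)])
        delta, excluded = change_from_baseline(scores, "rpwb", "week5")
        assert delta["change"].tolist() == [0.0]
        assert excluded == []

    def test_simple_difference(self):
        scores = self._scores([("a", "baseline", 100.0), ("a", "week5", 104.2)])
        delta, _ = change_from_baseline(scores, "rpwb", "week5")
        assert delta["change"].iloc[0] == pytest.approx(4.2)

    def test_missing_records_excluded_and_reported(self):
        scores = self._scores(
            [
                ("a", "baseline", 1.0),
                ("a", "week5", 2.0),
                ("b", "baseline", 3.0),
                ("c", "week5", 4.0),
            ]
        )
        delta, excluded = change_from_baseline(scores, "rpwb", "week5")
        assert delta["participant_id"].tolist() == ["a"]
        assert excluded == ["b", "c"]

    def test_matches_rowwise_join_oracle(self):
        rng = np.random.default_rng(9)
        vals = []
        for i in range(30):
            vals.append((f"p{i}", "baseline", rng.normal()))
            vals.append((f"p{i}", "week5", rng.normal()))
        scores = self._scores(vals)
        delta, _ = change_from_baseline(scores, "rpwb", "week5")
        wide = scores.pivot(index="participant_id", columns="timepoint", values="value")
        expected = (wide["week5"] - wide["baseline"]).sort_index()
        got = delta.set_index("participant_id")["change"].sort_index()
        assert np.allclose(got.to_numpy(), expected.to_numpy())
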