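"""Locked-window selection: tie-breaks, inclusivity, evaluability denominators."""

import datetime as dt
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promlock import (
    BehaviorMapping,
    DEFAULT_WINDOWS,
    Timepoint,
    assign_windows,
    build_analysis_cohort,
    default_behavior_mapping,
    evaluability_table,
    generate_cohort,
    select_baseline,
    select_in_window,
)

from conftest import full_capture_config, make_episodes, make_observations

M12 = DEFAULT_WINDOWS[Timepoint.M12]
BASE = DEFAULT_WINDOWS[Timepoint.BASELINE]


def _cands(days):
    return [(f"obs{d}", d) for d in days]


class TestSelectInWindow:
    @pytest.mark.parametrize(
        "days,expected",
        [
            ([200, 350], 200),  # |200-270|=70 beats |350-270|=80
            ([240, 300], 240),  # equidistant: earlier wins
            ([170, 370], None),  # both outside the inclusive bounds
            ([180], 180),  # exactly at the lower bound is selectable
            ([365], 365),  # exactly at the upper bound is selectable
            ([179], None),
            ([366], None),
        ],
    )
    def test_follow_up_selection(self, days, expected):
        chosen = select_in_window(_cands(days), M12.lower, M12.upper, M12.target)
        assert (chosen[1] if chosen else None) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=-200, max_value=900), min_size=0, max_size=12))
    def test_selection_is_order_invariant_and_deterministic(self, days):
        cands = _cands(list(dict.fromkeys(days)))
        shuffled = cands[:]
        random.Random(0).shuffle(shuffled)
        a = select_in_window(cands, M12.lower, M12.upper, M12.target)
        b = select_in_window(shuffled, M12.lower, M12.upper, M12.target)
        assert a == b
        if a is not None:
            assert M12.lower <= a[1] <= M12.upper


class TestSelectBaseline:
    @pytest.mark.parametrize(
        "days,expected_day,expected_flag",
        [
            ([-80, -10, 5], -10, False),  # pre-treatment preferred, nearest T0
            ([5, 10], 5, False),  # no pre-treatment: closest post day in window
            ([20, 60], 20, True),  # fallback window, flagged early-post
            ([0, 5], 0, False),  # day 0 counts as pre-treatment
            ([-90, 95], -90, False),  # inclusive preferred lower bound
            ([-91, 91], None, False),  # outside both windows
        ],
    )
    def test_two_step_rule(self, days, expected_day, expected_flag):
        chosen, early = select_baseline(_cands(days), BASE)
        assert (chosen[1] if chosen else None) == expected_day
        assert early is expected_flag

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=-150, max_value=150), min_size=1, max_size=10))
    def test_fallback_entered_only_when_preferred_window_empty(self, days):
        chosen, early = select_baseline(_cands(list(set(days))), BASE)
        preferred_exists = any(BASE.lower <= d <= BASE.upper for d in days)
        if early:
            assert not preferred_exists
            assert BASE.fallback[0] <= chosen[1] <= BASE.fallback[1]
        elif chosen is not None:
            assert BASE.lower <= chosen[1] <= BASE.upper


@pytest.fixture()
def anchored_episode(mapping):
    eps = make_episodes([("E1", "A", "Leiomyosarcoma", "2022-01-01", "", "")])
    cohort, _ = build_analysis_cohort(eps, mapping)
    return cohort


def _day(offset):
    return (dt.date(2022, 1, 1) + dt.timedelta(days=offset)).isoformat()


class TestAssignWindows:
    def test_episode_without_observations_has_three_nonevaluable_rows(self, anchored_episode):
        out = assign_windows(anchored_episode, make_observations([]))
        assert len(out) == 3
        assert not out["evaluable"].any()
        assert set(out["timepoint"]) == {"BASELINE", "M12", "M24"}

    def test_observation_without_metrics_is_never_selectable(self, anchored_episode):
        obs = make_observations([("E1", _day(270), "", "")])
        out = assign_windows(anchored_episode, obs)
        assert not out["evaluable"].any()

    def test_vas_only_observation_is_evaluable(self, anchored_episode):
        obs = make_observations([("E1", _day(730), "", "64")])
        out = assign_windows(anchored_episode, obs)
        row = out[out["timepoint"] == "M24"].iloc[0]
        assert row["evaluable"]
        assert row["eq_vas"] == 64 and pd.isna(row["eq5d_index"])

    def test_same_day_duplicates_prefer_more_complete_observation(self, anchored_episode):
        obs = make_observations(
            [
                ("E1", _day(270), "0.80", ""),
                ("E1", _day(270), "0.70", "75"),  # two metrics: wins despite later order
            ]
        )
        out = assign_windows(anchored_episode, obs)
        row = out[out["timepoint"] == "M12"].iloc[0]
        assert row["eq5d_index"] == 0.70 and row["eq_vas"] == 75

    def test_same_day_ties_break_to_first_input_row(self, anchored_episode):
        obs = make_observations(
            [("E1", _day(270), "0.80", "70"), ("E1", _day(270), "0.60", "60")]
        )
        out = assign_windows(anchored_episode, obs)
        assert out[out["timepoint"] == "M12"].iloc[0]["eq5d_index"] == 0.80

    def test_unknown_episode_observations_ignored_with_log(self, anchored_episode, caplog):
        obs = make_observations([("GHOST", _day(270), "0.9", "90")])
        with caplog.at_level("WARNING"):
            out = assign_windows(anchored_episode, obs)
        assert len(out) == 3 and not out["evaluable"].any()
        assert any("unknown episode ids" in r.message for r in caplog.records)


class TestEvaluabilityTable:
    def _table(self, n_eligible, evaluable_offsets):
        cohort = pd.DataFrame(
            {
                "episode_id": [f"E{i}" for i in range(n_eligible)],
                "institution": ["A"] * n_eligible,
                "t0": [dt.date(2022, 1, 1)] * n_eligible,
            }
        )
        rows = []
        for i in range(n_eligible):
            for tp in ("BASELINE", "M12", "M24"):
                ev = tp == "BASELINE" and i < len(evaluable_offsets)
                rows.append(
                    {
                        "episode_id": f"E{i}",
                        "institution": "A",
                        "timepoint": tp,
                        "obs_date": None,
                        "offset_days": evaluable_offsets[i] if ev else pd.NA,
                        "eq5d_index": 0.9 if ev else float("nan"),
                        "eq_vas": 90 if ev else pd.NA,
                        "early_post_baseline": False,
                        "evaluable": ev,
                    }
                )
        return evaluability_table(pd.DataFrame(rows), cohort)

    def test_percentage_at_two_decimals(self):
        table = self._table(729, [0] * 107)
        row = table[(table.institution == "A") & (table.timepoint == "BASELINE")].iloc[0]
        assert row["n_evaluable"] == 107 and row["n_eligible"] == 729
        assert row["pct_evaluable"] == 14.68

    def test_zero_evaluable_is_zero_percent(self):
        table = self._table(50, [])
        row = table[(table.institution == "A") & (table.timepoint == "M12")].iloc[0]
        assert row["pct_evaluable"] == 0.00

    def test_singleton_offset_median_and_iqr_collapse(self):
        table = self._table(10, [-42])
        row = table[(table.institution == "A") & (table.timepoint == "BASELINE")].iloc[0]
        assert (row["offset_median"], row["offset_q1"], row["offset_q3"]) == (-42, -42, -42)

    def test_full_capture_cohort_is_fully_evaluable(self):
        eps, obs, _ = generate_cohort(full_capture_config())
        mapping = BehaviorMapping.from_frame(default_behavior_mapping())
        cohort, _ = build_analysis_cohort(eps, mapping)
        table = evaluability_table(assign_windows(cohort, obs), cohort)
        assert (table["pct_evaluable"] == 100.0).all()
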