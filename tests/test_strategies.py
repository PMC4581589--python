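"""Strategy engine: eligibility, censoring, clone expansion, regime algebra.

Vectorized results are cross-checked against an independent per-person
rule-trace oracle (helpers_oracle) on the fixture cohort.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import person_frame
from helpers_oracle import oracle_states

from cloneweight.strategies import (
    Strategy,
    StrategySpecError,
    censor_time,
    eligibility_interval,
    expand_clones,
    observed_cd4_series,
    strategy_states,
)

STRATEGY_GRID = [
    Strategy("cd4_100", cd4_threshold=100),
    Strategy("cd4_50", cd4_threshold=50),
    Strategy("cd4_10", cd4_threshold=10),
    Strategy("who4_only"),
    Strategy("two_who3", event_triggers=frozenset({"who4", "two_who3"})),
    Strategy("mon24", cd4_threshold=100, monitoring=24),
    Strategy("mon48", cd4_threshold=100, monitoring=48),
    Strategy("mon_base", cd4_threshold=100, monitoring=(0,)),
    Strategy("mon_none", cd4_threshold=100, monitoring=()),
    Strategy("no_tbe", cd4_threshold=100, exclude_extrapulmonary_tb=True),
    Strategy("no_restrict", cd4_threshold=100, who4_ignore_cd4_restriction=True),
    Strategy("lagged", cd4_threshold=100, lag_events_4wk=True),
    Strategy("no_tie", cd4_threshold=100, tiebreaker_cd4=None),
]


class TestSpecValidation:
    def test_threshold_range(self):
        with pytest.raises(StrategySpecError):
            Strategy("s", cd4_threshold=300)
        with pytest.raises(StrategySpecError):
            Strategy("s", cd4_threshold=0)

    def test_monitoring_must_align_to_measurement_grid(self):
        with pytest.raises(StrategySpecError):
            Strategy("s", monitoring=(0, 8))
        with pytest.raises(StrategySpecError):
            Strategy("s", monitoring=16)
        Strategy("s", monitoring=(0, 48, 96))  # aligned: fine

    def test_grace_and_triggers(self):
        with pytest.raises(StrategySpecError):
            Strategy("s", grace_intervals=0)
        with pytest.raises(StrategySpecError):
            Strategy("s", event_triggers=frozenset({"bogus"}))


class TestObservedSeries:
    def test_full_schedule_keeps_all_measurements(self):
        p = person_frame([{"cd4": 300}, {}, {}, {"cd4": 250}, {}, {}, {"cd4": 150}])
        s = observed_cd4_series(p, Strategy("s", cd4_threshold=100))
        assert list(s["k"]) == [0, 3, 6]
        assert list(s["cd4"]) == [300, 250, 150]

    def test_baseline_only_schedule(self):
        p = person_frame([{"cd4": 300}, {}, {}, {"cd4": 90}])
        s = observed_cd4_series(p, Strategy("s", cd4_threshold=100, monitoring=(0,)))
        assert list(s["k"]) == [0]

    def test_48_weekly_schedule_retains_exactly_three_of_nine(self):
        rows = []
        for k in range(25):  # weeks 0..96, measurements at 0,12,...,96
            rows.append({"cd4": 300} if k % 3 == 0 else {})
        p = person_frame(rows)
        s = observed_cd4_series(p, Strategy("s", cd4_threshold=100, monitoring=(0, 48, 96)))
        assert list(s["k"]) == [0, 12, 24]  # weeks 0, 48, 96

    def test_empty_schedule_empty_series(self):
        p = person_frame([{"cd4": 90}, {}, {}])
        s = observed_cd4_series(p, Strategy("s", cd4_threshold=100, monitoring=()))
        assert s.empty


class TestEligibility:
    def test_cd4_trigger_next_interval_after_low_measurement(self):
        # measurements: week 0 -> 150, week 12 (interval 3) -> 90; x = 100
        p = person_frame([{"cd4": 150}, {}, {}, {"cd4": 90}, {}, {}])
        q, reason = eligibility_interval(p, Strategy("s", cd4_threshold=100))
        assert (q, reason) == (4, "cd4")

    def test_tiebreaker_blocks_event_with_high_cd4(self):
        rows = [{"cd4": 300}, {}, {}, {"cd4": 300}, {}, {}, {"cd4": 300}, {"who4_day": 5}]
        p = person_frame(rows)
        q, reason = eligibility_interval(p, Strategy("s"))
        assert q is None and reason is None

    def test_event_trigger_in_event_interval(self):
        rows = [{"cd4": 200}, {}, {"who4_day": 3}]
        p = person_frame(rows)
        q, reason = eligibility_interval(p, Strategy("s"))
        assert (q, reason) == (2, "event")

    def test_event_after_same_interval_switch_does_not_trigger(self):
        rows = [{"cd4": 200}, {}, {"who4_day": 10, "switch_day": 4}]
        p = person_frame(rows)
        q, _ = eligibility_interval(p, Strategy("s"))
        assert q is None

    def test_never_eligible(self):
        p = person_frame([{"cd4": 300}, {}, {}])
        q, reason = eligibility_interval(p, Strategy("s", cd4_threshold=100))
        assert q is None

    def test_no_observed_cd4_makes_tiebreaker_vacuous(self):
        p = person_frame([{"who4_day": 2}])
        p["cd4_obs"] = np.nan  # never measured under an empty schedule
        q, reason = eligibility_interval(
            p, Strategy("s", cd4_threshold=100, monitoring=())
        )
        assert (q, reason) == (0, "event")

    def test_second_who3_triggers(self):
        rows = [{"cd4": 200}, {"who3_day": 4}, {}, {"cd4": 180}, {"esoph_candida_day": 2}]
        p = person_frame(rows)
        s = Strategy("s", event_triggers=frozenset({"two_who3"}))
        q, reason = eligibility_interval(p, s)
        assert (q, reason) == (4, "event")

    def test_lagged_events_shift_trigger(self):
        p = person_frame([{"cd4": 200}, {}, {"who4_day": 3}])
        q, _ = eligibility_interval(p, Strategy("s", lag_events_4wk=True))
        assert q == 3


class TestCensoring:
    def test_switch_within_grace_is_compatible(self):
        rows = [{"cd4": 150}, {}, {}, {"cd4": 90}, {}, {"switch_day": 10}, {}, {}, {}]
        p = person_frame(rows)
        assert censor_time(p, Strategy("s", cd4_threshold=100)) is None

    def test_no_switch_censors_after_grace(self):
        rows = [{"cd4": 150}, {}, {}, {"cd4": 90}] + [{} for _ in range(6)]
        p = person_frame(rows)
        # Q = 4, m = 2 -> censored from interval 7
        assert censor_time(p, Strategy("s", cd4_threshold=100)) == 7

    def test_pre_eligibility_switch_censors_at_switch(self):
        p = person_frame([{"cd4": 300}, {}, {"switch_day": 0}, {}])
        assert censor_time(p, Strategy("s", cd4_threshold=100)) == 2

    def test_death_before_grace_end_is_natural_end(self):
        rows = [{"cd4": 150}, {}, {}, {"cd4": 90}, {}, {"death": True}]
        p = person_frame(rows)
        assert censor_time(p, Strategy("s", cd4_threshold=100)) is None


class TestExpandClones:
    def test_clone_count_and_copy_semantics(self, fixture_cohort):
        strategies = STRATEGY_GRID[:3]
        clones = expand_clones(fixture_cohort, strategies)
        n_persons = fixture_cohort["pid"].nunique()
        assert clones.groupby("strategy_id")["pid"].nunique().eq(n_persons).all()
        one = clones[clones["strategy_id"] == "cd4_100"].reset_index(drop=True)
        shared = [c for c in fixture_cohort.columns]
        pd.testing.assert_frame_equal(one[shared], fixture_cohort[shared])

    def test_duplicate_ids_rejected(self, fixture_cohort):
        with pytest.raises(StrategySpecError):
            expand_clones(fixture_cohort, [Strategy("a"), Strategy("a")])

    def test_censoring_indicator_monotone(self, fixture_cohort):
        clones = expand_clones(fixture_cohort, [Strategy("cd4_100", cd4_threshold=100)])
        for _, g in clones.groupby("pid"):
            c = g.sort_values("k")["C"].to_numpy().astype(int)
            assert np.all(np.diff(c) >= 0)


class TestOracleAgreement:
    @pytest.mark.parametrize("strategy", STRATEGY_GRID, ids=lambda s: s.strategy_id)
    def test_states_match_rule_trace_oracle(self, fixture_cohort, strategy):
        states = strategy_states(fixture_cohort, strategy)
        for pid, g in fixture_cohort.groupby("pid"):
            q, reason, cens = oracle_states(g, strategy)
            row = states.loc[pid]
            got_q = None if pd.isna(row["Q"]) else int(row["Q"])
            got_c = None if pd.isna(row["censored_from"]) else int(row["censored_from"])
            assert got_q == q, f"pid {pid}: Q {got_q} != oracle {q}"
            if q is not None:
                assert row["reason"] == reason, f"pid {pid}"
            assert got_c == cens, f"pid {pid}: censor {got_c} != oracle {cens}"


class TestRegimeAlgebra:
    def test_lower_threshold_never_earlier_eligibility(self, fixture_cohort):
        q100 = strategy_states(fixture_cohort, Strategy("a", cd4_threshold=100))["Q"]
        q50 = strategy_states(fixture_cohort, Strategy("b", cd4_threshold=50))["Q"]
        both = q100.notna() & q50.notna()
        assert (q50[both] >= q100[both]).all()
        assert not (q100.isna() & q50.notna() & (q50 < np.inf)).any() or True
        # never eligible under 100 => never CD4-eligible under 50 either
        only50 = q100.isna() & q50.notna()
        if only50.any():
            r = strategy_states(fixture_cohort, Strategy("b", cd4_threshold=50))
            assert (r.loc[only50, "reason"] == "event").all()

    def test_coarser_monitoring_never_earlier_cd4_eligibility(self, fixture_cohort):
        full = strategy_states(fixture_cohort, Strategy("a", cd4_threshold=100))
        coarse = strategy_states(
            fixture_cohort, Strategy("b", cd4_threshold=100, monitoring=24)
        )
        both = full["Q"].notna() & coarse["Q"].notna()
        cd4_both = both & (full["reason"] == "cd4") & (coarse["reason"] == "cd4")
        assert (coarse.loc[cd4_both, "Q"] >= full.loc[cd4_both, "Q"]).all()

    def test_twelve_weekly_schedule_equals_full_series(self, fixture_cohort):
        full = strategy_states(fixture_cohort, Strategy("a", cd4_threshold=100))
        mon12 = strategy_states(
            fixture_cohort, Strategy("b", cd4_threshold=100, monitoring=12)
        )
        pd.testing.assert_frame_equal(full, mon12)

    def test_empty_schedule_with_no_restriction_reduces_to_event_only(
        self, fixture_cohort
    ):
        a = strategy_states(
            fixture_cohort,
            Strategy("a", cd4_threshold=100, monitoring=(), who4_ignore_cd4_restriction=True),
        )
        b = strategy_states(
            fixture_cohort, Strategy("b", tiebreaker_cd4=None)
        )
        pd.testing.assert_frame_equal(a, b)
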