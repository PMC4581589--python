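"""Weight engine: strategy weights vs enumeration oracle, substudy and
LTFU weights, truncation, positivity guards."""

import numpy as np
import pandas as pd
import pytest

from conftest import person_frame
from helpers_oracle import oracle_weight_series

from cloneweight.strategies import Strategy, expand_clones
from cloneweight.weights import (
    PositivityError,
    WeightAlignmentError,
    combine_truncate,
    compute_strategy_weights,
    ltfu_weight_series,
    substudy_weights,
    weight_summary,
)


def clone_with_probs(person: pd.DataFrame, strategy: Strategy, p_switch) -> pd.DataFrame:
    clones = expand_clones(person, [strategy])
    clones["p_switch"] = np.where(clones["on_first_line"], p_switch, np.nan)
    return clones


class TestStrategyWeightArithmetic:
    def test_first_grace_interval_no_switch_factor(self):
        # m=2, r=0, p_A = 0.9: factor (1 - 1/3) / 0.9
        rows = [{"cd4": 90}] + [{} for _ in range(4)]
        p = person_frame(rows)
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 0.1)
        out = compute_strategy_weights(clones, grace_m=2)
        r0 = out[(out["k"] == 1)]["w_factor"].iloc[0]
        assert r0 == pytest.approx((1 - 1 / 3) / 0.9, abs=1e-12)

    def test_last_grace_interval_without_switch_zeroes_weight(self):
        rows = [{"cd4": 90}] + [{} for _ in range(4)]
        p = person_frame(rows)
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 0.1)
        out = compute_strategy_weights(clones, grace_m=2)
        # Q = 1, grace = 1..3; interval 3 is the forced-switch interval
        assert out[out["k"] == 3]["w_strategy"].iloc[0] == 0.0

    def test_switch_in_grace_uses_uniform_numerator(self):
        rows = [{"cd4": 90}, {}, {"switch_day": 5}, {}, {}]
        p = person_frame(rows)
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 0.2)
        out = compute_strategy_weights(clones, grace_m=2).set_index("k")
        # interval 0 pre-eligibility factor 1/0.8; Q = 1: interval 1
        # no-switch factor (1-1/3)/0.8; interval 2 (r=1) switch factor
        # (1/2)/0.2; afterwards factor 1
        assert out.loc[0, "w_factor"] == pytest.approx(1 / 0.8, abs=1e-12)
        assert out.loc[1, "w_factor"] == pytest.approx((2 / 3) / 0.8, abs=1e-12)
        assert out.loc[2, "w_factor"] == pytest.approx(0.5 / 0.2, abs=1e-12)
        assert out.loc[3, "w_factor"] == 1.0
        assert out.loc[4, "w_strategy"] == pytest.approx(
            (1 / 0.8) * (2 / 3) / 0.8 * 0.5 / 0.2
        )

    def test_pre_eligibility_inverse_probability(self):
        p = person_frame([{"cd4": 150}, {}, {}, {"cd4": 90}, {}])
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 0.05)
        out = compute_strategy_weights(clones, grace_m=2).set_index("k")
        for k in (0, 1, 2, 3):
            assert out.loc[k, "w_factor"] == pytest.approx(1 / 0.95, abs=1e-12)

    def test_censored_rows_have_zero_weight(self):
        p = person_frame([{"cd4": 300}, {}, {"switch_day": 0}, {}])
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 0.1)
        out = compute_strategy_weights(clones, grace_m=2).set_index("k")
        assert (out.loc[2:, "w_strategy"] == 0.0).all()
        assert (out.loc[:1, "w_strategy"] > 0).all()


class TestOracleEquivalence:
    def test_fixture_weights_match_enumeration(self, fixture_weighted):
        cohort_w, _, _ = fixture_weighted
        for strategy in (
            Strategy("cd4_100", cd4_threshold=100),
            Strategy("who4_only"),
            Strategy("mon48", cd4_threshold=100, monitoring=48),
        ):
            clones = expand_clones(cohort_w, [strategy])
            out = compute_strategy_weights(clones, strategy.grace_m)
            for pid, g in out.groupby("pid"):
                Q = g["Q_x"].iloc[0]
                cens = g["censored_from"].iloc[0]
                want = oracle_weight_series(
                    g,
                    None if pd.isna(Q) else int(Q),
                    None if pd.isna(cens) else int(cens),
                    strategy.grace_m,
                )
                got = g.sort_values("k")["w_strategy"].to_numpy()
                assert np.max(np.abs(got - want)) <= 1e-12, f"pid {pid}"


class TestPositivity:
    def test_tiny_no_switch_denominator_raises(self):
        p = person_frame([{"cd4": 150}, {}, {}])
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 1 - 1e-9)
        with pytest.raises(PositivityError):
            compute_strategy_weights(clones, grace_m=2)

    def test_tiny_switch_denominator_raises(self):
        rows = [{"cd4": 90}, {"switch_day": 3}, {}]
        p = person_frame(rows)
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 1e-9)
        with pytest.raises(PositivityError):
            compute_strategy_weights(clones, grace_m=2)

    def test_positivity_violation_is_logged(self, caplog):
        p = person_frame([{"cd4": 150}, {}, {}])
        clones = clone_with_probs(p, Strategy("s", cd4_threshold=100), 1 - 1e-9)
        with caplog.at_level("ERROR"), pytest.raises(PositivityError):
            compute_strategy_weights(clones, grace_m=2)
        assert "positivity violation" in caplog.text


class TestSubstudyWeights:
    def _cohort(self, n_sti, n_ct, entry=1, n_out=5, K=4):
        frames = []
        pid = 0
        for group, count in (("sti", n_sti), ("ct", n_ct), ("none", n_out)):
            for _ in range(count):
                f = person_frame([{"cd4": 200}] + [{} for _ in range(K - 1)], pid=pid)
                f["substudy"] = group
                f["substudy_stratum"] = "A:LCM"
                frames.append(f)
                pid += 1
        return pd.concat(frames, ignore_index=True)

    def test_balanced_stratum_weight_two(self):
        cohort = self._cohort(30, 30)
        w = substudy_weights(cohort, entry_interval=1)
        ct = cohort["substudy"] == "ct"
        assert (w[ct & (cohort["k"] >= 1)] == 2.0).all()
        assert (w[ct & (cohort["k"] == 0)] == 1.0).all()
        sti = cohort["substudy"] == "sti"
        assert (w[sti & (cohort["k"] >= 1)] == 0.0).all()
        assert (w[cohort["substudy"] == "none"] == 1.0).all()

    def test_unbalanced_stratum_weight(self):
        cohort = self._cohort(20, 40)
        w = substudy_weights(cohort, entry_interval=1)
        ct = (cohort["substudy"] == "ct") & (cohort["k"] >= 1)
        assert (w[ct] == 1.5).all()

    def test_no_substudy_all_ones(self, fixture_cohort):
        plain = fixture_cohort.copy()
        plain["substudy"] = "none"
        assert (substudy_weights(plain, 1) == 1.0).all()

    def test_stratum_without_continuous_arm_raises(self):
        cohort = self._cohort(5, 0)
        with pytest.raises(PositivityError):
            substudy_weights(cohort, entry_interval=1)


class TestLtfuWeights:
    def test_matches_closed_form_cumulative_product(self):
        p = pd.concat(
            [person_frame([{"cd4": 200}] + [{} for _ in range(3)], pid=i) for i in range(3)],
            ignore_index=True,
        )
        probs = pd.Series(np.tile([0.01, 0.02, 0.05, 0.0], 3), index=p.index)
        w = ltfu_weight_series(p, probs)
        want = np.tile(np.cumprod(1 / (1 - np.array([0.01, 0.02, 0.05, 0.0]))), 3)
        assert np.max(np.abs(w.to_numpy() - want)) <= 1e-12

    def test_non_decreasing_within_person(self, fixture_weighted):
        cohort_w, _, _ = fixture_weighted
        for _, g in cohort_w.groupby("pid"):
            assert np.all(np.diff(g.sort_values("k")["w_ltfu"].to_numpy()) >= -1e-15)

    def test_zero_dropout_gives_unit_weights(self):
        from cloneweight.pipeline import attach_person_interval_weights
        from cloneweight.synthetic import SimulationConfig, generate_cohort

        cfg = SimulationConfig(n_individuals=60, n_intervals=8, seed=12, ltfu_hazard=0.0)
        cohort = generate_cohort(cfg)
        cohort_w, _, ltfu_fit = attach_person_interval_weights(cohort)
        assert ltfu_fit is None
        assert (cohort_w["w_ltfu"] == 1.0).all()

    def test_retention_below_floor_raises(self):
        p = person_frame([{"cd4": 200}, {}])
        probs = pd.Series([0.5, 1.0 - 1e-9], index=p.index)
        with pytest.raises(PositivityError):
            ltfu_weight_series(p, probs)


class TestCombineTruncate:
    def test_truncates_at_cap(self):
        s = pd.Series([37.2, 2.5, 0.0])
        ones = pd.Series([1.0, 1.0, 1.0])
        out = combine_truncate(s, ones, ones)
        assert list(out["w"]) == [10.0, 2.5, 0.0]
        assert list(out["w_raw"]) == [37.2, 2.5, 0.0]

    def test_infinite_cap_keeps_raw(self):
        s = pd.Series([37.2, 2.5])
        ones = pd.Series([1.0, 1.0])
        out = combine_truncate(s, ones, ones, cap=np.inf)
        assert (out["w"] == out["w_raw"]).all()

    def test_componentwise_product(self):
        a = pd.Series([2.0, 3.0])
        b = pd.Series([0.5, 2.0])
        c = pd.Series([1.0, 1.5])
        out = combine_truncate(a, b, c)
        assert np.allclose(out["w_raw"], [1.0, 9.0])

    def test_misaligned_series_rejected(self):
        a = pd.Series([1.0, 2.0])
        b = pd.Series([1.0, 2.0], index=[5, 6])
        with pytest.raises(WeightAlignmentError):
            combine_truncate(a, b, b.copy())

    def test_weight_summary_reports_truncation(self):
        w = pd.Series([0.0, 1.0, 5.0, 10.0, 10.0])
        s = weight_summary(w)
        assert s["n_positive"] == 4
        assert s["max"] == 10.0
        assert s["frac_truncated"] == pytest.approx(0.5)
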