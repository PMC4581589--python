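"""Switching strategies, eligibility, artificial censoring, clone expansion.

A strategy is a dynamic regime: switch to second-line ART at the first
*observed* CD4 count below a threshold and/or at a qualifying WHO stage 3/4
event (subject to a CD4 tie-breaker), within a grace period of
``grace_intervals`` 4-week intervals. Which CD4 counts are observed is set
by the monitoring schedule; measurements off the schedule are invisible to
the regime (though never to the weight models).

Interval convention: interval ``k`` covers days ``[28k, 28k + 28)``
(0-based, half-open); a week-``w`` measurement lands in interval ``w // 4``
and is taken on the interval's first day, so it precedes any same-interval
event or switch. A CD4 trigger makes the individual eligible from the
interval *after* the measurement; an event trigger makes them eligible in
the event's own interval provided the event occurred strictly before any
switch. Eligible individuals may switch in intervals ``Q .. Q + m`` (with
``m = grace_intervals - 1``); failure to switch censors the clone from
``Q + m + 1``, and switching before eligibility censors at the switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASUREMENT_WEEK_GRID = 12  # CD4 is measured every 12 weeks

VALID_TRIGGERS = frozenset({"who4", "two_who3"})


class StrategySpecError(ValueError):
    """Invalid strategy definition."""


@dataclass(frozen=True)
class Strategy:
    """A switching rule plus monitoring schedule plus grace period.

    Parameters
    ----------
    cd4_threshold
        Switch at the first observed CD4 below this value (cells/mm^3),
        or ``None`` for event-only strategies.
    event_triggers
        Subset of ``{"who4", "two_who3"}``: first non-Candida WHO 4 event,
        and/or second WHO 3 / esophageal candidiasis event.
    tiebreaker_cd4
        Event triggers apply only if the last prior observed CD4 was below
        this value (vacuously satisfied when no CD4 was ever observed under
        the schedule); ``None`` disables the restriction.
    monitoring
        ``"all"`` (every 12-weekly measurement), an integer period in weeks
        (multiple of 12, e.g. 24, 48, 96, always including week 0), or an
        explicit tuple of week offsets (possibly empty).
    """

    strategy_id: str
    cd4_threshold: float | None = None
    event_triggers: frozenset = frozenset({"who4"})
    tiebreaker_cd4: float | None = 250.0
    monitoring: object = "all"
    grace_intervals: int = 3
    exclude_extrapulmonary_tb: bool = False
    who4_ignore_cd4_restriction: bool = False
    lag_events_4wk: bool = False

    def __post_init__(self) -> None:
        if self.grace_intervals < 1:
            raise StrategySpecError("grace_intervals must be >= 1")
        if self.cd4_threshold is not None and not (0 < self.cd4_threshold < 250):
            raise StrategySpecError("cd4_threshold must lie in (0, 250)")
        trig = frozenset(self.event_triggers)
        if not trig <= VALID_TRIGGERS:
            raise StrategySpecError(f"unknown event triggers: {trig - VALID_TRIGGERS}")
        object.__setattr__(self, "event_triggers", trig)
        mon = self.monitoring
        if isinstance(mon, str):
            if mon != "all":
                raise StrategySpecError(f"unknown monitoring spec {mon!r}")
        elif isinstance(mon, (int, np.integer)):
            if mon <= 0 or mon % MEASUREMENT_WEEK_GRID != 0:
                raise StrategySpecError(
                    "monitoring period must be a positive multiple of "
                    f"{MEASUREMENT_WEEK_GRID} weeks"
                )
        else:
            weeks = tuple(int(w) for w in mon)
            for w in weeks:
                if w < 0 or w % MEASUREMENT_WEEK_GRID != 0:
                    raise StrategySpecError(
                        f"monitoring week {w} is not on the "
                        f"{MEASUREMENT_WEEK_GRID}-weekly measurement grid"
                    )
            object.__setattr__(self, "monitoring", weeks)

    @property
    def grace_m(self) -> int:
        """Number of grace intervals after the first one (m)."""
        return self.grace_intervals - 1

    def observes_week(self, week: int) -> bool:
        if isinstance(self.monitoring, str):
            return True
        if isinstance(self.monitoring, (int, np.integer)):
            return week % int(self.monitoring) == 0
        return week in self.monitoring

    def observes_weeks(self, weeks: np.ndarray) -> np.ndarray:
        weeks = np.asarray(weeks)
        if isinstance(self.monitoring, str):
            return np.ones(weeks.shape, dtype=bool)
        if isinstance(self.monitoring, (int, np.integer)):
            return weeks % int(self.monitoring) == 0
        return np.isin(weeks, np.asarray(self.monitoring, dtype=weeks.dtype))


def _who4_day_cols(strategy: Strategy) -> list[str]:
    cols = ["who4_day"]
    if not strategy.exclude_extrapulmonary_tb:
        cols.append("tb_extra_day")
    return cols


_WHO3_DAY_COLS = ["who3_day", "esoph_candida_day", "tb_pulm_day"]


def observed_cd4_series(person: pd.DataFrame, strategy: Strategy) -> pd.DataFrame:
    """CD4 measurements visible under the strategy's monitoring schedule.

    Returns a frame with columns ``k`` and ``cd4`` (one row per retained
    measurement, in interval order).
    """
    measured = person["cd4_obs"].notna()
    retained = measured & strategy.observes_weeks(4 * person["k"].to_numpy())
    out = person.loc[retained, ["k", "cd4_obs"]].rename(columns={"cd4_obs": "cd4"})
    return out.reset_index(drop=True)


def strategy_states(cohort: pd.DataFrame, strategy: Strategy) -> pd.DataFrame:
    """Per-person eligibility and censoring state under one strategy.

    Returns a frame indexed by ``pid`` with columns ``Q`` (first eligible
    interval, NaN if never), ``reason`` ("cd4", "event" or None; ties go to
    the event), ``censored_from`` (first artificially censored interval,
    NaN if never censored during follow-up).
    """
    df = cohort
    pid = df["pid"]
    k = df["k"].to_numpy()
    measured = df["cd4_obs"].notna().to_numpy()
    retained = measured & strategy.observes_weeks(4 * k)

    # CD4 trigger: first retained measurement below threshold -> next interval
    if strategy.cd4_threshold is not None:
        trig_cd4 = retained & (df["cd4_obs"].to_numpy() < strategy.cd4_threshold)
    else:
        trig_cd4 = np.zeros(len(df), dtype=bool)
    q_cd4 = (
        pd.Series(np.where(trig_cd4, k, np.nan), index=df.index)
        .groupby(pid, sort=False)
        .min()
        + 1
    )

    # last prior observed CD4 for the tie-breaker (strategy-observed series)
    locf = df["cd4_obs"].where(retained).groupby(pid, sort=False).ffill()
    if strategy.tiebreaker_cd4 is None or strategy.who4_ignore_cd4_restriction:
        tie_ok = np.ones(len(df), dtype=bool)
    else:
        tie_ok = (locf.isna() | (locf < strategy.tiebreaker_cd4)).to_numpy()

    sw_day = df["switch_day"].to_numpy()

    def _valid(day_col: str) -> np.ndarray:
        day = df[day_col].to_numpy()
        return ~np.isnan(day) & (np.isnan(sw_day) | (day < sw_day))

    trig_evt = np.zeros(len(df), dtype=bool)
    if "who4" in strategy.event_triggers:
        any_who4 = np.zeros(len(df), dtype=bool)
        for c in _who4_day_cols(strategy):
            any_who4 |= _valid(c)
        trig_evt |= any_who4 & tie_ok
    if "two_who3" in strategy.event_triggers:
        count = np.zeros(len(df), dtype=int)
        for c in _WHO3_DAY_COLS:
            count += _valid(c).astype(int)
        cum = pd.Series(count, index=df.index).groupby(pid, sort=False).cumsum().to_numpy()
        trig_evt |= (cum >= 2) & (cum - count < 2) & (count >= 1) & tie_ok

    q_evt = (
        pd.Series(np.where(trig_evt, k, np.nan), index=df.index)
        .groupby(pid, sort=False)
        .min()
    )
    if strategy.lag_events_4wk:
        q_evt = q_evt + 1

    states = pd.DataFrame({"q_cd4": q_cd4, "q_evt": q_evt})
    states["Q"] = states.min(axis=1)
    states["reason"] = np.select(
        [states["q_evt"] <= states["Q"], states["q_cd4"] <= states["Q"]],
        ["event", "cd4"],
        default=None,
    )

    per = df.groupby(pid, sort=False)["k"]
    states["last_k"] = per.max()
    first_switch = (
        pd.Series(np.where(df["switch"].to_numpy(), k, np.nan), index=df.index)
        .groupby(pid, sort=False)
        .min()
    )
    states["first_switch"] = first_switch

    Q = states["Q"].to_numpy()
    s = states["first_switch"].to_numpy()
    last_k = states["last_k"].to_numpy()
    mQ = np.isnan(Q)
    m = strategy.grace_m
    cens = np.full(len(states), np.nan)
    # pre-eligibility switch (or any switch when never eligible)
    pre = ~np.isnan(s) & (mQ | (s < Q))
    cens[pre] = s[pre]
    # no switch within the grace period, follow-up continuing past it
    late = ~mQ & ~pre & (np.isnan(s) | (s > Q + m)) & (last_k >= Q + m + 1)
    cens[late] = Q[late] + m + 1
    states["censored_from"] = cens
    states.index.name = "pid"
    return states[["Q", "reason", "censored_from", "first_switch", "last_k"]]


def eligibility_interval(person: pd.DataFrame, strategy: Strategy):
    """First eligible interval ``Q`` (or None) and trigger reason."""
    st = strategy_states(person, strategy).iloc[0]
    q = None if pd.isna(st["Q"]) else int(st["Q"])
    return q, (st["reason"] if q is not None else None)


def censor_time(person: pd.DataFrame, strategy: Strategy):
    """Interval from which the person's clone is artificially censored."""
    st = strategy_states(person, strategy).iloc[0]
    return None if pd.isna(st["censored_from"]) else int(st["censored_from"])


def expand_clones(cohort: pd.DataFrame, strategies) -> pd.DataFrame:
    """Replicate the cohort once per strategy with censoring state attached.

    Adds columns ``strategy_id``, ``Q_x``, ``r`` (grace offset, NaN outside
    the grace period), ``censored_from`` and ``C`` (artificial-censoring
    indicator; rows with ``C == 1`` are excluded from outcome risk sets).
    """
    strategies = list(strategies)
    if not strategies:
        raise StrategySpecError("at least one strategy is required")
    ids = [s.strategy_id for s in strategies]
    if len(set(ids)) != len(ids):
        raise StrategySpecError("duplicate strategy_id")
    parts = []
    for strat in strategies:
        states = strategy_states(cohort, strat)
        clone = cohort.copy()
        clone["src_row"] = np.arange(len(cohort))
        clone["strategy_id"] = strat.strategy_id
        clone["Q_x"] = clone["pid"].map(states["Q"])
        cens = clone["pid"].map(states["censored_from"])
        clone["censored_from"] = cens
        clone["C"] = (clone["k"] >= cens).fillna(False).astype(bool)
        r = clone["k"] - clone["Q_x"]
        clone["r"] = r.where((r >= 0) & (r <= strat.grace_m))
        parts.append(clone)
    return pd.concat(parts, ignore_index=True)
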