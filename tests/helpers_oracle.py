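"""Independent rule-trace oracles used to cross-check the vectorized
strategy engine and weight engine.

These are deliberately written as explicit per-person Python loops, straight
from the regime definitions, and share no code with the implementation.
"""

import math

import numpy as np
import pandas as pd

WHO3_COLS = ("who3_day", "esoph_candida_day", "tb_pulm_day")


def _valid_event(day, switch_day) -> bool:
    """Event counts only when strictly before a same-interval switch."""
    if day is None or (isinstance(day, float) and math.isnan(day)):
        return False
    if switch_day is None or (isinstance(switch_day, float) and math.isnan(switch_day)):
        return True
    return day < switch_day


def oracle_states(person: pd.DataFrame, strategy):
    """(Q, reason, censored_from) for one person's history, by rule trace."""
    rows = person.sort_values("k").to_dict("records")
    x = strategy.cd4_threshold
    m = strategy.grace_intervals - 1

    who4_cols = ["who4_day"] + (
        [] if strategy.exclude_extrapulmonary_tb else ["tb_extra_day"]
    )

    # --- CD4 trigger: first retained measurement below x -> next interval
    q_cd4 = None
    for row in rows:
        if not math.isnan(row["cd4_obs"]) and strategy.observes_week(4 * row["k"]):
            if x is not None and row["cd4_obs"] < x:
                q_cd4 = row["k"] + 1
                break

    # --- event trigger, with tie-breaker on last retained CD4
    q_evt = None
    last_obs = None
    n_who3 = 0
    for row in rows:
        k = row["k"]
        if not math.isnan(row["cd4_obs"]) and strategy.observes_week(4 * k):
            last_obs = row["cd4_obs"]
        if strategy.tiebreaker_cd4 is None or strategy.who4_ignore_cd4_restriction:
            tie_ok = True
        else:
            tie_ok = last_obs is None or last_obs < strategy.tiebreaker_cd4
        sw_day = row["switch_day"]
        triggered = False
        if "who4" in strategy.event_triggers:
            if any(_valid_event(row[c], sw_day) for c in who4_cols) and tie_ok:
                triggered = True
        if "two_who3" in strategy.event_triggers:
            hits = sum(_valid_event(row[c], sw_day) for c in WHO3_COLS)
            if hits and n_who3 < 2 <= n_who3 + hits and tie_ok:
                triggered = True
            n_who3 += hits
        if triggered and q_evt is None:
            q_evt = k + 1 if strategy.lag_events_4wk else k
    candidates = [q for q in (q_cd4, q_evt) if q is not None]
    if not candidates:
        Q, reason = None, None
    else:
        Q = min(candidates)
        reason = "event" if (q_evt is not None and q_evt <= Q) else "cd4"

    # --- artificial censoring
    first_switch = None
    for row in rows:
        if row["switch"]:
            first_switch = row["k"]
            break
    last_k = rows[-1]["k"]
    if Q is None:
        cens = first_switch
    elif first_switch is not None and first_switch < Q:
        cens = first_switch
    elif first_switch is not None and Q <= first_switch <= Q + m:
        cens = None
    elif last_k >= Q + m + 1:
        cens = Q + m + 1
    else:
        cens = None
    return Q, reason, cens


def oracle_weight_series(
    person: pd.DataFrame, Q, censored_from, grace_m: int
) -> np.ndarray:
    """W_x(k) per interval by term-by-term enumeration of the weight formula.

    ``person`` must carry a ``p_switch`` column (NaN off the switch risk
    set). Censored intervals get weight 0.
    """
    rows = person.sort_values("k").to_dict("records")
    m = grace_m
    out = np.zeros(len(rows))
    prod = 1.0
    for i, row in enumerate(rows):
        k = row["k"]
        censored = censored_from is not None and k >= censored_from
        if not censored and row["on_first_line"]:
            p_A = 1.0 - row["p_switch"]
            if Q is None or k < Q:
                if not row["switch"]:
                    prod *= 1.0 / p_A
            elif k <= Q + m:
                r = k - Q
                if row["switch"]:
                    prod *= (1.0 / (m + 1 - r)) / (1.0 - p_A)
                else:
                    prod *= (1.0 - 1.0 / (m + 1 - r)) / p_A
            # beyond the grace period without censoring: switched clone, factor 1
        out[i] = 0.0 if censored else prod
    return out
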