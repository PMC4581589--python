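"""Inverse-probability weights for the clone-censor-weight estimator.

Three multiplicative components per clone-interval:

* **strategy weights** ``W_x(k)`` — nonstabilized inverse-probability-of-
  censoring weights with a uniform-over-grace numerator. Writing
  ``p_A(j) = P(no switch in j | history)``, an uncensored clone accumulates,
  per interval ``j <= k``:

  - before eligibility: ``1 / p_A(j)``;
  - grace interval with offset ``r`` and no switch:
    ``(1 - 1/(m+1-r)) / p_A(Q+r)``;
  - grace interval with the switch: ``(1/(m+1-r)) / (1 - p_A(Q+r))``;
  - after the switch (or after the grace period): 1;

  and ``W_x(k) = 0`` whenever the clone is artificially censored
  (``C_x(k) = 1``). The numerators 1/(m+1), ..., 1/1 spread the forced
  switch uniformly over the m+1 grace intervals; at the last grace interval
  the no-switch numerator is 0, matching censoring of never-switchers.

* **substudy weights** — structured-treatment-interruption participants are
  censored (weight 0) from substudy entry; continuous-therapy participants
  are upweighted by (n_STI + n_CT) / n_CT within center x arm stratum
  (approximately 2 under 1:1 allocation).

* **LTFU weights** — cumulative product of 1 / P(remaining in follow-up),
  from a pooled logistic dropout model.

The combined product is truncated at 10 (raw product retained).
Strategy weights are always computed from switch probabilities fitted on
the complete measurement record — monitoring-frequency regimes only filter
what the *regime* observes, never what the weight models see.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

POSITIVITY_FLOOR = 1e-6
DEFAULT_TRUNCATION = 10.0


class PositivityError(RuntimeError):
    """A required denominator fell below the positivity floor."""


class WeightAlignmentError(ValueError):
    """Weight series indexed by different clone-intervals."""


class StrategyWeightPlan:
    """Resample-invariant structure of the strategy-weight computation.

    Eligibility, grace offsets and censoring are functions of each person's
    data alone, so they are precomputed once; only the switch probabilities
    change between (bootstrap) model fits. ``evaluate`` turns a vector of
    per-clone-row switch probabilities into ``W_x(k)``.
    """

    def __init__(self, clones: pd.DataFrame, grace_m: int):
        self.grace_m = grace_m
        k = clones["k"].to_numpy()
        Q = clones["Q_x"].to_numpy(dtype=float)
        r = clones["r"].to_numpy(dtype=float)
        on_first = clones["on_first_line"].to_numpy(dtype=bool)
        sw = clones["switch"].to_numpy(dtype=bool)
        self.C = clones["C"].to_numpy(dtype=bool)
        pre = on_first & (np.isnan(Q) | (k < Q))
        grace = on_first & ~np.isnan(r)
        self.pre_ns = pre & ~sw
        self.g_ns = grace & ~sw
        self.g_sw = grace & sw
        self.r = r
        # person segments (clone tables are sorted by strategy, pid, k)
        seg = (
            clones["strategy_id"].astype(str) + "\x00" + clones["pid"].astype(str)
        )
        self.seg_codes = pd.factorize(seg, sort=False)[0]
        self._detail = clones[["pid", "strategy_id", "k"]]

    def factors(self, p_switch: np.ndarray, active: np.ndarray | None = None) -> np.ndarray:
        """Per-row factors; ``active`` masks rows of persons present in the
        (re)sample — positivity is enforced, and factors computed, only
        there (inactive rows carry no weight anywhere downstream)."""
        p_sw = np.asarray(p_switch, dtype=float)
        p_A = 1.0 - p_sw
        need_pA = (self.pre_ns | self.g_ns) & ~self.C
        bad = need_pA & (p_A < POSITIVITY_FLOOR)
        bad |= self.g_sw & ~self.C & (p_sw < POSITIVITY_FLOOR)
        if active is not None:
            bad &= active
        if bad.any():
            detail = self._detail.loc[bad].head(20)
            log.error(
                "positivity violation: %d clone-intervals with denominator < %g\n%s",
                int(bad.sum()), POSITIVITY_FLOOR, detail.to_string(index=False),
            )
            raise PositivityError(
                f"{int(bad.sum())} clone-intervals with switch-model denominator "
                f"below {POSITIVITY_FLOOR}"
            )
        factor = np.ones(len(p_sw))
        m = self.grace_m
        with np.errstate(divide="ignore", invalid="ignore"):
            factor[self.pre_ns] = 1.0 / p_A[self.pre_ns]
            factor[self.g_ns] = (1.0 - 1.0 / (m + 1 - self.r[self.g_ns])) / p_A[self.g_ns]
            factor[self.g_sw] = (1.0 / (m + 1 - self.r[self.g_sw])) / p_sw[self.g_sw]
        # censored rows contribute weight 0 regardless of their factor
        factor[self.C] = 1.0
        if active is not None:
            factor[~active] = 1.0
        return factor

    def evaluate(
        self, p_switch: np.ndarray, active: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (per-row factor, cumulative W_x(k)) for given switch probs."""
        factor = self.factors(p_switch, active=active)
        cum = pd.Series(factor).groupby(self.seg_codes, sort=False).cumprod()
        return factor, cum.to_numpy() * (~self.C)


def compute_strategy_weights(clones: pd.DataFrame, grace_m: int) -> pd.DataFrame:
    """Nonstabilized strategy weights ``W_x(k)`` per clone-interval.

    Requires a ``p_switch`` column on ``clones`` (merge the fitted switch
    probabilities onto the clone table first). Returns ``clones`` with
    ``w_factor`` and ``w_strategy`` columns added. Raises
    :class:`PositivityError` when a required denominator is below
    ``POSITIVITY_FLOOR``.
    """
    plan = StrategyWeightPlan(clones, grace_m)
    factor, w = plan.evaluate(clones["p_switch"].to_numpy(dtype=float))
    out = clones.copy()
    out["w_factor"] = factor
    out["w_strategy"] = w
    return out


def substudy_weights(
    cohort: pd.DataFrame,
    entry_interval: int,
    person_multiplicity: pd.Series | None = None,
) -> pd.Series:
    """Per person-interval substudy weight.

    STI person-intervals from substudy entry carry weight 0 (censoring);
    continuous-therapy person-intervals carry the stratum upweight
    ``(n_STI + n_CT) / n_CT``; everything else carries 1.
    ``person_multiplicity`` (pid -> count) reweights the stratum counts for
    bootstrap resamples.
    """
    w = pd.Series(1.0, index=cohort.index, name="w_substudy")
    if "substudy" not in cohort or (cohort["substudy"] == "none").all():
        return w
    persons = cohort.drop_duplicates("pid")[["pid", "substudy", "substudy_stratum"]]
    if person_multiplicity is None:
        persons = persons.assign(mult=1)
    else:
        persons = persons.assign(mult=persons["pid"].map(person_multiplicity).fillna(0))
    counts = (
        persons[persons["substudy"] != "none"]
        .groupby(["substudy_stratum", "substudy"])["mult"]
        .sum()
        .unstack(fill_value=0)
    )
    ct_w = {}
    for st, row in counts.iterrows():
        n_sti = int(row.get("sti", 0))
        n_ct = int(row.get("ct", 0))
        if n_ct == 0:
            if n_sti > 0:
                log.error("substudy stratum %s has STI but no continuous arm", st)
                raise PositivityError(
                    f"substudy stratum {st}: no continuous-therapy person to upweight"
                )
            continue
        ct_w[st] = (n_sti + n_ct) / n_ct
    after = cohort["k"] >= entry_interval
    sti = (cohort["substudy"] == "sti") & after
    ct = (cohort["substudy"] == "ct") & after
    w[sti] = 0.0
    w[ct] = cohort.loc[ct, "substudy_stratum"].map(ct_w).fillna(1.0)
    return w


def ltfu_weight_series(cohort: pd.DataFrame, p_ltfu: pd.Series) -> pd.Series:
    """Cumulative inverse-probability-of-remaining weights per person-interval."""
    p = np.asarray(p_ltfu, dtype=float)
    retain = 1.0 - p
    if (retain < POSITIVITY_FLOOR).any():
        n_bad = int((retain < POSITIVITY_FLOOR).sum())
        log.error("LTFU model: %d person-intervals with retention < %g", n_bad, POSITIVITY_FLOOR)
        raise PositivityError("retention probability below positivity floor")
    inv = pd.Series(1.0 / retain, index=cohort.index)
    return inv.groupby(cohort["pid"], sort=False).cumprod().rename("w_ltfu")


def combine_truncate(
    w_strategy: pd.Series,
    w_substudy: pd.Series,
    w_ltfu: pd.Series,
    cap: float = DEFAULT_TRUNCATION,
) -> pd.DataFrame:
    """Elementwise product of the three components, truncated at ``cap``.

    The raw product is kept alongside for sensitivity analyses with
    untruncated weights (``cap=np.inf`` makes them identical).
    """
    for other in (w_substudy, w_ltfu):
        if len(other) != len(w_strategy) or not w_strategy.index.equals(other.index):
            raise WeightAlignmentError("weight series are not aligned")
    raw = w_strategy * w_substudy * w_ltfu
    return pd.DataFrame({"w_raw": raw, "w": np.minimum(raw, cap)})


def weight_summary(w: pd.Series, cap: float = DEFAULT_TRUNCATION) -> dict:
    w = np.asarray(w, dtype=float)
    pos = w[w > 0]
    return {
        "n": int(w.size),
        "n_positive": int(pos.size),
        "mean": float(pos.mean()) if pos.size else 0.0,
        "p99": float(np.percentile(pos, 99)) if pos.size else 0.0,
        "max": float(pos.max()) if pos.size else 0.0,
        "frac_truncated": float((pos >= cap).mean()) if pos.size else 0.0,
    }
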