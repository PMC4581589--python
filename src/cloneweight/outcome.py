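"""Weighted pooled logistic mortality models on the expanded clone data.

The probability of death in interval ``k + 1`` is modeled among
clone-intervals that reach the end of ``k`` alive, artificially uncensored,
and still under follow-up at ``k + 1``, weighted by the truncated
inverse-probability weight accumulated through ``k``:

    logit P(death in k+1) = s(k) + encoding(X) + encoding(X) * k_m

where ``s(k)`` is a restricted cubic spline in the interval index and
``k_m`` indicates intervals beginning more than 96 weeks after baseline.
Two strategy encodings are supported: ``"hg"`` (CD4-threshold strategies
enter linearly through the threshold ``h``, event-only strategies through
dummies ``g``) and ``"f"`` (a categorical monitoring-frequency label per
strategy). Predicted hazards multiply into survival curves
``S(K) = prod_{k<K} (1 - hazard(k))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineSpec, percentile_knots, rcs_basis
from .switch_model import ModelFitError, PooledLogisticFit, fit_pooled_logistic

log = logging.getLogger(__name__)

K_M_FIRST_LATE_INTERVAL = 25  # first interval starting strictly after week 96


class ExtrapolationError(ValueError):
    """Survival requested beyond the fitted interval range."""


def late_period(k) -> np.ndarray:
    """k_m indicator: 1 when interval k begins more than 96 weeks (672 days)
    after baseline, i.e. k >= 25."""
    return (np.asarray(k) >= K_M_FIRST_LATE_INTERVAL).astype(float)


@dataclass
class SurvivalCurve:
    strategy_id: str
    survival: np.ndarray  # S(0..horizon), S(0) = 1
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    n_boot: int = 0


@dataclass
class OutcomeFit:
    fit: PooledLogisticFit
    mode: str
    encoding: pd.DataFrame  # per-strategy base encoding columns
    k_knots: tuple | None
    max_k: int


def prepare_outcome_rows(clones: pd.DataFrame, outcome: str = "death") -> pd.DataFrame:
    """Attach the discrete-time outcome to clone rows.

    A clone row at interval ``k`` enters the risk set for the event in
    ``k + 1`` when the person has an interval-``k+1`` row (so survived
    ``k``), the clone is artificially uncensored at ``k`` and its weight is
    positive. For the default ``outcome="death"``, intervals lost to
    follow-up are censoring (the ``k+1`` LTFU row leaves the risk set);
    for the ``"death_or_ltfu"`` sensitivity outcome, loss to follow-up is
    an event. Adds columns ``y`` and ``at_risk``.
    """
    if outcome not in ("death", "death_or_ltfu"):
        raise ValueError(f"unknown outcome {outcome!r}")
    df = clones
    grp = [df["strategy_id"], df["pid"]] if "strategy_id" in df else [df["pid"]]
    nxt_k = df["k"].groupby(grp, sort=False).shift(-1)
    nxt_death = df["death"].groupby(grp, sort=False).shift(-1, fill_value=False)
    nxt_ltfu = df["ltfu"].groupby(grp, sort=False).shift(-1, fill_value=True)
    out = df.copy()
    if outcome == "death":
        out["y"] = nxt_death.astype(bool).astype(float)
        at_risk = nxt_k.notna() & ~nxt_ltfu.astype(bool)
    else:
        out["y"] = (
            nxt_death.astype(bool) | (nxt_k.notna() & nxt_ltfu.astype(bool))
        ).astype(float)
        at_risk = nxt_k.notna()
    if "C" in out:
        at_risk &= ~out["C"]
    out["at_risk"] = at_risk
    return out


def encoding_frame(strategies, mode: str) -> pd.DataFrame:
    """Base (non-interacted) encoding columns per strategy.

    ``"hg"``: column ``h`` holds the CD4 threshold in cells/mm^3 (0 for
    event-only strategies) and each event-only strategy gets a ``g_<id>``
    dummy. ``"f"``: each strategy after the first gets an ``f_<id>`` dummy
    (the first strategy is the reference level).
    """
    strategies = list(strategies)
    ids = [s.strategy_id for s in strategies]
    if mode == "hg":
        enc = pd.DataFrame(index=pd.Index(ids, name="strategy_id"))
        enc["h"] = [s.cd4_threshold or 0.0 for s in strategies]
        for s in strategies:
            if s.cd4_threshold is None:
                enc[f"g_{s.strategy_id}"] = [
                    1.0 if t.strategy_id == s.strategy_id else 0.0 for t in strategies
                ]
    elif mode == "f":
        enc = pd.DataFrame(index=pd.Index(ids, name="strategy_id"))
        for s in strategies[1:]:
            enc[f"f_{s.strategy_id}"] = [
                1.0 if t.strategy_id == s.strategy_id else 0.0 for t in strategies
            ]
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")
    return enc


def _design(k: np.ndarray, enc_rows: pd.DataFrame, k_spec: SplineSpec | None) -> pd.DataFrame:
    X = pd.DataFrame(index=enc_rows.index)
    X["const"] = 1.0
    if k_spec is not None:
        for name, col in zip(k_spec.column_names, rcs_basis(k, k_spec).T):
            X[name] = col
    else:
        X["interval"] = k
    km = late_period(k)
    for col in enc_rows.columns:
        X[col] = enc_rows[col].to_numpy()
        X[f"{col}_km"] = enc_rows[col].to_numpy() * km
    return X


def fit_outcome_model(
    clones_weighted: pd.DataFrame,
    strategies,
    mode: str = "hg",
    k_knots: tuple | None = None,
) -> OutcomeFit:
    """Fit the weighted pooled logistic mortality model.

    ``clones_weighted`` must carry columns ``y``, ``at_risk`` (from
    :func:`prepare_outcome_rows`) and the combined truncated weight ``w``.
    """
    df = clones_weighted
    rows = df["at_risk"] & (df["w"] > 0)
    n_zero_w = int((df["at_risk"] & (df["w"] <= 0)).sum())
    if n_zero_w:
        log.info("outcome model: %d at-risk rows excluded for non-positive weight", n_zero_w)
    sub = df.loc[rows]
    if sub["y"].sum() == 0:
        raise ModelFitError("no deaths among at-risk clone-intervals")

    k = sub["k"].to_numpy(dtype=float)
    if k_knots is None:
        k_knots = percentile_knots(k)
    k_spec = SplineSpec(tuple(k_knots), "interval") if k_knots is not None else None

    enc = encoding_frame(strategies, mode)
    enc_rows = enc.reindex(sub["strategy_id"]).set_index(sub.index)
    X = _design(k, enc_rows, k_spec)
    dropped = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    # a constant encoding column is no strategy contrast; its k_m
    # interaction would act as a spurious pure-time effect — drop both
    dropped += [
        f"{c}_km" for c in enc.columns if c in dropped and f"{c}_km" in X.columns
    ]
    if dropped:
        log.info("outcome model: dropping constant columns %s", dropped)
        X = X.drop(columns=dropped)
    fit = fit_pooled_logistic(
        X, sub["y"], weights=sub["w"].to_numpy(dtype=float), model="outcome",
        k_knots=k_knots,
    )
    return OutcomeFit(
        fit=fit, mode=mode, encoding=enc, k_knots=k_knots, max_k=int(k.max())
    )


def predict_survival_curve(
    ofit: OutcomeFit, strategy_id: str, horizon: int
) -> SurvivalCurve:
    """Counterfactual survival S(0..horizon) for one fitted strategy."""
    if horizon - 1 > ofit.max_k:
        raise ExtrapolationError(
            f"horizon {horizon} exceeds fitted interval range (max k = {ofit.max_k})"
        )
    if strategy_id not in ofit.encoding.index:
        raise KeyError(f"strategy {strategy_id!r} was not in the fitted encoding")
    k = np.arange(horizon, dtype=float)
    enc_rows = pd.DataFrame(
        np.repeat(ofit.encoding.loc[[strategy_id]].to_numpy(), horizon, axis=0),
        columns=ofit.encoding.columns,
    )
    k_spec = SplineSpec(tuple(ofit.k_knots), "interval") if ofit.k_knots else None
    X = _design(k, enc_rows, k_spec)
    hazard = ofit.fit.predict(X)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - hazard)])
    return SurvivalCurve(strategy_id=strategy_id, survival=surv)


def pooled_logistic_survival(cohort: pd.DataFrame, horizon: int) -> np.ndarray:
    """Unweighted discrete-time survival estimate on the source cohort.

    Spline-only pooled logistic model of death in ``k + 1`` — the reduction
    of the clone-censor-weight estimator when no cloning, censoring or
    weighting occurs.
    """
    rows = prepare_outcome_rows(cohort)
    sub = rows.loc[rows["at_risk"]]
    k = sub["k"].to_numpy(dtype=float)
    k_knots = percentile_knots(k)
    k_spec = SplineSpec(tuple(k_knots), "interval") if k_knots is not None else None
    X = _design(k, pd.DataFrame(index=sub.index), k_spec)
    fit = fit_pooled_logistic(X, sub["y"], model="outcome", k_knots=k_knots)
    if horizon - 1 > k.max():
        raise ExtrapolationError("horizon beyond observed intervals")
    kk = np.arange(horizon, dtype=float)
    Xp = _design(kk, pd.DataFrame(index=pd.RangeIndex(horizon)), k_spec)
    hazard = fit.predict(Xp)
    return np.concatenate([[1.0], np.cumprod(1.0 - hazard)])


def survival_contrast(
    boot_a: np.ndarray, boot_b: np.ndarray, point_a: float, point_b: float
) -> dict:
    """Difference in survival with a percentile CI from paired replicates.

    ``boot_a``/``boot_b`` are per-replicate survival values at the chosen
    horizon (same replicates, same order).
    """
    boot_a = np.asarray(boot_a, dtype=float)
    boot_b = np.asarray(boot_b, dtype=float)
    if boot_a.shape != boot_b.shape:
        raise ValueError("bootstrap replicate counts differ between curves")
    diff = boot_a - boot_b
    est = point_a - point_b
    if diff.size:
        lo, hi = np.percentile(diff, [2.5, 97.5])
    else:
        lo = hi = est
    return {"difference": est, "ci_lower": float(lo), "ci_upper": float(hi)}
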