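"""Design matrices for the pooled logistic switch and retention models.

One builder serves both models: the switch model (probability of switching
to second-line ART in interval k, among person-intervals alive and still on
first-line ART) and the loss-to-follow-up model (same covariates plus a
prior-switch indicator, among all person-intervals in follow-up).

Covariates follow standard confounder-adjustment practice for this setting:
baseline factors (center x regimen, CD4 category, low BMI, low hemoglobin,
early WHO 4 history), and time-dependent factors (current CD4 as a
restricted cubic spline with knots at 15/50/100/200 under last observation
carried forward, low BMI / hemoglobin, recent cotrimoxazole while within
72 weeks of ART start, missed visits and doses, 5-category WHO 3/4 and
tuberculosis event histories with the highest level dominant, and a recent
WHO 4 x CD4<100 interaction). Event histories count only events occurring
with carried-forward CD4 below 250; events in the current interval count
only when they preceded the switch. Randomized arm is never included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SplineSpec, percentile_knots, rcs_basis

log = logging.getLogger(__name__)

CD4_SPLINE_KNOTS = (15.0, 50.0, 100.0, 200.0)
COTRIM_LAST_INTERVAL = 6  # 72 weeks on ART = 24 weeks after baseline
RECENT_LAGS = (0, 1, 2)  # interval k-2 .. k
DISTAL_LAGS = (3, 4, 5)  # interval k-5 .. k-3
EVENT_CD4_RESTRICTION = 250.0


class DesignError(ValueError):
    """Raised when required inputs for the design matrix are missing."""


@dataclass
class DesignMatrix:
    X: pd.DataFrame  # includes "const"; aligned to risk-set rows of cohort
    y: pd.Series
    k_knots: tuple | None
    dropped: list


def _lagged_any(flag: pd.Series, pid: pd.Series, lags) -> np.ndarray:
    g = flag.groupby(pid, sort=False)
    out = np.zeros(len(flag), dtype=bool)
    for lag in lags:
        out |= g.shift(lag, fill_value=False).to_numpy(dtype=bool)
    return out


def _history_dummies(
    df: pd.DataFrame, pid: pd.Series, stage3_cols, stage4_cols, prefix: str,
    cd4_locf: np.ndarray, switch_day: np.ndarray,
) -> pd.DataFrame:
    """5-category dominant event history as 4 dummies (reference: none).

    ``*_cols`` are event-day columns; an event qualifies when the
    carried-forward CD4 at its interval is below 250. Current-interval
    events qualify only when strictly before a same-interval switch.
    """
    qual = cd4_locf < EVENT_CD4_RESTRICTION

    def occurred(cols) -> pd.Series:
        any_evt = np.zeros(len(df), dtype=bool)
        for c in cols:
            any_evt |= df[c].notna().to_numpy()
        return pd.Series(any_evt & qual, index=df.index)

    def occurred_pre_switch(cols) -> np.ndarray:
        any_evt = np.zeros(len(df), dtype=bool)
        for c in cols:
            day = df[c].to_numpy()
            any_evt |= ~np.isnan(day) & (np.isnan(switch_day) | (day < switch_day))
        return any_evt & qual

    s3, s4 = occurred(stage3_cols), occurred(stage4_cols)
    s3_rec = occurred_pre_switch(stage3_cols) | _lagged_any(s3, pid, (1, 2))
    s4_rec = occurred_pre_switch(stage4_cols) | _lagged_any(s4, pid, (1, 2))
    s3_dis = _lagged_any(s3, pid, DISTAL_LAGS)
    s4_dis = _lagged_any(s4, pid, DISTAL_LAGS)

    out = pd.DataFrame(index=df.index)
    out[f"{prefix}_who4_recent"] = s4_rec
    out[f"{prefix}_who4_distal"] = s4_dis & ~s4_rec
    out[f"{prefix}_who3_recent"] = s3_rec & ~s4_rec & ~s4_dis
    out[f"{prefix}_who3_distal"] = s3_dis & ~s3_rec & ~s4_rec & ~s4_dis
    return out.astype(float)


def locf_cd4(cohort: pd.DataFrame) -> pd.Series:
    """Observed CD4 carried forward (all measurements, any schedule)."""
    out = cohort["cd4_obs"].groupby(cohort["pid"], sort=False).ffill()
    if out.isna().any():
        raise DesignError("person-intervals with no CD4 ever measured")
    return out


def build_design(
    cohort: pd.DataFrame,
    *,
    model: str = "switch",
    k_knots: tuple | None = None,
    drop_constant: bool = True,
) -> DesignMatrix:
    """Design matrix and outcome for the switch or LTFU pooled logistic model.

    ``model="switch"``: risk set is person-intervals on first-line ART;
    outcome is switching during the interval. ``model="ltfu"``: risk set is
    all person-intervals in follow-up; outcome is loss to follow-up during
    the interval, with a prior-switch indicator added.
    """
    if model not in ("switch", "ltfu"):
        raise ValueError(f"unknown model {model!r}")
    df = cohort
    pid = df["pid"]
    cd4 = locf_cd4(df).to_numpy()
    switch_day = df["switch_day"].to_numpy()

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0

    # baseline covariates
    for col, series in (
        ("center_regimen", df["center_regimen"]),
        ("base_cd4_cat", df["base_cd4_cat"]),
    ):
        dummies = pd.get_dummies(series, prefix=col, dtype=float)
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    X["base_bmi_low"] = df["base_bmi_low"].astype(float)
    X["base_hb_low"] = df["base_hb_low"].astype(float)
    X["base_who4_24_48"] = df["base_who4_24_48"].astype(float)

    # time-dependent covariates
    cd4_spec = SplineSpec(CD4_SPLINE_KNOTS, "cd4")
    cd4_basis = rcs_basis(cd4, cd4_spec)
    for name, col in zip(cd4_spec.column_names, cd4_basis.T):
        X[name] = col
    X["bmi_low"] = df["bmi_low"].astype(float)
    X["hb_low"] = df["hb_low"].astype(float)
    cotrim_prev = (
        df["cotrim"].groupby(pid, sort=False).shift(1, fill_value=False).to_numpy(dtype=bool)
    )
    X["cotrim_prev_early"] = (cotrim_prev & (df["k"].to_numpy() <= COTRIM_LAST_INTERVAL)).astype(float)
    X["missed_visits"] = df["missed_visits"].astype(float)
    X["missed_doses"] = df["missed_doses"].astype(float)

    who_hist = _history_dummies(
        df, pid, ["who3_day", "esoph_candida_day"], ["who4_day"], "hist",
        cd4, switch_day,
    )
    tb_hist = _history_dummies(
        df, pid, ["tb_pulm_day"], ["tb_extra_day"], "tb",
        cd4, switch_day,
    )
    X = pd.concat([X, who_hist, tb_hist], axis=1)
    X["who4_recent_lowcd4"] = who_hist["hist_who4_recent"] * (cd4 < 100.0)

    if model == "ltfu":
        X["prior_switch"] = (~df["on_first_line"]).astype(float)
        risk = pd.Series(True, index=df.index)
        y = df["ltfu"].astype(float)
    else:
        risk = df["on_first_line"]
        y = df["switch"].astype(float)

    X = X.loc[risk]
    y = y.loc[risk]

    # interval-specific intercept: restricted cubic spline in k
    k_risk = df.loc[risk, "k"].to_numpy(dtype=float)
    if k_knots is None:
        k_knots = percentile_knots(k_risk)
    if k_knots is not None:
        k_spec = SplineSpec(tuple(k_knots), "interval")
        for name, col in zip(k_spec.column_names, rcs_basis(k_risk, k_spec).T):
            X[name] = col
    else:
        log.warning("degenerate interval distribution; linear interval term only")
        X["interval"] = k_risk

    dropped = []
    if drop_constant:
        dropped = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
        if dropped:
            log.warning("dropping zero-variance design columns: %s", dropped)
            X = X.drop(columns=dropped)
    return DesignMatrix(X=X, y=y, k_knots=k_knots, dropped=dropped)
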