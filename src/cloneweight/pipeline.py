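"""End-to-end clone-censor-weight estimation pipeline.

simulate/load -> fit switch + LTFU models -> expand clones -> weights ->
weighted outcome model -> survival curves -> nonparametric bootstrap.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import outcome as oc
from . import strategies as st
from . import switch_model as swm
from . import synthetic as syn
from . import weights as wt

log = logging.getLogger(__name__)


@dataclass
class EstimateResult:
    curves: dict  # strategy_id -> SurvivalCurve
    clones: pd.DataFrame | None
    outcome_fit: oc.OutcomeFit | None
    switch_fit: swm.PooledLogisticFit | None
    ltfu_fit: swm.PooledLogisticFit | None
    strategy_stats: pd.DataFrame | None
    weight_stats: dict = field(default_factory=dict)


def attach_person_interval_weights(
    cohort: pd.DataFrame,
    substudy_entry_interval: int = 1,
    use_ltfu_weights: bool = True,
) -> tuple[pd.DataFrame, swm.PooledLogisticFit | None, swm.PooledLogisticFit | None]:
    """Fit switch and LTFU models on the source cohort and attach
    ``p_switch``, ``w_ltfu`` and ``w_substudy`` columns.

    The switch model sees the complete CD4 measurement record; a cohort
    with zero switches gets ``p_switch = 0`` exactly (the model itself is
    undefined there, but every weight denominator is 1).
    ``use_ltfu_weights=False`` skips the dropout model (used when loss to
    follow-up is part of the outcome rather than censoring).
    """
    from .design import build_design

    df = cohort.sort_values(["pid", "k"], kind="mergesort").reset_index(drop=True)
    if int(df["switch"].sum()) > 0:
        dm = build_design(df, model="switch")
        switch_fit = swm.fit_pooled_logistic(dm.X, dm.y, model="switch", k_knots=dm.k_knots)
        p_sw = pd.Series(np.nan, index=df.index)
        p_sw[dm.X.index] = switch_fit.predict(dm.X)
        df["p_switch"] = p_sw
    else:
        switch_fit = None
        df["p_switch"] = pd.Series(
            np.where(df["on_first_line"], 0.0, np.nan), index=df.index
        )
    if use_ltfu_weights and int(df["ltfu"].sum()) > 0:
        dml = build_design(df, model="ltfu")
        ltfu_fit = swm.fit_pooled_logistic(dml.X, dml.y, model="ltfu", k_knots=dml.k_knots)
        p_ltfu = pd.Series(ltfu_fit.predict(dml.X), index=df.index)
        df["w_ltfu"] = wt.ltfu_weight_series(df, p_ltfu)
    else:
        ltfu_fit = None
        df["w_ltfu"] = 1.0
    df["w_substudy"] = wt.substudy_weights(df, substudy_entry_interval)
    return df, switch_fit, ltfu_fit


def weighted_clones(
    cohort_w: pd.DataFrame,
    strategies,
    cap: float = wt.DEFAULT_TRUNCATION,
) -> pd.DataFrame:
    """Expand clones and attach strategy / combined / truncated weights."""
    parts = []
    for strat in strategies:
        clones = st.expand_clones(cohort_w, [strat])
        clones = wt.compute_strategy_weights(clones, strat.grace_m)
        parts.append(clones)
    clones = pd.concat(parts, ignore_index=True)
    combined = wt.combine_truncate(
        clones["w_strategy"], clones["w_substudy"], clones["w_ltfu"], cap=cap
    )
    clones["w_raw"] = combined["w_raw"]
    clones["w"] = combined["w"]
    return clones


def estimate_survival(
    cohort: pd.DataFrame,
    strategies,
    mode: str = "hg",
    horizon: int = 60,
    cap: float = wt.DEFAULT_TRUNCATION,
    substudy_entry_interval: int = 1,
    keep_clones: bool = True,
    outcome: str = "death",
) -> EstimateResult:
    """Point estimates of counterfactual survival for each strategy.

    ``outcome="death_or_ltfu"`` is the sensitivity analysis with loss to
    follow-up counted as an event (LTFU weights then drop out).
    """
    strategies = list(strategies)
    cohort_w, switch_fit, ltfu_fit = attach_person_interval_weights(
        cohort, substudy_entry_interval, use_ltfu_weights=(outcome == "death")
    )
    clones = weighted_clones(cohort_w, strategies, cap=cap)
    clones = oc.prepare_outcome_rows(clones, outcome=outcome)
    ofit = oc.fit_outcome_model(clones, strategies, mode=mode)
    curves = {
        s.strategy_id: oc.predict_survival_curve(ofit, s.strategy_id, horizon)
        for s in strategies
    }
    stats = strategy_compliance_stats(clones, strategies)
    wstats = wt.weight_summary(clones.loc[clones["at_risk"], "w"], cap=cap)
    return EstimateResult(
        curves=curves,
        clones=clones if keep_clones else None,
        outcome_fit=ofit,
        switch_fit=switch_fit,
        ltfu_fit=ltfu_fit,
        strategy_stats=stats,
        weight_stats=wstats,
    )


def strategy_compliance_stats(clones: pd.DataFrame, strategies) -> pd.DataFrame:
    """Per-strategy eligibility/compliance/death counts (substudy-weighted
    deaths among clone-intervals compatible with the strategy)."""
    recs = []
    for strat in strategies:
        sub = clones[clones["strategy_id"] == strat.strategy_id]
        per = sub.drop_duplicates("pid")
        eligible = per["Q_x"].notna()
        first_switch = (
            sub.loc[sub["switch"], ["pid", "k"]].groupby("pid")["k"].min()
        )
        fs = per["pid"].map(first_switch)
        in_grace = (
            eligible.to_numpy()
            & (fs.to_numpy() >= per["Q_x"].to_numpy())
            & (fs.to_numpy() <= per["Q_x"].to_numpy() + strat.grace_m)
        )
        deaths = float(
            (sub["death"] & ~sub["C"]).astype(float).mul(sub["w_substudy"]).sum()
        )
        n_elig = int(eligible.sum())
        recs.append(
            {
                "strategy_id": strat.strategy_id,
                "n_persons": len(per),
                "n_eligible": n_elig,
                "n_switched_in_grace": int(np.nansum(in_grace)),
                "pct_switched_in_grace": (
                    100.0 * np.nansum(in_grace) / n_elig if n_elig else np.nan
                ),
                "n_artificially_censored": int(per["censored_from"].notna().sum()),
                "weighted_deaths_compatible": deaths,
            }
        )
    return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# bootstrap


def resample_cohort(cohort: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample individuals with replacement (ignoring randomized arm),
    relabeling person ids so each draw is a distinct person."""
    codes, uniques = pd.factorize(cohort["pid"], sort=True)
    order = np.argsort(codes, kind="stable")
    sorted_rows = np.arange(len(cohort))[order]
    counts = np.bincount(codes, minlength=len(uniques))
    starts = np.concatenate([[0], np.cumsum(counts)])
    draw = rng.integers(0, len(uniques), len(uniques))
    sel = np.concatenate([sorted_rows[starts[c]: starts[c + 1]] for c in draw])
    new_pid = np.repeat(np.arange(len(draw)), counts[draw])
    boot = cohort.iloc[sel].copy()
    boot["pid"] = new_pid
    return boot.reset_index(drop=True)


def bootstrap_cis(
    cohort: pd.DataFrame,
    strategies,
    mode: str = "hg",
    horizon: int = 60,
    B: int = 500,
    seed: int = 0,
    cap: float = wt.DEFAULT_TRUNCATION,
    substudy_entry_interval: int = 1,
    outcome: str = "death",
) -> dict:
    """Nonparametric bootstrap over individuals.

    Every replicate re-estimates everything: switch model, LTFU model,
    substudy stratum weights, strategy weights, and the outcome model.
    Resampling persons with replacement is carried out through person
    frequency weights — a resample in which person i appears m_i times
    yields exactly the same likelihoods as fitting m_i duplicated copies —
    which lets the design matrices, eligibility states and censoring times
    (all resample-invariant) be computed once. Spline knots are held at the
    point-estimate values across replicates (fixed basis, re-estimated
    coefficients).

    Returns the point curves with percentile 2.5/97.5 bands attached, the
    per-replicate survival arrays, and the count of failed replicates.
    """
    if B < 1:
        raise ValueError("B must be >= 1 (use estimate_survival for B = 0)")
    from .design import build_design
    from .splines import SplineSpec

    strategies = list(strategies)
    df = cohort.sort_values(["pid", "k"], kind="mergesort").reset_index(drop=True)
    point = estimate_survival(
        df, strategies, mode=mode, horizon=horizon, cap=cap,
        substudy_entry_interval=substudy_entry_interval, keep_clones=True,
        outcome=outcome,
    )
    clones = point.clones
    ofit = point.outcome_fit

    codes_df, uniq_pids = pd.factorize(df["pid"], sort=True)
    n_persons = len(uniq_pids)

    # fixed design matrices (knots from the point estimate)
    if point.switch_fit is not None:
        dm_sw = build_design(df, model="switch", k_knots=point.switch_fit.k_knots)
        X_sw = dm_sw.X[point.switch_fit.columns]
        y_sw = dm_sw.y
        sw_pos = dm_sw.X.index.to_numpy()
    if point.ltfu_fit is not None:
        dm_lt = build_design(df, model="ltfu", k_knots=point.ltfu_fit.k_knots)
        X_lt = dm_lt.X[point.ltfu_fit.columns]
        y_lt = dm_lt.y

    # per-strategy weight plans on the fixed clone table
    blocks = []
    for strat in strategies:
        mask = (clones["strategy_id"] == strat.strategy_id).to_numpy()
        pos = np.flatnonzero(mask)
        blocks.append(
            (pos, clones.iloc[pos]["src_row"].to_numpy(),
             wt.StrategyWeightPlan(clones.iloc[pos], strat.grace_m))
        )

    # fixed outcome design on at-risk clone rows
    at_risk_pos = np.flatnonzero(clones["at_risk"].to_numpy())
    sub = clones.iloc[at_risk_pos]
    enc_rows = ofit.encoding.reindex(sub["strategy_id"]).set_index(sub.index)
    k_spec = SplineSpec(tuple(ofit.k_knots), "interval") if ofit.k_knots else None
    X_out = oc._design(sub["k"].to_numpy(dtype=float), enc_rows, k_spec)[
        ofit.fit.columns
    ]
    y_out = sub["y"].to_numpy(dtype=float)
    sub_src = sub["src_row"].to_numpy()
    sub_codes = codes_df[sub_src]

    # fixed prediction designs
    kk = np.arange(horizon, dtype=float)
    X_pred = {}
    for strat in strategies:
        er = pd.DataFrame(
            np.repeat(ofit.encoding.loc[[strat.strategy_id]].to_numpy(), horizon, axis=0),
            columns=ofit.encoding.columns,
        )
        X_pred[strat.strategy_id] = (
            oc._design(kk, er, k_spec)[ofit.fit.columns].to_numpy(dtype=float)
        )

    has_substudy = "substudy" in df and (df["substudy"] != "none").any()
    rng = np.random.default_rng(seed)
    reps: dict[str, list] = {s.strategy_id: [] for s in strategies}
    n_failed = 0
    from scipy.special import expit

    for b in range(B):
        mult = np.bincount(
            rng.integers(0, n_persons, n_persons), minlength=n_persons
        ).astype(float)
        w_row = mult[codes_df]
        try:
            if point.switch_fit is not None:
                fit_sw = swm.fit_pooled_logistic(
                    X_sw, y_sw, weights=w_row[sw_pos], model="switch",
                    start=point.switch_fit.params.to_numpy(), tol=1e-8,
                )
                p_switch = np.full(len(df), np.nan)
                p_switch[sw_pos] = fit_sw.predict(X_sw)
            else:
                p_switch = np.where(df["on_first_line"].to_numpy(), 0.0, np.nan)
            if point.ltfu_fit is not None:
                fit_lt = swm.fit_pooled_logistic(
                    X_lt, y_lt, weights=w_row, model="ltfu",
                    start=point.ltfu_fit.params.to_numpy(), tol=1e-8,
                )
                retain = 1.0 - fit_lt.predict(X_lt)
                if (retain[w_row > 0] < wt.POSITIVITY_FLOOR).any():
                    raise wt.PositivityError("retention probability below floor")
                w_lt = (
                    pd.Series(1.0 / retain).groupby(codes_df, sort=False).cumprod().to_numpy()
                )
            else:
                w_lt = np.ones(len(df))
            if has_substudy:
                w_ss = wt.substudy_weights(
                    df, substudy_entry_interval,
                    person_multiplicity=pd.Series(mult, index=uniq_pids),
                ).to_numpy()
            else:
                w_ss = np.ones(len(df))

            w_clone = np.zeros(len(clones))
            for pos, src, plan in blocks:
                _, W = plan.evaluate(p_switch[src], active=w_row[src] > 0)
                w_clone[pos] = W * w_ss[src] * w_lt[src]
            np.minimum(w_clone, cap, out=w_clone)

            w_fit = w_clone[at_risk_pos] * mult[sub_codes]
            keep = w_fit > 0
            fit_out = swm.fit_pooled_logistic(
                X_out.iloc[keep], pd.Series(y_out[keep]), weights=w_fit[keep],
                model="outcome", start=ofit.fit.params.to_numpy(), tol=1e-8,
            )
            params = fit_out.params.to_numpy()
            for sid, Xp in X_pred.items():
                hazard = expit(Xp @ params)
                reps[sid].append(np.concatenate([[1.0], np.cumprod(1.0 - hazard)]))
        except (swm.ModelFitError, wt.PositivityError) as exc:
            n_failed += 1
            log.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
    boot_arrays = {sid: np.array(v) for sid, v in reps.items()}
    for sid, curve in point.curves.items():
        arr = boot_arrays[sid]
        if arr.size:
            curve.lower = np.percentile(arr, 2.5, axis=0)
            curve.upper = np.percentile(arr, 97.5, axis=0)
            curve.n_boot = arr.shape[0]
    point.clones = None
    return {"point": point, "replicates": boot_arrays, "n_failed": n_failed}


# ---------------------------------------------------------------------------
# config-driven run


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def strategy_from_dict(d: dict) -> st.Strategy:
    d = dict(d)
    if "event_triggers" in d:
        d["event_triggers"] = frozenset(d["event_triggers"])
    if isinstance(d.get("monitoring"), list):
        d["monitoring"] = tuple(d["monitoring"])
    return st.Strategy(**d)


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full workflow from a config mapping; write a report bundle.

    Config keys: ``cohort`` (``{"synthetic": {...}}`` or ``{"csv": path}``),
    ``strategies`` (list of strategy mappings), ``mode`` ("hg"/"f"),
    ``horizon``, ``truncation``, ``bootstrap`` (B; 0 = point estimates
    only), ``seed``, ``substudy_entry_interval``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    horizon = int(config.get("horizon", 60))
    cap = float(config.get("truncation", wt.DEFAULT_TRUNCATION))
    mode = config.get("mode", "hg")
    B = int(config.get("bootstrap", 0))
    entry = int(config.get("substudy_entry_interval", 1))
    outcome_def = config.get("outcome", "death")

    stage = "cohort"
    try:
        src = config["cohort"]
        if "synthetic" in src:
            sim = syn.SimulationConfig.from_dict(dict(src["synthetic"]))
            cohort = syn.generate_cohort(sim)
            syn.write_cohort_csv(cohort, outdir / "cohort.csv")
        else:
            cohort = syn.read_cohort_csv(src["csv"])
        stage = "strategies"
        strategies = [strategy_from_dict(d) for d in config["strategies"]]
        stage = "estimate"
        if B > 0:
            boot = bootstrap_cis(
                cohort, strategies, mode=mode, horizon=horizon, B=B, seed=seed,
                cap=cap, substudy_entry_interval=entry, outcome=outcome_def,
            )
            result, replicates, n_failed = boot["point"], boot["replicates"], boot["n_failed"]
        else:
            result = estimate_survival(
                cohort, strategies, mode=mode, horizon=horizon, cap=cap,
                substudy_entry_interval=entry, outcome=outcome_def,
            )
            replicates, n_failed = {}, 0
        stage = "report"
        rows = []
        for sid, curve in result.curves.items():
            for k, s in enumerate(curve.survival):
                rows.append(
                    {
                        "strategy_id": sid,
                        "interval": k,
                        "week": 4 * k,
                        "survival": s,
                        "ci_lower": None if curve.lower is None else curve.lower[k],
                        "ci_upper": None if curve.upper is None else curve.upper[k],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "survival_curves.csv", index=False)
        if result.clones is not None:
            result.clones[
                ["pid", "strategy_id", "k", "Q_x", "r", "C",
                 "w_strategy", "w_substudy", "w_ltfu", "w_raw", "w"]
            ].to_csv(outdir / "weights.csv", index=False)
        if result.switch_fit is not None:
            result.switch_fit.to_json(outdir / "switch_model.json")
        if result.strategy_stats is not None:
            result.strategy_stats.to_csv(outdir / "strategy_stats.csv", index=False)
        (outdir / "weights_summary.json").write_text(
            json.dumps(result.weight_stats, indent=2)
        )
        report = write_report(result, horizon)
        (outdir / "report.txt").write_text(report)
        run_log = {
            "seed": seed,
            "mode": mode,
            "horizon": horizon,
            "truncation": cap,
            "bootstrap": B,
            "bootstrap_failed": n_failed,
            "n_strategies": len(strategies),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": {k: v for k, v in config.items() if k != "cohort"}
            | {"cohort": {k: ("<inline>" if k == "synthetic" else v) for k, v in config["cohort"].items()}},
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return {"result": result, "replicates": replicates, "outdir": outdir}


def write_report(result: EstimateResult, horizon: int) -> str:
    """Human-readable per-strategy summary (compliance and survival)."""
    stats = result.strategy_stats
    header = (
        f"{'strategy':<24}{'eligible':>9}{'grace%':>8}{'censored':>9}"
        f"{'deaths':>8}{'S(' + str(4 * horizon) + 'wk)':>10}{'95% CI':>18}"
    )
    lines = [header, "-" * len(header)]
    if stats is None or stats.empty:
        return "\n".join(lines) + "\n"
    for _, row in stats.iterrows():
        sid = row["strategy_id"]
        curve = result.curves.get(sid)
        s_end = curve.survival[-1] if curve is not None else np.nan
        if curve is not None and curve.lower is not None:
            ci = f"({curve.lower[-1]:.3f}, {curve.upper[-1]:.3f})"
        else:
            ci = "--"
        lines.append(
            f"{sid:<24}{row['n_eligible']:>9d}"
            f"{row['pct_switched_in_grace']:>8.1f}"
            f"{row['n_artificially_censored']:>9d}"
            f"{row['weighted_deaths_compatible']:>8.1f}"
            f"{s_end:>10.3f}{ci:>18}"
        )
    return "\n".join(lines) + "\n"
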