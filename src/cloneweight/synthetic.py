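"""Synthetic person-period cohort generator with counterfactual ground truth.

Emulates a two-arm ART-monitoring trial cohort: adults who completed 48
weeks of first-line ART, followed in 4-week intervals, with CD4 counts
measured every 12 weeks. In the LCM arm (laboratory + clinical monitoring)
CD4 results are returned to clinicians, who tend to switch patients to
second-line ART after low counts; in the CDM arm (clinically driven
monitoring) CD4 results are withheld and switches follow clinical events
only. Latent CD4 evolves on the square-root scale; WHO stage 3/4 events,
death, and loss to follow-up have per-interval logistic hazards that
decrease with the current true CD4 count.

The same latent mechanism can be re-simulated under *forced* compliance
with a switching strategy (eligibility evaluated on the CD4 counts the
strategy would observe, switch interval drawn uniformly over the grace
period), giving Monte-Carlo ground truth for the counterfactual survival
curve that the clone-censor-weight estimator targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .strategies import Strategy

CD4_MEASUREMENT_PERIOD = 3  # intervals between CD4 measurements (12 weeks)
DAYS_PER_INTERVAL = 28

EVENT_TYPES = ("who3", "esoph_candida", "who4", "tb_pulm", "tb_extra")

_DAY_COLS = {e: f"{e}_day" for e in EVENT_TYPES}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class LogisticHazard:
    """Per-interval event probability expit(intercept - cd4_slope * cd4)."""

    intercept: float
    cd4_slope: float

    def prob(self, cd4: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept - self.cd4_slope * cd4)


def _default_event_hazards() -> dict:
    return {
        "who3": LogisticHazard(-3.8, 0.008),
        "esoph_candida": LogisticHazard(-5.5, 0.008),
        "who4": LogisticHazard(-4.6, 0.010),
        "tb_pulm": LogisticHazard(-5.0, 0.006),
        "tb_extra": LogisticHazard(-6.0, 0.008),
    }


@dataclass
class SimulationConfig:
    """Parameters of the data-generating mechanism.

    CD4 dynamics are autoregressive on the square-root scale: responders
    revert toward a personal target ``sqrt(baseline) + cd4_responder_gain``;
    individuals failing first-line ART drift down by ``cd4_drift_failing``
    per 4-week interval until they switch, after which CD4 recovers at up to
    ``cd4_drift_secondline`` per interval. Observed CD4 adds measurement
    noise on the square-root scale and is rounded to whole cells/mm^3.
    """

    n_individuals: int = 2946
    n_intervals: int = 65
    seed: int = 0
    arm_fraction_lcm: float = 0.5

    # baseline CD4, sqrt scale: median ~201 cells/mm3, ~11% below 100
    baseline_sqrt_cd4_mean: float = 14.18
    baseline_sqrt_cd4_sd: float = 3.41

    # probability of ongoing first-line virological failure:
    # expit(failure_logit_intercept - failure_logit_slope * sqrt(cd4_0))
    failure_logit_intercept: float = 1.6
    failure_logit_slope: float = 0.18

    # CD4 dynamics (sqrt cells/mm3 per interval)
    cd4_drift_failing: float = -0.12
    cd4_drift_secondline: float = 0.25
    cd4_reversion: float = 0.05
    cd4_responder_gain: float = 4.0
    cd4_process_noise_sd: float = 0.35
    cd4_obs_noise_sd: float = 0.8

    # clinical event hazards, logit scale, decreasing in true CD4
    event_hazards: dict = field(default_factory=_default_event_hazards)

    # death hazard: expit(intercept - cd4_slope*cd4 + who4_recent*coef
    #                     + on_second_line*coef)
    death_intercept: float = -4.3
    death_cd4_slope: float = 0.02
    death_who4_recent: float = 1.5
    death_secondline: float = -0.25

    # natural (behavioral) switching propensities per interval
    switch_base: float = 8e-4
    switch_lcm_low_cd4: float = 0.055
    lcm_action_threshold: float = 100.0
    switch_who4_lcm: float = 0.18
    switch_who4_cdm: float = 0.22
    switch_who3_recur_cdm: float = 0.06

    ltfu_hazard: float = 0.001

    # structured-treatment-interruption substudy (1:1 within center x arm)
    substudy_fraction: float = 0.27
    substudy_entry_interval: int = 1

    # ancillary covariates
    p_missed_visits: float = 0.01
    p_missed_doses: float = 0.05
    p_bmi_low_baseline: float = 0.15
    p_hb_low_baseline: float = 0.05
    p_flag_recover: float = 0.05
    p_flag_onset: float = 0.005
    p_flag_onset_lowcd4: float = 0.02
    p_cotrimoxazole: float = 0.5
    p_cotrim_stop: float = 0.08
    p_cotrim_start: float = 0.03
    p_who4_weeks24to48: float = 0.08

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if self.n_intervals < 1:
            raise ConfigError("n_intervals must be >= 1")
        probs = {
            "arm_fraction_lcm": self.arm_fraction_lcm,
            "switch_base": self.switch_base,
            "switch_lcm_low_cd4": self.switch_lcm_low_cd4,
            "switch_who4_lcm": self.switch_who4_lcm,
            "switch_who4_cdm": self.switch_who4_cdm,
            "switch_who3_recur_cdm": self.switch_who3_recur_cdm,
            "ltfu_hazard": self.ltfu_hazard,
            "substudy_fraction": self.substudy_fraction,
            "p_missed_visits": self.p_missed_visits,
            "p_missed_doses": self.p_missed_doses,
            "p_bmi_low_baseline": self.p_bmi_low_baseline,
            "p_hb_low_baseline": self.p_hb_low_baseline,
            "p_flag_recover": self.p_flag_recover,
            "p_flag_onset": self.p_flag_onset,
            "p_flag_onset_lowcd4": self.p_flag_onset_lowcd4,
            "p_cotrimoxazole": self.p_cotrimoxazole,
            "p_cotrim_stop": self.p_cotrim_stop,
            "p_cotrim_start": self.p_cotrim_start,
            "p_who4_weeks24to48": self.p_who4_weeks24to48,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, hz in self.event_hazards.items():
            if hz.cd4_slope < 0:
                raise ConfigError(f"event hazard {name}: cd4_slope must be >= 0")
        if self.death_cd4_slope < 0:
            raise ConfigError("death_cd4_slope must be >= 0")
        if self.cd4_obs_noise_sd < 0 or self.cd4_process_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["event_hazards"] = {
            k: [v.intercept, v.cd4_slope] for k, v in self.event_hazards.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "event_hazards" in d:
            d["event_hazards"] = {
                k: LogisticHazard(*v) for k, v in d["event_hazards"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrueSurvival:
    """Forced-regime Monte-Carlo survival: the estimator's ground truth."""

    strategy_id: str
    survival: np.ndarray  # S(k), k = 0..n_intervals; S(0) = 1
    n_replicates: int
    monte_carlo_se: np.ndarray


# ---------------------------------------------------------------------------
# shared mechanism pieces


def _cd4_step(s, mu, failing, on_first_line, cfg, eps):
    """One AR step of sqrt-CD4. Responders revert toward mu; first-line
    failures drift down; switched failures recover at a capped rate."""
    responder = s + cfg.cd4_reversion * (mu - s)
    fail_first = s + cfg.cd4_drift_failing
    recover = s + np.minimum(cfg.cd4_drift_secondline, cfg.cd4_reversion * (mu - s))
    out = np.where(failing & on_first_line, fail_first, np.where(failing, recover, responder))
    return np.clip(out + eps, 1.0, None)


def _death_prob(cfg, cd4, who4_recent, on_second_line):
    from scipy.special import expit

    return expit(
        cfg.death_intercept
        - cfg.death_cd4_slope * cd4
        + cfg.death_who4_recent * who4_recent
        + cfg.death_secondline * on_second_line
    )


def _observe_cd4(s, cfg, rng, n):
    noise = rng.normal(0.0, cfg.cd4_obs_noise_sd, n)
    return np.round(np.clip(s + noise, 1.0, None) ** 2)


# ---------------------------------------------------------------------------
# natural cohort


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the observational person-period cohort.

    Returns a long DataFrame with one row per individual per 4-week
    interval, from interval 0 until death, loss to follow-up, or the
    administrative end. Deterministic given ``config.seed``.
    """
    config.validate()
    cfg = config
    n, K = cfg.n_individuals, cfg.n_intervals
    rng = np.random.default_rng(cfg.seed)

    arm = np.where(rng.random(n) < cfg.arm_fraction_lcm, "LCM", "CDM")
    center = rng.choice(np.array(["A", "B", "C"]), size=n, p=[0.40, 0.35, 0.25])
    regimen = rng.choice(
        np.array(["CBV-TDF", "CBV-ABC", "CBV-NVP"]), size=n, p=[0.73, 0.17, 0.10]
    )
    s = np.clip(
        rng.normal(cfg.baseline_sqrt_cd4_mean, cfg.baseline_sqrt_cd4_sd, n),
        np.sqrt(3.0),
        np.sqrt(1500.0),
    )
    from scipy.special import expit

    failing = rng.random(n) < expit(
        cfg.failure_logit_intercept - cfg.failure_logit_slope * s
    )
    mu = s + cfg.cd4_responder_gain
    bmi_low = rng.random(n) < cfg.p_bmi_low_baseline
    hb_low = rng.random(n) < cfg.p_hb_low_baseline
    cotrim = rng.random(n) < cfg.p_cotrimoxazole
    base_who4 = rng.random(n) < cfg.p_who4_weeks24to48

    # substudy: 1:1 STI / continuous-therapy split within center x arm
    substudy = np.full(n, "none", dtype=object)
    in_ss = rng.random(n) < cfg.substudy_fraction
    stratum = np.char.add(np.char.add(center.astype(str), ":"), arm.astype(str))
    for st in np.unique(stratum):
        idx = np.flatnonzero(in_ss & (stratum == st))
        idx = rng.permutation(idx)
        half = len(idx) // 2
        substudy[idx[:half]] = "sti"
        substudy[idx[half:]] = "ct"

    alive = np.ones(n, dtype=bool)
    in_fup = np.ones(n, dtype=bool)  # not yet lost to follow-up
    on_first = np.ones(n, dtype=bool)
    last_returned = np.full(n, np.nan)  # CD4 result seen by LCM clinicians
    who3like_count = np.zeros(n, dtype=int)  # cumulative WHO3/candida/pulm-TB
    evt_hist = {e: np.zeros((n, 2), dtype=bool) for e in ("who4like", "who3like")}

    rows: dict[str, list] = {c: [] for c in (
        "pid", "k", "on_first_line", "switch", "switch_day", "cd4_obs", "true_cd4",
        "bmi_low", "hb_low", "cotrim", "missed_visits", "missed_doses",
        "who3_day", "esoph_candida_day", "who4_day", "tb_pulm_day", "tb_extra_day",
        "death", "ltfu",
    )}
    pid_all = np.arange(n)
    base_cd4 = np.full(n, np.nan)

    for k in range(K):
        active = alive & in_fup
        if k > 0:
            eps = rng.normal(0.0, cfg.cd4_process_noise_sd, n)
            s = _cd4_step(s, mu, failing, on_first, cfg, eps)
        cd4 = s**2

        measured = k % CD4_MEASUREMENT_PERIOD == 0
        cd4_obs = np.full(n, np.nan)
        if measured:
            cd4_obs = _observe_cd4(s, cfg, rng, n)
            last_returned = np.where(arm == "LCM", cd4_obs, last_returned)
            if k == 0:
                base_cd4 = cd4_obs.copy()

        # clinical events (day in 0..26 so a switch can always follow)
        evt_day = {}
        for e in EVENT_TYPES:
            p = cfg.event_hazards[e].prob(cd4)
            occ = rng.random(n) < p
            day = rng.integers(0, 27, n)
            evt_day[e] = np.where(occ & active, day, np.nan)
        who4like_now = ~np.isnan(evt_day["who4"]) | ~np.isnan(evt_day["tb_extra"])
        who3like_now = (
            ~np.isnan(evt_day["who3"])
            | ~np.isnan(evt_day["esoph_candida"])
            | ~np.isnan(evt_day["tb_pulm"])
        )
        who4_recent = who4like_now | evt_hist["who4like"][:, 0] | evt_hist["who4like"][:, 1]
        who3_recent = who3like_now | evt_hist["who3like"][:, 0] | evt_hist["who3like"][:, 1]
        who3like_count = who3like_count + who3like_now.astype(int)

        # behavioral switch decision (CDM clinicians never see CD4 results)
        low_seen = (arm == "LCM") & (last_returned < cfg.lcm_action_threshold)
        p_sw = np.full(n, cfg.switch_base)
        p_sw = p_sw + np.where(low_seen, cfg.switch_lcm_low_cd4, 0.0)
        p_sw = p_sw + np.where(
            who4_recent,
            np.where(arm == "LCM", cfg.switch_who4_lcm, cfg.switch_who4_cdm),
            0.0,
        )
        p_sw = p_sw + np.where(
            (arm == "CDM") & (who3like_count >= 2) & who3_recent,
            cfg.switch_who3_recur_cdm,
            0.0,
        )
        p_sw = np.clip(p_sw, 0.0, 0.95)
        on_first_start = on_first.copy()
        sw = (rng.random(n) < p_sw) & active & on_first
        sw_day = rng.integers(0, 28, n).astype(float)
        # switches prompted within the interval usually follow the event
        day_stack = np.column_stack([evt_day[e] for e in EVENT_TYPES])
        any_evt_day = ~np.isnan(day_stack).all(axis=1)
        cur_max_day = np.full(n, np.nan)
        cur_max_day[any_evt_day] = np.nanmax(day_stack[any_evt_day], axis=1)
        bump = sw & ~np.isnan(cur_max_day) & (rng.random(n) < 0.8)
        sw_day = np.where(bump & (sw_day <= cur_max_day), cur_max_day + 1, sw_day)
        sw_day = np.where(sw, sw_day, np.nan)
        on_first = on_first & ~sw

        # death, then loss to follow-up (recorded in this interval's row)
        p_d = _death_prob(cfg, cd4, who4_recent, ~on_first_start)
        die = (rng.random(n) < p_d) & active
        lost = (rng.random(n) < cfg.ltfu_hazard) & active & ~die

        missed_v = rng.random(n) < cfg.p_missed_visits
        missed_d = rng.random(n) < cfg.p_missed_doses

        rec = active
        rows["pid"].append(pid_all[rec])
        rows["k"].append(np.full(rec.sum(), k))
        rows["on_first_line"].append(on_first_start[rec])
        rows["switch"].append(sw[rec])
        rows["switch_day"].append(sw_day[rec])
        rows["cd4_obs"].append(cd4_obs[rec])
        rows["true_cd4"].append(cd4[rec])
        rows["bmi_low"].append(bmi_low[rec])
        rows["hb_low"].append(hb_low[rec])
        rows["cotrim"].append(cotrim[rec])
        rows["missed_visits"].append(missed_v[rec])
        rows["missed_doses"].append(missed_d[rec])
        for e in EVENT_TYPES:
            rows[_DAY_COLS[e]].append(evt_day[e][rec])
        rows["death"].append(die[rec])
        rows["ltfu"].append(lost[rec])

        alive = alive & ~die
        in_fup = in_fup & ~lost
        for key, now in (("who4like", who4like_now), ("who3like", who3like_now)):
            evt_hist[key] = np.column_stack([now, evt_hist[key][:, 0]])

        # covariate evolution for the next interval
        onset = np.where(cd4 < 100, cfg.p_flag_onset_lowcd4, cfg.p_flag_onset)
        bmi_low = np.where(
            bmi_low, rng.random(n) >= cfg.p_flag_recover, rng.random(n) < onset
        )
        hb_low = np.where(
            hb_low, rng.random(n) >= cfg.p_flag_recover, rng.random(n) < onset
        )
        cotrim = np.where(
            cotrim, rng.random(n) >= cfg.p_cotrim_stop, rng.random(n) < cfg.p_cotrim_start
        )

    df = pd.DataFrame({c: np.concatenate(v) for c, v in rows.items()})
    person = pd.DataFrame(
        {
            "pid": pid_all,
            "arm": arm,
            "center": center,
            "regimen": regimen,
            "center_regimen": [f"{c}|{r}" for c, r in zip(center, regimen)],
            "base_cd4": base_cd4,
        }
    )
    base_rows = df[df["k"] == 0].set_index("pid")
    person["base_bmi_low"] = base_rows["bmi_low"].reindex(pid_all).to_numpy()
    person["base_hb_low"] = base_rows["hb_low"].reindex(pid_all).to_numpy()
    person["base_who4_24_48"] = base_who4
    person["substudy"] = substudy
    person["substudy_stratum"] = stratum
    cat = np.where(base_cd4 < 100, "<100", np.where(base_cd4 < 200, "100-199", ">=200"))
    person["base_cd4_cat"] = cat

    out = df.merge(person, on="pid", how="left")
    out = out.sort_values(["pid", "k"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# forced-regime counterfactual simulation


def simulate_counterfactual_survival(
    config: SimulationConfig,
    strategy: Strategy,
    n_replicates: int,
    seed_offset: int = 1,
) -> TrueSurvival:
    """Monte-Carlo survival under forced compliance with ``strategy``.

    Re-simulates the latent mechanism for ``n_replicates`` independent
    trajectories. Eligibility is evaluated on CD4 counts observed under the
    strategy's monitoring schedule; the switch interval is drawn uniformly
    over the grace period. Behavioral switching, loss to follow-up, and the
    substudy play no role. Survival is conditional on surviving interval 0
    (matching the discrete-time estimator, which models death in interval
    k+1 given survival through k).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    config.validate()
    cfg = config
    n, K = int(n_replicates), cfg.n_intervals
    m = strategy.grace_intervals - 1
    rng = np.random.default_rng([cfg.seed, 980227, seed_offset])
    from scipy.special import expit

    s = np.clip(
        rng.normal(cfg.baseline_sqrt_cd4_mean, cfg.baseline_sqrt_cd4_sd, n),
        np.sqrt(3.0),
        np.sqrt(1500.0),
    )
    failing = rng.random(n) < expit(
        cfg.failure_logit_intercept - cfg.failure_logit_slope * s
    )
    mu = s + cfg.cd4_responder_gain

    alive = np.ones(n, dtype=bool)
    on_first = np.ones(n, dtype=bool)
    eligible = np.zeros(n, dtype=bool)
    target = np.full(n, -1, dtype=int)
    pending = np.zeros(n, dtype=bool)  # CD4-trigger eligibility from next interval
    pending_evt = np.zeros(n, dtype=bool)  # lagged event trigger
    last_retained = np.full(n, np.nan)
    who3like_count = np.zeros(n, dtype=int)
    hist_who4 = np.zeros((n, 2), dtype=bool)

    want_who4 = "who4" in strategy.event_triggers
    want_two3 = "two_who3" in strategy.event_triggers
    x = strategy.cd4_threshold

    alive_end = np.zeros((K, n), dtype=bool)

    def _grant(newly: np.ndarray, k: int) -> None:
        idx = np.flatnonzero(newly)
        if idx.size:
            eligible[idx] = True
            target[idx] = k + rng.integers(0, m + 1, idx.size)

    for k in range(K):
        if k > 0:
            eps = rng.normal(0.0, cfg.cd4_process_noise_sd, n)
            s = _cd4_step(s, mu, failing, on_first, cfg, eps)
        cd4 = s**2

        # eligibility postponed from the previous interval
        _grant((pending | pending_evt) & ~eligible & alive & on_first, k)
        pending[:] = False
        pending_evt[:] = False

        if k % CD4_MEASUREMENT_PERIOD == 0:
            obs = _observe_cd4(s, cfg, rng, n)
            retained = strategy.observes_week(4 * k)
            if retained:
                last_retained = np.where(alive, obs, last_retained)
                if x is not None:
                    pending |= (obs < x) & ~eligible & alive & on_first

        occ = {}
        for e in EVENT_TYPES:
            occ[e] = (rng.random(n) < cfg.event_hazards[e].prob(cd4)) & alive
        who4like = occ["who4"]
        if not strategy.exclude_extrapulmonary_tb:
            who4like = who4like | occ["tb_extra"]
        who3like = occ["who3"] | occ["esoph_candida"] | occ["tb_pulm"]
        prev_count = who3like_count.copy()
        who3like_count = who3like_count + who3like.astype(int)

        tie_ok = (
            np.ones(n, dtype=bool)
            if (strategy.tiebreaker_cd4 is None or strategy.who4_ignore_cd4_restriction)
            else (np.isnan(last_retained) | (last_retained < strategy.tiebreaker_cd4))
        )
        trig = np.zeros(n, dtype=bool)
        if want_who4:
            trig |= who4like & tie_ok
        if want_two3:
            trig |= (prev_count < 2) & (who3like_count >= 2) & tie_ok
        trig &= ~eligible & alive & on_first
        if strategy.lag_events_4wk:
            pending_evt |= trig
        else:
            _grant(trig, k)

        on_first_start = on_first.copy()
        force = eligible & on_first & alive & (target == k)
        on_first = on_first & ~force

        who4_recent = who4like | hist_who4[:, 0] | hist_who4[:, 1]
        p_d = _death_prob(cfg, cd4, who4_recent, ~on_first_start)
        die = (rng.random(n) < p_d) & alive
        alive = alive & ~die
        alive_end[k] = alive
        hist_who4 = np.column_stack([who4like, hist_who4[:, 0]])

    base = alive_end[0]
    n_base = int(base.sum())
    if n_base == 0:
        raise ConfigError("no trajectory survived interval 0; cannot condition")
    surv = np.empty(K + 1)
    surv[0] = 1.0
    for k in range(K):
        surv[k + 1] = alive_end[k][base].mean()
    se = np.sqrt(np.clip(surv * (1 - surv), 0.0, None) / n_base)
    return TrueSurvival(
        strategy_id=strategy.strategy_id,
        survival=surv,
        n_replicates=n_base,
        monte_carlo_se=se,
    )


# ---------------------------------------------------------------------------
# IO


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("on_first_line", "switch", "bmi_low", "hb_low", "cotrim",
                "missed_visits", "missed_doses", "death", "ltfu",
                "base_bmi_low", "base_hb_low", "base_who4_24_48"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df.sort_values(["pid", "k"], kind="mergesort").reset_index(drop=True)
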