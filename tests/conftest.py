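"""Shared fixtures: the small reference cohort and frame-building helpers."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cloneweight.synthetic import SimulationConfig, generate_cohort

CONFIG_DIR = Path(__file__).resolve().parents[1] / "configs"

EVENT_DAY_COLS = (
    "who3_day",
    "esoph_candida_day",
    "who4_day",
    "tb_pulm_day",
    "tb_extra_day",
)


@pytest.fixture(scope="session")
def fixture_config() -> SimulationConfig:
    return SimulationConfig.from_yaml(CONFIG_DIR / "fixture_cohort.yaml")


@pytest.fixture(scope="session")
def fixture_cohort(fixture_config) -> pd.DataFrame:
    """The shipped reference cohort: 200 persons, 30 intervals."""
    return generate_cohort(fixture_config)


@pytest.fixture(scope="session")
def fixture_weighted(fixture_cohort):
    """Fixture cohort with fitted p_switch / LTFU / substudy weights."""
    from cloneweight.pipeline import attach_person_interval_weights

    cohort_w, switch_fit, ltfu_fit = attach_person_interval_weights(fixture_cohort)
    return cohort_w, switch_fit, ltfu_fit


def person_frame(rows: list[dict], pid: int = 0) -> pd.DataFrame:
    """Build a minimal person-period frame from sparse row specs.

    Each row dict may set: cd4 (measured value), switch_day, and any of the
    event day columns. Intervals are consecutive from 0.
    """
    n = len(rows)
    df = pd.DataFrame(
        {
            "pid": pid,
            "k": np.arange(n),
            "on_first_line": True,
            "switch": False,
            "switch_day": np.nan,
            "cd4_obs": np.nan,
            "true_cd4": 200.0,
            "bmi_low": False,
            "hb_low": False,
            "cotrim": False,
            "missed_visits": False,
            "missed_doses": False,
            "death": False,
            "ltfu": False,
            "arm": "LCM",
            "center": "A",
            "regimen": "CBV-TDF",
            "center_regimen": "A|CBV-TDF",
            "base_cd4": 200.0,
            "base_cd4_cat": ">=200",
            "base_bmi_low": False,
            "base_hb_low": False,
            "base_who4_24_48": False,
            "substudy": "none",
            "substudy_stratum": "A:LCM",
        }
    )
    for c in EVENT_DAY_COLS:
        df[c] = np.nan
    switched = False
    for i, spec in enumerate(rows):
        for key, val in spec.items():
            if key == "cd4":
                df.loc[i, "cd4_obs"] = float(val)
            elif key == "switch_day":
                df.loc[i, "switch_day"] = float(val)
                df.loc[i, "switch"] = True
            else:
                df.loc[i, key] = val
    # maintain treatment-line bookkeeping after a switch
    sw_rows = df.index[df["switch"]]
    if len(sw_rows):
        df.loc[df.index > sw_rows[0], "on_first_line"] = False
    if df.loc[0, "base_cd4"] == 200.0 and not np.isnan(df.loc[0, "cd4_obs"]):
        df["base_cd4"] = df.loc[0, "cd4_obs"]
    return df
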