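"""Life-year accounting and scenario comparison.

All outcomes are expected life-years per 1000 persons over the remaining
lifespan starting at the beginning of 2020:

* ``LY``   -- under the disrupted scenario;
* ``LYNS`` -- under no screening;
* ``LYND`` -- under no disruption;
* ``LYL  = LYND - LY``   (life-years lost to the disruption);
* ``LYG  = LYND - LYNS`` (life-years gained by undisrupted screening);
* ``%LYLost = 100 * LYL / LYG``.

The three LY values must come from the same persons under common random
numbers, so the identities hold exactly by construction.  Losses are also
expressed as life-days per person, and outcomes are compared across model
presets as (min, max) ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSet",
    "ComparativeRange",
    "life_years",
    "per_person_life_years",
    "outcome_table",
    "outcomes_from_runs",
    "relative_risk",
    "comparative_range",
    "life_days_per_person",
    "round_half_up",
]

DAYS_PER_YEAR = 365.25
#: LY accrue from the beginning of 2020; pandemic effects start in April.
LY_ANCHOR_OFFSET_YEARS = 0.25


def round_half_up(x: float) -> int:
    """Nearest-integer rounding with .5 away from zero (report style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class OutcomeSet:
    """Life-year and CRC outcomes for one (scenario, preset) cell."""

    scenario_label: str
    preset_label: str
    n: int
    LY: float
    LYNS: float
    LYND: float
    LYL: float
    LYG_no_disruption: float
    pct_LY_lost: Optional[float]
    crc_cases_per_1000: float
    crc_deaths_per_1000: float
    mc_se: Dict[str, float]

    def __post_init__(self) -> None:
        if not np.isclose(self.LYL, self.LYND - self.LY, atol=1e-9):
            raise ValueError("LYL must equal LYND - LY")
        if not np.isclose(self.LYG_no_disruption, self.LYND - self.LYNS, atol=1e-9):
            raise ValueError("LYG must equal LYND - LYNS")


@dataclass(frozen=True)
class ComparativeRange:
    """Element-wise (min, max) of outcomes across model presets."""

    ranges: Dict[str, tuple]

    def __getitem__(self, key: str) -> tuple:
        return self.ranges[key]


def per_person_life_years(death_ages: np.ndarray, age_at_pandemic: float) -> np.ndarray:
    """Remaining life-years per person from the beginning of 2020."""
    anchor = age_at_pandemic - LY_ANCHOR_OFFSET_YEARS
    return np.maximum(np.asarray(death_ages, dtype=float) - anchor, 0.0)


def life_years(death_ages: Sequence[float], age_at_pandemic: float) -> float:
    """Expected remaining life-years per 1000 persons from the 2020 anchor."""
    ly = per_person_life_years(np.asarray(death_ages, dtype=float), age_at_pandemic)
    if ly.size == 0:
        raise ValueError("life_years needs a non-empty population")
    return float(ly.mean() * 1000.0)


def outcome_table(
    LY: float,
    LYNS: float,
    LYND: float,
    cases: float = float("nan"),
    deaths: float = float("nan"),
    scenario_label: str = "",
    preset_label: str = "",
    n: int = 0,
    mc_se: Optional[Dict[str, float]] = None,
) -> OutcomeSet:
    """Assemble an OutcomeSet from per-1000 LY values; identities hold exactly.

    The percent lost is undefined (``None``) when LYG <= 0.
    """
    lyl = LYND - LY
    lyg = LYND - LYNS
    pct = 100.0 * lyl / lyg if lyg > 0 else None
    return OutcomeSet(
        scenario_label=scenario_label,
        preset_label=preset_label,
        n=n,
        LY=LY,
        LYNS=LYNS,
        LYND=LYND,
        LYL=lyl,
        LYG_no_disruption=lyg,
        pct_LY_lost=pct,
        crc_cases_per_1000=cases,
        crc_deaths_per_1000=deaths,
        mc_se=mc_se or {},
    )


def outcomes_from_runs(
    disrupted: pd.DataFrame,
    no_disruption: pd.DataFrame,
    no_screening: pd.DataFrame,
    age_at_pandemic: float,
    mask: Optional[np.ndarray] = None,
    scenario_label: str = "",
    preset_label: str = "",
) -> OutcomeSet:
    """OutcomeSet from three per-person scenario runs on the same persons.

    ``mask`` restricts the accounting to the cohort members (alive and
    CRC-free at the pandemic onset); Monte-Carlo standard errors of the LY
    quantities and of the paired differences are reported per 1000 persons.
    """
    for df in (no_disruption, no_screening):
        if not np.array_equal(df["person_id"].to_numpy(), disrupted["person_id"].to_numpy()):
            raise ValueError("runs must cover the same persons in the same order")
    if mask is None:
        mask = np.ones(len(disrupted), dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cohort after masking")
    ly_d = per_person_life_years(disrupted["death_age"].to_numpy()[mask], age_at_pandemic)
    ly_nd = per_person_life_years(no_disruption["death_age"].to_numpy()[mask], age_at_pandemic)
    ly_ns = per_person_life_years(no_screening["death_age"].to_numpy()[mask], age_at_pandemic)
    n = int(mask.sum())
    sqrt_n = math.sqrt(n)
    mc_se = {
        "LY": 1000.0 * float(ly_d.std(ddof=1)) / sqrt_n,
        "LYND": 1000.0 * float(ly_nd.std(ddof=1)) / sqrt_n,
        "LYNS": 1000.0 * float(ly_ns.std(ddof=1)) / sqrt_n,
        "LYL": 1000.0 * float((ly_nd - ly_d).std(ddof=1)) / sqrt_n,
        "LYG_no_disruption": 1000.0 * float((ly_nd - ly_ns).std(ddof=1)) / sqrt_n,
    }
    cases = 1000.0 * float(disrupted["crc_case"].to_numpy()[mask].mean())
    deaths = 1000.0 * float(disrupted["crc_death"].to_numpy()[mask].mean())
    return outcome_table(
        LY=1000.0 * float(ly_d.mean()),
        LYNS=1000.0 * float(ly_ns.mean()),
        LYND=1000.0 * float(ly_nd.mean()),
        cases=cases,
        deaths=deaths,
        scenario_label=scenario_label,
        preset_label=preset_label,
        n=n,
        mc_se=mc_se,
    )


def relative_risk(scenario_per_1000: float, reference_per_1000: float) -> float:
    """Ratio of per-1000 lifetime CRC counts (cases or deaths)."""
    if reference_per_1000 == 0:
        raise ZeroDivisionError("relative risk undefined for a zero reference count")
    return scenario_per_1000 / reference_per_1000


_RANGE_FIELDS = (
    "LY",
    "LYNS",
    "LYND",
    "LYL",
    "LYG_no_disruption",
    "pct_LY_lost",
    "crc_cases_per_1000",
    "crc_deaths_per_1000",
)


def comparative_range(outcomes_by_preset: Sequence[OutcomeSet]) -> ComparativeRange:
    """Element-wise (min, max) across model presets for one scenario."""
    if not outcomes_by_preset:
        raise ValueError("need at least one preset outcome")
    ranges = {}
    for name in _RANGE_FIELDS:
        vals = [getattr(o, name) for o in outcomes_by_preset]
        vals = [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if vals:
            ranges[name] = (min(vals), max(vals))
    return ComparativeRange(ranges)


def life_days_per_person(ly_per_1000: float) -> float:
    """Convert LY per 1000 persons to life-days per person."""
    return ly_per_1000 / 1000.0 * DAYS_PER_YEAR
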