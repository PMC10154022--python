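"""Experiment driver and report generation.

``run_experiment`` executes a configured set of scenario labels for each
model preset and colonoscopy-sensitivity scenario, under common random
numbers, and writes tidy outcome tables plus a machine-readable run manifest
(seed, config digest, package version, wall time).  ``render_reports``
produces the summary-table CSV (one row per scenario x model, LY columns
rounded to integers at report time only) and dot-plot data for the
losses-by-scenario figure: rows below 2 life-days lost per person are
filtered out and the rest sorted from highest to lowest loss.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fixtures import default_life_table, default_presets, generate_population, load_test_profiles
from .natural_history import ModelPreset
from .outcomes import (
    OutcomeSet,
    life_days_per_person,
    outcomes_from_runs,
    round_half_up,
)
from .policy import default_surveillance_table
from .scenarios import (
    Disruption,
    DisruptionType,
    Scenario,
    parse_scenario_code,
    run_scenario,
    unscreened_outcomes,
)

logger = logging.getLogger("crc_disrupt")

__all__ = ["ExperimentConfig", "run_experiment", "render_reports", "LIFE_DAYS_FIGURE_THRESHOLD"]

#: Scenarios losing less than this many life-days per person are omitted
#: from the dot-plot data.
LIFE_DAYS_FIGURE_THRESHOLD = 2.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serialisable description of one experiment run."""

    scenarios: tuple
    n: int
    seed: int
    sensitivity_scenarios: tuple = ("high",)
    presets: tuple = ("preset-A", "preset-B")
    output_dir: str = "results"
    formats: tuple = ("csv",)

    def __post_init__(self) -> None:
        for label in self.scenarios:
            parse_scenario_code(label)  # fail before any simulation starts
        if self.n < 1 or self.seed < 0:
            raise ValueError("need n >= 1 and seed >= 0")
        for s in self.sensitivity_scenarios:
            if s not in ("high", "low"):
                raise ValueError(f"unknown sensitivity scenario {s!r}")

    def to_dict(self) -> dict:
        return {
            "scenarios": list(self.scenarios),
            "n": self.n,
            "seed": self.seed,
            "sensitivity_scenarios": list(self.sensitivity_scenarios),
            "presets": list(self.presets),
            "output_dir": self.output_dir,
            "formats": list(self.formats),
        }

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            scenarios=tuple(raw["scenarios"]),
            n=int(raw["n"]),
            seed=int(raw["seed"]),
            sensitivity_scenarios=tuple(raw.get("sensitivity_scenarios", ["high"])),
            presets=tuple(raw.get("presets", ["preset-A", "preset-B"])),
            output_dir=str(raw.get("output_dir", "results")),
            formats=tuple(raw.get("formats", ["csv"])),
        )


def _outcome_row(o: OutcomeSet, sensitivity: str) -> dict:
    return {
        "scenario": o.scenario_label,
        "model": o.preset_label,
        "sensitivity": sensitivity,
        "n": o.n,
        "LY_ns": o.LYNS,
        "LY_nd": o.LYND,
        "LYG_no_disruption": o.LYG_no_disruption,
        "LY": o.LY,
        "LYG_disrupted": o.LY - o.LYNS,
        "LYL": o.LYL,
        "pct_LY_lost": o.pct_LY_lost if o.pct_LY_lost is not None else np.nan,
        "crc_cases_per_1000": o.crc_cases_per_1000,
        "crc_deaths_per_1000": o.crc_deaths_per_1000,
        "life_days_lost_per_person": life_days_per_person(o.LYL),
        "se_LY": o.mc_se.get("LY", np.nan),
        "se_LYL": o.mc_se.get("LYL", np.nan),
        "se_LYG": o.mc_se.get("LYG_no_disruption", np.nan),
    }


def run_experiment(config: ExperimentConfig, presets: Optional[Sequence[ModelPreset]] = None) -> Dict[str, Path]:
    """Run every (scenario x preset x sensitivity) cell and write results.

    Returns paths of the written artifacts.  A rerun with the same config
    produces byte-identical outcome tables.
    """
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    life_table = default_life_table()
    table = default_surveillance_table()
    profiles = load_test_profiles()
    all_presets = {p.label: p for p in (presets if presets is not None else default_presets())}
    chosen = [all_presets[label] for label in config.presets]

    rows: List[dict] = []
    for preset in chosen:
        # one population per (preset, cohort age); shared across that cohort's scenarios
        populations: Dict[float, list] = {}
        cache: Dict[tuple, pd.DataFrame] = {}
        for sensitivity in config.sensitivity_scenarios:
            for label in config.scenarios:
                scenario = parse_scenario_code(label, sensitivity)
                cohort = scenario.cohort
                if cohort.age_2020 not in populations:
                    birth = cohort.birth_year
                    populations[cohort.age_2020], _ = generate_population(
                        preset, life_table, birth, config.n, config.seed
                    )
                pop = populations[cohort.age_2020]
                ns_key = ("ns", cohort.age_2020)
                if ns_key not in cache:
                    cache[ns_key] = unscreened_outcomes(pop, cohort.age_2020)
                ns = cache[ns_key]
                nd_key = ("nd", cohort.code, cohort.arm_modality.value, sensitivity)
                if nd_key not in cache:
                    nd_scenario = Scenario(
                        cohort=cohort,
                        disruption=Disruption(DisruptionType.NONE),
                        sensitivity_scenario=sensitivity,
                    )
                    cache[nd_key] = run_scenario(
                        nd_scenario, pop, profiles["colonoscopy"], profiles["fit"], preset, config.seed, table
                    )
                nd = cache[nd_key]
                dis = run_scenario(
                    scenario, pop, profiles["colonoscopy"], profiles["fit"], preset, config.seed, table
                )
                alive = np.array([h.other_cause_death_age for h in pop]) > cohort.age_2020
                mask = alive & ~nd["pre_pandemic_dx"].to_numpy()
                o = outcomes_from_runs(
                    dis, nd, ns, cohort.age_2020, mask, scenario_label=label, preset_label=preset.label
                )
                logger.info(
                    "scenario=%s preset=%s sens=%s n=%d seed=%d LYNS=%.1f LYND=%.1f LY=%.1f",
                    label, preset.label, sensitivity, o.n, config.seed, o.LYNS, o.LYND, o.LY,
                )
                rows.append(_outcome_row(o, sensitivity))

    outcomes_df = pd.DataFrame(rows)
    paths = {"outcomes": out_dir / "outcomes.csv"}
    outcomes_df.to_csv(paths["outcomes"], index=False, float_format="%.6f")

    # min-max range across presets per (scenario, sensitivity)
    range_rows = []
    value_cols = ["LY_ns", "LY_nd", "LYG_no_disruption", "LY", "LYL", "pct_LY_lost"]
    for (label, sens), grp in outcomes_df.groupby(["scenario", "sensitivity"], sort=False):
        row = {"scenario": label, "sensitivity": sens}
        for col in value_cols:
            row[f"{col}_min"] = grp[col].min()
            row[f"{col}_max"] = grp[col].max()
        range_rows.append(row)
    paths["ranges"] = out_dir / "ranges.csv"
    pd.DataFrame(range_rows).to_csv(paths["ranges"], index=False, float_format="%.6f")

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def render_reports(outcomes_csv, out_dir, make_plots: bool = False) -> Dict[str, Path]:
    """Summary-table CSV and dot-plot data from an outcomes table.

    LY columns are rounded to integers and percents to the nearest integer at
    report time; dot-plot rows are filtered at 2 life-days lost per person
    and sorted from highest to lowest loss.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(outcomes_csv)
    table = pd.DataFrame(
        {
            "scenario": df["scenario"],
            "model": df["model"],
            "sensitivity": df["sensitivity"],
            "LY_ns": df["LY_ns"].map(round_half_up),
            "LY_nd": df["LY_nd"].map(round_half_up),
            "LYG": df["LYG_no_disruption"].map(round_half_up),
            "LY": df["LY"].map(round_half_up),
            "LYG_disrupted": df["LYG_disrupted"].map(round_half_up),
            "LYL": df["LYL"].map(round_half_up),
            "pct_LY_lost": [round_half_up(v) if np.isfinite(v) else "" for v in df["pct_LY_lost"]],
        }
    )
    paths = {"summary_table": out_dir / "summary_table.csv"}
    table.to_csv(paths["summary_table"], index=False)

    dots = df[["scenario", "model", "sensitivity", "LYL", "life_days_lost_per_person"]].copy()
    kept = dots[dots["life_days_lost_per_person"] >= LIFE_DAYS_FIGURE_THRESHOLD]
    if kept.empty:
        logger.info("all scenarios below %.1f life-days lost; dot-plot data empty", LIFE_DAYS_FIGURE_THRESHOLD)
    kept = kept.sort_values("LYL", ascending=False, kind="mergesort")
    paths["dotplot"] = out_dir / "dotplot_data.csv"
    kept.to_csv(paths["dotplot"], index=False, float_format="%.6f")

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * max(len(kept), 1))))
        labels = kept["scenario"] + " (" + kept["model"] + ")"
        ax.scatter(kept["LYL"], range(len(kept)))
        ax.set_yticks(range(len(kept)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.invert_yaxis()
        ax.set_xlabel("Life-years lost per 1000 persons")
        fig.tight_layout()
        paths["figure"] = out_dir / "losses_dotplot.png"
        fig.savefig(paths["figure"], dpi=150)
        plt.close(fig)
    return paths
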