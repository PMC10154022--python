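"""Bundled synthetic inputs: life table, model presets, test profiles.

The package ships everything its simulations consume: a synthetic cohort life
table built from a Gompertz-Makeham hazard, two natural-history presets
(``preset-A`` / ``preset-B``) whose parameters are documented YAML, the
per-lesion test-sensitivity profiles, the surveillance-interval table, and a
frozen reference-population digest for reproducibility tests.

The presets are explicit stand-ins for two structurally different
microsimulation models; their parameters were chosen at design time so that
lifetime unscreened CRC incidence falls in a plausible 4-7% band and the two
presets differ (frailty family, growth, sojourn, FIT positivity mode), so
cross-model output ranges are non-degenerate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .detection import Modality, TestProfile
from .natural_history import (
    DOMAIN_NATURAL_HISTORY,
    ConfigurationError,
    LifeHistory,
    LifeTable,
    ModelPreset,
    person_rng,
    simulate_life_history,
)
from .policy import SurveillanceTable, default_surveillance_table

__all__ = [
    "make_life_table",
    "default_life_table",
    "default_presets",
    "load_test_profiles",
    "generate_population",
    "population_digest",
    "FixtureBundle",
    "load_fixture_bundle",
    "export_fixtures",
]

#: Gompertz-Makeham parameters of the bundled life table (per-year hazard
#: a + b*exp(c*age)), chosen so remaining life expectancy roughly matches a
#: present-day average-risk US cohort (about 32 y at 50, 24 y at 60, 16 y at 70).
DEFAULT_MAKEHAM_A = 5.0e-4
DEFAULT_GOMPERTZ_B = 2.2e-5
DEFAULT_GOMPERTZ_C = 0.095
DEFAULT_MAX_AGE = 100


def make_life_table(
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    max_age: int = DEFAULT_MAX_AGE,
) -> LifeTable:
    """Life table from the continuous hazard ``a + b*exp(c*age)``.

    Annual probabilities are ``1 - exp(-H(x, x+1))`` with the hazard
    integrated exactly over each year; the terminal age is forced to 1.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ConfigurationError("Gompertz-Makeham parameters must be >= 0")
    ages = np.arange(0, max_age)
    if gompertz_c > 0:
        cum = gompertz_b / gompertz_c * (np.exp(gompertz_c * (ages + 1)) - np.exp(gompertz_c * ages))
    else:
        cum = gompertz_b * np.ones_like(ages, dtype=float)
    q = 1.0 - np.exp(-(makeham_a + cum))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages, q)


def default_life_table() -> LifeTable:
    """The bundled synthetic cohort life table."""
    ref = resources.files("crc_disrupt.data").joinpath("life_table.csv")
    with ref.open("r") as fh:
        return LifeTable.from_csv(fh)


def default_presets() -> Tuple[ModelPreset, ModelPreset]:
    """The two bundled natural-history presets (preset-A, preset-B)."""
    out = []
    for name in ("preset_a.yaml", "preset_b.yaml"):
        ref = resources.files("crc_disrupt.data").joinpath(name)
        with resources.as_file(ref) as path:
            out.append(ModelPreset.from_yaml(path))
    return out[0], out[1]


def load_test_profiles() -> Dict[str, Dict[str, TestProfile]]:
    """Bundled per-lesion sensitivity/specificity profiles.

    Returns ``{"colonoscopy": {"high": ..., "low": ...},
    "fit": {"crcspin": ..., "miscan": ...}}``.
    """
    import yaml

    ref = resources.files("crc_disrupt.data").joinpath("test_profiles.yaml")
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    colo = {}
    for label, p in raw["colonoscopy"].items():
        colo[label] = TestProfile(
            modality=Modality.COLONOSCOPY,
            sens_small=p["sens_small"],
            sens_medium=p["sens_medium"],
            sens_large=p["sens_large"],
            sens_preclinical=p["sens_preclinical"],
            specificity=p["specificity"],
            positivity_mode="per_lesion",
            scenario_label=label,
        )
    fit = {}
    for label, p in raw["fit"].items():
        if "sens_preclinical_early" in p:
            preclin = (p["sens_preclinical_early"], p["sens_preclinical_late"])
        else:
            preclin = p["sens_preclinical"]
        fit[label] = TestProfile(
            modality=Modality.FIT,
            sens_small=p["sens_small"],
            sens_medium=p["sens_medium"],
            sens_large=p["sens_large"],
            sens_preclinical=preclin,
            specificity=p["specificity"],
            positivity_mode=p["positivity_mode"],
            scenario_label=label,
        )
    return {"colonoscopy": colo, "fit": fit}


# --------------------------------------------------------------------------
# Populations
# --------------------------------------------------------------------------


def generate_population(
    preset: ModelPreset,
    life_table: LifeTable,
    birth_year: float,
    n: int,
    seed: int,
) -> Tuple[List[LifeHistory], str]:
    """Simulate ``n`` unscreened life histories with per-person substreams.

    Person ``i`` of an ``n``-person run is identical to person ``i`` of any
    other run with the same seed, so populations are prefix-stable across
    sizes.  Returns the population and its digest.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    histories = [
        simulate_life_history(
            preset,
            life_table,
            birth_year,
            person_rng(seed, pid, DOMAIN_NATURAL_HISTORY),
            person_id=pid,
        )
        for pid in range(n)
    ]
    return histories, population_digest(histories)


def _q(x) -> str:
    """Quantise an event age to 1e-9 years for platform-stable hashing."""
    return "-" if x is None else format(round(float(x) * 1e9), "d")


def population_digest(histories: List[LifeHistory]) -> str:
    """SHA-256 over quantised per-person event ages (platform-stable)."""
    h = hashlib.sha256()
    for hist in histories:
        parts = [
            str(hist.person_id),
            _q(hist.other_cause_death_age),
            _q(hist.clinical_dx_age),
            _q(hist.death_age),
        ]
        for a in hist.adenomas:
            parts.append(_q(a.onset_age))
            parts.append(_q(a.transform_age))
            parts.append(_q(a.clinical_dx_age))
        h.update("|".join(parts).encode())
        h.update(b";")
    return h.hexdigest()


@dataclass(frozen=True)
class FixtureBundle:
    """Everything the simulations consume, plus a frozen reference digest."""

    life_table: LifeTable
    presets: Tuple[ModelPreset, ModelPreset]
    test_profiles: Dict[str, Dict[str, TestProfile]]
    surveillance_table: SurveillanceTable
    reference_n: int
    reference_seed: int
    reference_digests: Dict[str, str]


def load_fixture_bundle() -> FixtureBundle:
    ref = resources.files("crc_disrupt.data").joinpath("reference_population.json")
    with ref.open("r") as fh:
        meta = json.load(fh)
    return FixtureBundle(
        life_table=default_life_table(),
        presets=default_presets(),
        test_profiles=load_test_profiles(),
        surveillance_table=default_surveillance_table(),
        reference_n=int(meta["n"]),
        reference_seed=int(meta["seed"]),
        reference_digests=dict(meta["digests"]),
    )


def export_fixtures(directory) -> List[str]:
    """Write the bundled inputs (life table, presets, tables) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    lt = default_life_table()
    path = directory / "life_table.csv"
    lt.to_csv(path)
    written.append(str(path))
    for preset in default_presets():
        path = directory / f"{preset.label.replace('-', '_')}.yaml"
        preset.to_yaml(path)
        written.append(str(path))
    table = default_surveillance_table()
    path = directory / "surveillance_intervals.csv"
    table.to_csv(path)
    written.append(str(path))
    profiles = load_test_profiles()
    rows = []
    for modality, group in profiles.items():
        for label, p in group.items():
            pre = p.sens_preclinical
            rows.append(
                {
                    "modality": modality,
                    "profile": label,
                    "sens_small": p.sens_small,
                    "sens_medium": p.sens_medium,
                    "sens_large": p.sens_large,
                    "sens_preclinical": pre if isinstance(pre, (int, float)) else "/".join(str(v) for v in pre),
                    "specificity": p.specificity,
                    "positivity_mode": p.positivity_mode,
                }
            )
    path = directory / "test_profiles.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(str(path))
    return written
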