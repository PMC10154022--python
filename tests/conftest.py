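"""Shared fixtures: bundled inputs, synthetic persons, reference populations."""

from __future__ import annotations

import pytest

from crc_disrupt import (
    Adenoma,
    LifeHistory,
    default_life_table,
    default_presets,
    default_surveillance_table,
    generate_population,
    load_test_profiles,
)

#: root seed for every stochastic test in the suite
SUITE_SEED = 20260927 % (2**31)

#: population size for the large common-random-numbers property suites
PROPERTY_N = 100_000


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def profiles():
    return load_test_profiles()


@pytest.fixture(scope="session")
def surveillance_table():
    return default_surveillance_table()


def make_person(
    lesions=(),
    ocd=90.0,
    person_id=0,
    birth_year=1970.25,
    u_survival=0.5,
):
    """Hand-built LifeHistory for deterministic detection/policy tests.

    ``lesions`` is a list of dicts with keys onset/rate/transform/sojourn/reach.
    """
    adenomas = []
    for j, spec in enumerate(lesions):
        transform = spec.get("transform")
        sojourn = spec.get("sojourn")
        dx = transform + sojourn if transform is not None and sojourn is not None else None
        if dx is not None and dx >= ocd:
            dx = None
        adenomas.append(
            Adenoma(
                lesion_id=j,
                onset_age=spec["onset"],
                growth_rate=spec.get("rate", 0.5),
                transform_age=transform,
                sojourn_years=sojourn,
                clinical_dx_age=dx,
                within_reach=spec.get("reach", True),
            )
        )
    dx_all = [a.clinical_dx_age for a in adenomas if a.clinical_dx_age is not None]
    clinical_dx = min(dx_all) if dx_all else None
    preclin = min((a.transform_age for a in adenomas if a.transform_age is not None), default=None)
    return LifeHistory(
        person_id=person_id,
        birth_year=birth_year,
        adenomas=adenomas,
        preclinical_onset_age=preclin,
        clinical_dx_age=clinical_dx,
        crc_death_age=None,
        other_cause_death_age=ocd,
        death_age=ocd,
        cause="other",
        u_survival=u_survival,
    )


@pytest.fixture(scope="session")
def u50_populations(presets, life_table):
    """One U50 population per preset for the common-random-numbers suites."""
    pops = {}
    for preset in presets:
        pop, _ = generate_population(preset, life_table, 1970.25, PROPERTY_N, SUITE_SEED)
        pops[preset.label] = pop
    return pops
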