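"""Natural-history module: onset process, life table sampling, growth, survival."""

import math

import numpy as np
import pytest

from crc_disrupt import (
    DetectionMode,
    LifeTable,
    ModelPreset,
    SizeClass,
    crc_death_age,
    lesion_size_class,
    other_cause_death_age,
    person_rng,
    simulate_life_history,
)
from crc_disrupt.natural_history import ConfigurationError, SurvivalParams, survival_quantile

from .conftest import SUITE_SEED, make_person


def flat_preset(onset_rate=0.0, frailty_var=0.0, transform=(0.0, 0.0, 0.0), **kw):
    """Minimal preset with a constant onset hazard from birth."""
    defaults = dict(
        label="test",
        onset_age_breaks=(0.0,),
        onset_rates=(onset_rate,),
        frailty_distribution="lognormal",
        frailty_variance=frailty_var,
        growth_rate_median=0.5,
        growth_rate_sigma_log=0.5,
        initial_diameter_mm=1.0,
        medium_threshold_mm=6.0,
        large_threshold_mm=10.0,
        reach_probability=1.0,
        transform_annual_prob=transform,
        sojourn_mean_years=3.0,
        sojourn_sd_years=1.5,
        survival_clinical=SurvivalParams(0.4, 4.0),
        survival_screen=SurvivalParams(0.7, 6.0),
        fit_positivity_mode="per_person",
        fit_profile_key="crcspin",
    )
    defaults.update(kw)
    return ModelPreset(**defaults)


def uniform_life_table(q=0.0, max_age=100):
    probs = np.full(max_age, q)
    probs[-1] = 1.0
    return LifeTable(np.arange(max_age), probs)


class TestOtherCauseDeath:
    def test_terminal_year_only(self):
        lt = uniform_life_table(0.0, max_age=80)
        rng = person_rng(SUITE_SEED, 0)
        ages = [other_cause_death_age(lt, rng) for _ in range(50)]
        assert all(79.0 <= a <= 80.0 for a in ages)

    def test_constant_hazard_matches_geometric_mean(self):
        q = 0.05
        lt = uniform_life_table(q, max_age=400)  # long horizon: negligible truncation
        rng = person_rng(SUITE_SEED, 1)
        n = 100_000
        cdf = lt.death_age_cdf()
        u = rng.random(n)
        years = np.searchsorted(cdf, u, side="right")
        mean_year = years.mean()
        # geometric: E[#completed years] = (1-q)/q
        expect = (1 - q) / q
        se = np.std(years, ddof=1) / math.sqrt(n)
        assert abs(mean_year - expect) < 4 * se

    def test_empirical_cdf_matches_life_table(self, life_table):
        rng = person_rng(SUITE_SEED, 2)
        n = 100_000
        ages = np.array([other_cause_death_age(life_table, rng) for _ in range(n)])
        cdf = life_table.death_age_cdf()
        grid = life_table.ages + 1.0
        ecdf = np.searchsorted(np.sort(ages), grid, side="right") / n
        assert np.max(np.abs(ecdf - cdf)) < 0.01  # KS tolerance at n=1e5

    def test_bounds(self, life_table):
        rng = person_rng(SUITE_SEED, 3)
        ages = [other_cause_death_age(life_table, rng) for _ in range(1000)]
        assert all(0 < a <= life_table.max_age for a in ages)


class TestLifeTable:
    def test_terminal_probability_required(self):
        with pytest.raises(ConfigurationError):
            LifeTable(np.arange(10), np.full(10, 0.5))

    def test_probabilities_bounded(self):
        probs = np.full(10, 0.5)
        probs[-1] = 1.0
        probs[3] = 1.5
        with pytest.raises(ConfigurationError):
            LifeTable(np.arange(10), probs)


class TestSimulateLifeHistory:
    def test_zero_onset_hazard_means_no_disease(self, life_table):
        preset = flat_preset(onset_rate=0.0)
        for pid in range(50):
            h = simulate_life_history(preset, life_table, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid)
            assert h.adenomas == []
            assert h.clinical_dx_age is None and h.crc_death_age is None
            assert h.death_age == h.other_cause_death_age and h.cause == "other"

    def test_zero_transformation_means_no_cancer(self, life_table):
        preset = flat_preset(onset_rate=0.05, transform=(0.0, 0.0, 0.0))
        seen_adenoma = False
        for pid in range(200):
            h = simulate_life_history(preset, life_table, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid)
            seen_adenoma = seen_adenoma or bool(h.adenomas)
            assert h.clinical_dx_age is None
        assert seen_adenoma

    def test_homogeneous_poisson_onset_closed_form(self):
        # constant hazard, zero frailty: P(>=1 adenoma by age a) = 1 - exp(-lam*a)
        lam, a = 0.02, 60.0
        lt = uniform_life_table(0.0, max_age=70)  # everyone alive through age a
        preset = flat_preset(onset_rate=lam, frailty_var=0.0)
        n = 100_000
        hits = 0
        for pid in range(n):
            h = simulate_life_history(preset, lt, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid)
            hits += any(ad.onset_age <= a for ad in h.adenomas)
        p_hat = hits / n
        p = 1 - math.exp(-lam * a)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 4 * se

    def test_determinism_and_event_ordering(self, presets, life_table):
        preset = presets[0]
        for pid in range(300):
            h1 = simulate_life_history(preset, life_table, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid)
            h2 = simulate_life_history(preset, life_table, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid)
            assert h1.death_age == h2.death_age
            assert [a.onset_age for a in h1.adenomas] == [a.onset_age for a in h2.adenomas]
            for a in h1.adenomas:
                if a.transform_age is not None:
                    assert a.onset_age < a.transform_age
                    if a.clinical_dx_age is not None:
                        assert a.transform_age < a.clinical_dx_age
            if h1.cause == "CRC":
                assert h1.clinical_dx_age is not None
                assert h1.clinical_dx_age < h1.crc_death_age
                assert h1.death_age == h1.crc_death_age <= h1.other_cause_death_age
            assert h1.death_age <= h1.other_cause_death_age

    def test_life_table_consistency_without_disease(self, life_table):
        # with no adenomas, mean simulated lifespan equals the life-table expectation
        preset = flat_preset(onset_rate=0.0)
        n = 20_000
        deaths = np.array(
            [
                simulate_life_history(preset, life_table, 1970.25, person_rng(SUITE_SEED, pid), person_id=pid).death_age
                for pid in range(n)
            ]
        )
        expect = life_table.expected_remaining_life(0.0)
        se = deaths.std(ddof=1) / math.sqrt(n)
        assert abs(deaths.mean() - expect) < 3 * se

    def test_negative_hazard_rejected(self):
        with pytest.raises(ConfigurationError):
            flat_preset(onset_rate=-0.01)


class TestSizeClass:
    def test_starts_small_and_grows_monotonically(self, presets):
        preset = presets[0]
        a = make_person([{"onset": 50.0, "rate": 0.5}]).adenomas[0]
        assert lesion_size_class(a, 50.0, preset) is SizeClass.SMALL
        classes = [int(lesion_size_class(a, age, preset)) for age in np.linspace(50, 90, 81)]
        assert classes == sorted(classes)

    def test_zero_growth_stays_small(self, presets):
        a = make_person([{"onset": 50.0, "rate": 0.0}]).adenomas[0]
        assert lesion_size_class(a, 89.0, presets[0]) is SizeClass.SMALL

    def test_threshold_bracketing(self, presets):
        # rate 0.5 mm/y from 1 mm: crosses 6 mm at +10 y and 10 mm at +18 y
        preset = presets[0]
        a = make_person([{"onset": 50.0, "rate": 0.5}]).adenomas[0]
        eps = 1e-6
        assert lesion_size_class(a, 60.0 - eps, preset) is SizeClass.SMALL
        assert lesion_size_class(a, 60.0 + eps, preset) is SizeClass.MEDIUM
        assert lesion_size_class(a, 68.0 - eps, preset) is SizeClass.MEDIUM
        assert lesion_size_class(a, 68.0 + eps, preset) is SizeClass.LARGE

    def test_before_onset_rejected(self, presets):
        a = make_person([{"onset": 50.0}]).adenomas[0]
        with pytest.raises(ValueError):
            lesion_size_class(a, 49.0, presets[0])


class TestCrcSurvival:
    def test_point_mass_at_zero(self):
        assert survival_quantile(SurvivalParams(0.0, 0.0), 0.3) == 0.0

    def test_cure_fraction_is_top_of_distribution(self):
        p = SurvivalParams(0.4, 5.0)
        assert math.isinf(survival_quantile(p, 0.75))
        assert math.isfinite(survival_quantile(p, 0.55))

    def test_mean_matches_configured_distribution(self, presets):
        preset = presets[0]
        rng = person_rng(SUITE_SEED, 10)
        n = 100_000
        draws = np.array([crc_death_age(preset, 60.0, DetectionMode.CLINICAL, rng) for _ in range(n)])
        finite = draws[np.isfinite(draws)] - 60.0
        params = preset.survival_clinical
        frac_fatal = len(finite) / n
        se_frac = math.sqrt(frac_fatal * (1 - frac_fatal) / n)
        assert abs(frac_fatal - (1 - params.cure_probability)) < 4 * se_frac
        se_mean = finite.std(ddof=1) / math.sqrt(len(finite))
        assert abs(finite.mean() - params.exp_mean_years) < 4 * se_mean

    @pytest.mark.parametrize("preset_idx", [0, 1])
    def test_screen_detected_survival_dominates(self, presets, preset_idx):
        preset = presets[preset_idx]
        for u in np.linspace(0.001, 0.999, 199):
            s = survival_quantile(preset.survival_screen, u)
            c = survival_quantile(preset.survival_clinical, u)
            assert s >= c

    def test_death_after_diagnosis(self, presets):
        rng = person_rng(SUITE_SEED, 11)
        for _ in range(200):
            d = crc_death_age(presets[0], 55.0, DetectionMode.SCREEN, rng)
            assert d >= 55.0
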