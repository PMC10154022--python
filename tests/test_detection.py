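"""Colonoscopy and FIT result generation against the bundled sensitivity table."""

import math

import pytest

from crc_disrupt import (
    Modality,
    TestProfile,
    colonoscopy_exam,
    diagnostic_colonoscopy_after_positive_fit,
    fit_exam,
    person_rng,
)
from crc_disrupt.detection import prevalent_lesions

from .conftest import SUITE_SEED, make_person


def binom_se(p, n):
    return math.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def high(profiles):
    return profiles["colonoscopy"]["high"]


@pytest.fixture(scope="module")
def low(profiles):
    return profiles["colonoscopy"]["low"]


class TestColonoscopy:
    def test_perfect_sensitivity_detects_everything(self, presets):
        profile = TestProfile(Modality.COLONOSCOPY, 1.0, 1.0, 1.0, 1.0, 0.86)
        person = make_person([{"onset": 40.0, "rate": 0.1}, {"onset": 50.0, "rate": 0.6}, {"onset": 55.0, "rate": 2.0}])
        rng = person_rng(SUITE_SEED, 0)
        res = colonoscopy_exam(person, 60.0, profile, rng, presets[0])
        assert len(res.detected_adenomas) == 3 and not res.detected_cancer

    def test_large_adenoma_detection_frequency(self, presets, high):
        # one >=10 mm lesion, high-sensitivity profile: detection rate ~ 0.95
        person = make_person([{"onset": 40.0, "rate": 1.0}])
        rng = person_rng(SUITE_SEED, 1)
        n = 30_000
        hits = sum(
            bool(colonoscopy_exam(person, 60.0, high, rng, presets[0]).detected_adenomas) for _ in range(n)
        )
        assert abs(hits / n - 0.95) < 4 * binom_se(0.95, n)

    def test_independent_detection_product(self, presets, high):
        # one small + one medium lesion: P(>=1 detected) = 1-(1-0.75)(1-0.85)
        person = make_person([{"onset": 59.9, "rate": 0.5}, {"onset": 48.0, "rate": 0.5}])
        rng = person_rng(SUITE_SEED, 2)
        n = 30_000
        hits = sum(
            bool(colonoscopy_exam(person, 60.0, high, rng, presets[0]).detected_adenomas) for _ in range(n)
        )
        p = 1 - (1 - 0.75) * (1 - 0.85)
        assert abs(hits / n - p) < 4 * binom_se(p, n)

    def test_sensitivity_monotone_in_size_class(self, high, low):
        for profile in (high, low):
            assert profile.sens_small <= profile.sens_medium <= profile.sens_large

    def test_low_detections_subset_of_high_with_shared_draws(self, presets, high, low):
        person = make_person(
            [{"onset": 40.0, "rate": 1.0}, {"onset": 50.0, "rate": 0.6}, {"onset": 58.0, "rate": 0.4}]
        )
        for rep in range(300):
            ids_low = {
                a.lesion_id
                for a in colonoscopy_exam(person, 60.0, low, person_rng(SUITE_SEED, rep), presets[0]).detected_adenomas
            }
            ids_high = {
                a.lesion_id
                for a in colonoscopy_exam(person, 60.0, high, person_rng(SUITE_SEED, rep), presets[0]).detected_adenomas
            }
            assert ids_low <= ids_high

    def test_out_of_reach_lesion_never_detected(self, presets, high):
        person = make_person([{"onset": 40.0, "rate": 1.0, "reach": False}])
        rng = person_rng(SUITE_SEED, 3)
        for _ in range(200):
            assert not colonoscopy_exam(person, 60.0, high, rng, presets[0]).detected_adenomas

    def test_preclinical_cancer_detection_ends_screening(self, presets, high):
        person = make_person([{"onset": 40.0, "rate": 1.0, "transform": 55.0, "sojourn": 8.0}])
        rng = person_rng(SUITE_SEED, 4)
        n = 20_000
        hits = sum(colonoscopy_exam(person, 60.0, high, rng, presets[0]).detected_cancer for _ in range(n))
        assert abs(hits / n - 0.95) < 4 * binom_se(0.95, n)

    def test_exam_after_death_rejected(self, presets, high):
        person = make_person([], ocd=70.0)
        with pytest.raises(ValueError):
            colonoscopy_exam(person, 71.0, high, person_rng(SUITE_SEED, 5), presets[0])

    def test_underlying_history_never_mutated(self, presets, high):
        person = make_person([{"onset": 40.0, "rate": 1.0}])
        before = [(a.lesion_id, a.onset_age) for a in person.adenomas]
        colonoscopy_exam(person, 60.0, high, person_rng(SUITE_SEED, 6), presets[0])
        assert [(a.lesion_id, a.onset_age) for a in person.adenomas] == before

    def test_removed_lesions_are_invisible(self, presets):
        profile = TestProfile(Modality.COLONOSCOPY, 1.0, 1.0, 1.0, 1.0, 0.86)
        person = make_person([{"onset": 40.0, "rate": 1.0}, {"onset": 50.0, "rate": 0.5}])
        res = colonoscopy_exam(person, 60.0, profile, person_rng(SUITE_SEED, 7), presets[0], removed=[0])
        assert {a.lesion_id for a in res.detected_adenomas} == {1}


class TestFit:
    def test_lesion_free_positivity_is_one_minus_specificity(self, presets, profiles):
        person = make_person([])
        for key in ("crcspin", "miscan"):
            profile = profiles["fit"][key]
            rng = person_rng(SUITE_SEED, 8)
            n = 30_000
            hits = sum(fit_exam(person, 60.0, profile, rng, presets[0]).positive for _ in range(n))
            assert abs(hits / n - 0.03) < 4 * binom_se(0.03, n)

    def test_per_person_mode_uses_most_advanced_lesion(self, presets, profiles):
        # most advanced lesion >=10 mm: positivity ~ 0.22 under the per-person profile
        profile = profiles["fit"]["crcspin"]
        person = make_person([{"onset": 40.0, "rate": 1.0}, {"onset": 59.0, "rate": 0.5}])
        rng = person_rng(SUITE_SEED, 9)
        n = 30_000
        hits = sum(fit_exam(person, 60.0, profile, rng, presets[0]).positive for _ in range(n))
        assert abs(hits / n - 0.22) < 4 * binom_se(0.22, n)

    def test_per_lesion_mode_independence_product(self, presets, profiles):
        # two 6-9 mm lesions at sensitivity 0.114 plus the bleeding channel:
        # P(positive) = 1 - (1-0.114)^2 * 0.97
        profile = profiles["fit"]["miscan"]
        person = make_person([{"onset": 50.0, "rate": 0.5}, {"onset": 49.0, "rate": 0.55}])
        rng = person_rng(SUITE_SEED, 10)
        n = 30_000
        hits = sum(fit_exam(person, 60.0, profile, rng, presets[1]).positive for _ in range(n))
        p = 1 - (1 - 0.114) ** 2 * 0.97
        assert abs(hits / n - p) < 4 * binom_se(p, n)

    def test_small_adenomas_never_trigger_lesion_mode_fit(self, presets, profiles):
        # preset-B FIT small-adenoma sensitivity is exactly 0; only the
        # bleeding channel can fire
        profile = profiles["fit"]["miscan"]
        person = make_person([{"onset": 59.5, "rate": 0.3}])
        rng = person_rng(SUITE_SEED, 11)
        n = 30_000
        hits = sum(fit_exam(person, 60.0, profile, rng, presets[1]).positive for _ in range(n))
        assert abs(hits / n - 0.03) < 4 * binom_se(0.03, n)

    def test_early_late_preclinical_split(self, presets, profiles):
        profile = profiles["fit"]["miscan"]
        person = make_person([{"onset": 40.0, "rate": 1.0, "transform": 58.0, "sojourn": 6.0}])
        rng = person_rng(SUITE_SEED, 12)
        n = 30_000
        # age 60: 2/6 through sojourn -> early sensitivity 0.62565 (plus bleeding)
        hits_early = sum(fit_exam(person, 60.0, profile, rng, presets[1]).positive for _ in range(n))
        p_early = 1 - (1 - 0.62565) * 0.97
        assert abs(hits_early / n - p_early) < 4 * binom_se(p_early, n)
        # age 63: 5/6 through sojourn -> late sensitivity 0.886
        hits_late = sum(fit_exam(person, 63.0, profile, rng, presets[1]).positive for _ in range(n))
        p_late = 1 - (1 - 0.886) * 0.97
        assert abs(hits_late / n - p_late) < 4 * binom_se(p_late, n)


class TestDiagnosticColonoscopy:
    def test_follows_positive_fit_and_removes_lesion(self, presets, profiles, high):
        person = make_person([{"onset": 40.0, "rate": 1.0}])
        rng = person_rng(SUITE_SEED, 13)
        n = 20_000
        removed = 0
        positives = 0
        for _ in range(n):
            fit = fit_exam(person, 60.0, profiles["fit"]["crcspin"], rng, presets[0])
            if fit.positive:
                positives += 1
                res = diagnostic_colonoscopy_after_positive_fit(person, 60.0, high, rng, presets[0])
                removed += bool(res.detected_adenomas)
        assert positives > 0
        assert abs(removed / positives - 0.95) < 4 * binom_se(0.95, positives)

    def test_preclinical_cancer_found_with_preclinical_sensitivity(self, presets, high):
        person = make_person([{"onset": 40.0, "rate": 1.0, "transform": 55.0, "sojourn": 9.0}])
        rng = person_rng(SUITE_SEED, 14)
        n = 20_000
        hits = sum(
            diagnostic_colonoscopy_after_positive_fit(person, 60.0, high, rng, presets[0]).detected_cancer
            for _ in range(n)
        )
        assert abs(hits / n - 0.95) < 4 * binom_se(0.95, n)


class TestPrevalentLesions:
    def test_partitions_by_transformation(self, presets):
        person = make_person(
            [
                {"onset": 40.0, "rate": 0.5, "transform": 55.0, "sojourn": 5.0},
                {"onset": 50.0, "rate": 0.5},
            ]
        )
        adenomas, cancers = prevalent_lesions(person, 58.0)
        assert [a.lesion_id for a in adenomas] == [1]
        assert [c.lesion_id for c in cancers] == [0]
        # after the latent clinical surfacing age the lesion is no longer preclinical
        adenomas, cancers = prevalent_lesions(person, 61.0)
        assert cancers == []

    def test_future_lesions_invisible(self, presets):
        person = make_person([{"onset": 65.0, "rate": 0.5}])
        adenomas, cancers = prevalent_lesions(person, 60.0)
        assert adenomas == [] and cancers == []
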