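"""Screening-test result generation: colonoscopy and FIT.

Colonoscopy detects each prevalent within-reach adenoma independently with a
size-class sensitivity and detects preclinical cancer with its own
sensitivity; detected adenomas are removed *in the consuming scenario* (the
underlying natural history is never mutated).  FIT positivity comes in two
flavours, matching the two model traditions this package emulates:

* ``per_person`` -- the test is positive with the sensitivity of the most
  advanced lesion present (or 1 - specificity when lesion-free);
* ``per_lesion`` -- every lesion triggers its own Bernoulli draw, OR-ed with
  an other-cause-bleeding draw at 1 - specificity that is independent of
  adenoma status.

Colonoscopy specificity is carried in the profile for completeness but is not
used in simulation: false-positive colonoscopies only matter for burden
outcomes, which are out of scope here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .natural_history import Adenoma, LifeHistory, ModelPreset, SizeClass, lesion_size_class

__all__ = [
    "Modality",
    "ExamKind",
    "TestProfile",
    "ExamResult",
    "prevalent_lesions",
    "colonoscopy_exam",
    "fit_exam",
    "diagnostic_colonoscopy_after_positive_fit",
]


class Modality(str, enum.Enum):
    COLONOSCOPY = "colonoscopy"
    FIT = "FIT"


class ExamKind(str, enum.Enum):
    SCREENING = "screening"
    DIAGNOSTIC = "diagnostic"
    SURVEILLANCE = "surveillance"


@dataclass(frozen=True)
class TestProfile:
    """Per-size-class sensitivities and specificity for one modality.

    ``sens_preclinical`` is a single probability, or an (early, late) pair for
    stool tests whose preclinical sensitivity depends on how far through the
    sojourn the cancer is (the split is at the sojourn midpoint).
    """

    modality: Modality
    sens_small: float
    sens_medium: float
    sens_large: float
    sens_preclinical: Union[float, tuple]
    specificity: float
    positivity_mode: str = "per_lesion"  # colonoscopy is inherently per-lesion
    scenario_label: str = ""

    def __post_init__(self) -> None:
        probs = [self.sens_small, self.sens_medium, self.sens_large, self.specificity]
        if isinstance(self.sens_preclinical, (int, float)):
            probs.append(float(self.sens_preclinical))
        else:
            probs.extend(self.sens_preclinical)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("test probabilities must lie in [0, 1]")
        if self.positivity_mode not in ("per_lesion", "per_person"):
            raise ValueError("positivity mode must be per_lesion or per_person")

    def sensitivity(self, size: SizeClass) -> float:
        return (self.sens_small, self.sens_medium, self.sens_large)[int(size) - 1]

    def preclinical_sensitivity(self, stage_fraction: float) -> float:
        """Sensitivity for preclinical cancer at ``stage_fraction`` of sojourn."""
        s = self.sens_preclinical
        if isinstance(s, (int, float)):
            return float(s)
        early, late = s
        return float(early) if stage_fraction < 0.5 else float(late)


@dataclass
class ExamResult:
    """Outcome of one exam.

    ``detected_adenomas`` lists the lesions found and removed (colonoscopy
    only); a detected cancer ends the screening process.
    """

    exam_age: float
    exam_kind: ExamKind
    modality: Modality
    positive: bool = False
    detected_adenomas: tuple = ()
    detected_cancer: bool = False


def prevalent_lesions(
    history: LifeHistory,
    age: float,
    removed: Sequence[int] = (),
) -> tuple:
    """Split the person's unremoved lesions at ``age`` into (adenomas, preclinical cancers).

    A lesion is an adenoma from onset until its (latent) transformation age,
    and a preclinical cancer from transformation until clinical diagnosis.
    """
    removed_set = set(removed)
    adenomas = []
    cancers = []
    for a in history.adenomas:
        if a.lesion_id in removed_set or a.onset_age > age:
            continue
        if a.transform_age is not None and age >= a.transform_age:
            dx = a.clinical_dx_age
            if dx is None or age < dx:
                cancers.append(a)
        else:
            adenomas.append(a)
    return adenomas, cancers


def _check_exam_pre(history: LifeHistory, age: float, diagnosed: bool) -> None:
    if age >= history.other_cause_death_age:
        raise ValueError("exam scheduled after death")
    if diagnosed:
        raise ValueError("exam scheduled after CRC diagnosis")


def colonoscopy_exam(
    history: LifeHistory,
    age: float,
    profile: TestProfile,
    rng_stream: np.random.Generator,
    preset: ModelPreset,
    removed: Sequence[int] = (),
    exam_kind: ExamKind = ExamKind.SCREENING,
    already_diagnosed: bool = False,
) -> ExamResult:
    """One colonoscopy: independent per-lesion detection, cancer detection.

    One uniform is drawn per prevalent within-reach lesion in onset order (and
    one per preclinical cancer), so profiles sharing a stream state detect
    nested lesion sets when one profile dominates the other component-wise.
    """
    if profile.modality is not Modality.COLONOSCOPY:
        raise ValueError("profile is not a colonoscopy profile")
    _check_exam_pre(history, age, already_diagnosed)
    adenomas, cancers = prevalent_lesions(history, age, removed)
    detected = []
    for a in adenomas:
        u = rng_stream.random()
        if a.within_reach and u < profile.sensitivity(lesion_size_class(a, age, preset)):
            detected.append(a)
    detected_cancer = False
    for c in cancers:
        u = rng_stream.random()
        if not c.within_reach:
            continue
        stage = _stage_fraction(c, age)
        if u < profile.preclinical_sensitivity(stage):
            detected_cancer = True
    return ExamResult(
        exam_age=age,
        exam_kind=exam_kind,
        modality=Modality.COLONOSCOPY,
        positive=bool(detected or detected_cancer),
        detected_adenomas=tuple(detected),
        detected_cancer=detected_cancer,
    )


def _stage_fraction(lesion: Adenoma, age: float) -> float:
    """Fraction of the preclinical sojourn elapsed at ``age``."""
    if lesion.transform_age is None or lesion.sojourn_years in (None, 0):
        return 0.0
    return min(max((age - lesion.transform_age) / lesion.sojourn_years, 0.0), 1.0)


def _most_advanced(adenomas: list, cancers: list, age: float, preset: ModelPreset):
    """Most advanced lesion: preclinical cancer beats any adenoma, then size."""
    if cancers:
        return max(cancers, key=lambda c: _stage_fraction(c, age))
    if adenomas:
        return max(adenomas, key=lambda a: int(lesion_size_class(a, age, preset)))
    return None


def fit_exam(
    history: LifeHistory,
    age: float,
    profile: TestProfile,
    rng_stream: np.random.Generator,
    preset: ModelPreset,
    removed: Sequence[int] = (),
    already_diagnosed: bool = False,
) -> ExamResult:
    """One FIT result under the profile's positivity mode."""
    if profile.modality is not Modality.FIT:
        raise ValueError("profile is not a FIT profile")
    _check_exam_pre(history, age, already_diagnosed)
    adenomas, cancers = prevalent_lesions(history, age, removed)
    fp_rate = 1.0 - profile.specificity
    positive = False
    if profile.positivity_mode == "per_person":
        lesion = _most_advanced(adenomas, cancers, age, preset)
        if lesion is None:
            positive = rng_stream.random() < fp_rate
        else:
            if lesion.transform_age is not None and age >= lesion.transform_age:
                p = profile.preclinical_sensitivity(_stage_fraction(lesion, age))
            else:
                p = profile.sensitivity(lesion_size_class(lesion, age, preset))
            positive = rng_stream.random() < p
    else:
        for a in adenomas:
            if rng_stream.random() < profile.sensitivity(lesion_size_class(a, age, preset)):
                positive = True
        for c in cancers:
            if rng_stream.random() < profile.preclinical_sensitivity(_stage_fraction(c, age)):
                positive = True
        # other-cause bleeding, independent of adenoma status
        if rng_stream.random() < fp_rate:
            positive = True
    return ExamResult(
        exam_age=age,
        exam_kind=ExamKind.SCREENING,
        modality=Modality.FIT,
        positive=bool(positive),
    )


def diagnostic_colonoscopy_after_positive_fit(
    history: LifeHistory,
    age: float,
    colo_profile: TestProfile,
    rng_stream: np.random.Generator,
    preset: ModelPreset,
    removed: Sequence[int] = (),
) -> ExamResult:
    """Diagnostic colonoscopy triggered by a positive FIT at the same age."""
    return colonoscopy_exam(
        history,
        age,
        colo_profile,
        rng_stream,
        preset,
        removed=removed,
        exam_kind=ExamKind.DIAGNOSTIC,
    )
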