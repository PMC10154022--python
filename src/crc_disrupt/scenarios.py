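"""Cohorts, disruption scenarios and the counterfactual replay engine.

Eight pre-pandemic cohorts are defined by their age in April 2020 and their
screening history (e.g. C70 received screening colonoscopies at ages 50 and
60).  Each scenario pairs a cohort with a post-pandemic disruption: short
delays of 3/9/18 months carried forward to all later exams, long-term delays
to the Medicare age (65) or to 75, a permanent switch from colonoscopy to
annual FIT (a boundary case), or total discontinuation (the worst-case
boundary).  Scenario codes follow the ``[cohort] | [disruption]`` grammar,
e.g. ``"C60 | F18m"`` or ``"F70 | U"``.

Every person's latent natural history is drawn once and replayed against each
scenario's exam schedule (common random numbers), so scenario contrasts
isolate the effect of the disruption.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import (
    ExamKind,
    Modality,
    TestProfile,
    colonoscopy_exam,
    diagnostic_colonoscopy_after_positive_fit,
    fit_exam,
)
from .natural_history import (
    DOMAIN_SCREENING,
    ConfigurationError,
    DetectionMode,
    LifeHistory,
    ModelPreset,
    person_rng,
    survival_quantile,
)
from .policy import (
    PlannedExam,
    ScheduleMachine,
    ScreeningPolicy,
    SurveillanceTable,
    classify_findings,
    default_surveillance_table,
)

__all__ = [
    "PANDEMIC_CALENDAR_TIME",
    "DisruptionType",
    "Disruption",
    "CohortSpec",
    "Scenario",
    "make_cohort",
    "build_counterfactual_schedule",
    "apply_disruption",
    "parse_scenario_code",
    "all_scenario_labels",
    "run_scenario",
    "unscreened_outcomes",
]

#: Pandemic onset: April 2020.
PANDEMIC_CALENDAR_TIME = 2020.25

COHORT_CODES = ("U50", "U60", "C60", "F60", "f60", "U70", "C70", "F70")

COHORT_AGES = {"U50": 50, "U60": 60, "C60": 60, "F60": 60, "f60": 60, "U70": 70, "C70": 70, "F70": 70}

#: Pre-pandemic exam ages by cohort (all strictly before April 2020).
_PRE_PANDEMIC = {
    "U50": [],
    "U60": [],
    "C60": [(50, Modality.COLONOSCOPY)],
    "F60": [(a, Modality.FIT) for a in range(50, 60)],
    "f60": [(a, Modality.FIT) for a in (50, 52, 54, 56)],
    "U70": [],
    "C70": [(50, Modality.COLONOSCOPY), (60, Modality.COLONOSCOPY)],
    "F70": [(a, Modality.FIT) for a in range(50, 70)],
}

#: Post-pandemic counterfactual routine exam ages by (cohort, arm modality).
_POST_PANDEMIC = {
    ("U50", Modality.COLONOSCOPY): [50, 60, 70],
    ("U50", Modality.FIT): list(range(50, 76)),
    ("U60", Modality.COLONOSCOPY): [60, 70],
    ("U60", Modality.FIT): list(range(60, 76)),
    ("C60", Modality.COLONOSCOPY): [60, 70],
    ("F60", Modality.FIT): list(range(60, 76)),
    ("f60", Modality.FIT): list(range(60, 76)),
    ("U70", Modality.COLONOSCOPY): [70],
    ("U70", Modality.FIT): list(range(70, 76)),
    ("C70", Modality.COLONOSCOPY): [70],
    ("F70", Modality.FIT): list(range(70, 76)),
}


class DisruptionType(str, enum.Enum):
    NONE = "none"
    SHORT_DELAY = "short_delay"
    LONG_DELAY_TO_AGE = "long_delay_to_age"
    SWITCH_TO_FIT = "switch_to_fit"
    DISCONTINUE = "discontinue"


@dataclass(frozen=True)
class Disruption:
    """A post-pandemic disruption; delays apply from April 2020 onward only."""

    type: DisruptionType
    delay_months: int = 0      # 3 / 9 / 18 for short delays and switches
    resume_age: int = 0        # 65 or 75 for long delays

    def __post_init__(self) -> None:
        if self.type in (DisruptionType.SHORT_DELAY, DisruptionType.SWITCH_TO_FIT):
            if self.delay_months not in (3, 9, 18):
                raise ConfigurationError("short delays are 3, 9 or 18 months")
        if self.type is DisruptionType.LONG_DELAY_TO_AGE and self.resume_age not in (65, 75):
            raise ConfigurationError("long delays resume at age 65 or 75")

    @property
    def delay_years(self) -> float:
        return self.delay_months / 12.0


@dataclass(frozen=True)
class CohortSpec:
    """A pre-pandemic cohort plus the counterfactual (no-disruption) arm."""

    code: str
    age_2020: float
    arm_modality: Modality
    pre_pandemic_exams: tuple
    counterfactual_exam_ages: tuple
    policy: ScreeningPolicy

    @property
    def birth_year(self) -> float:
        return PANDEMIC_CALENDAR_TIME - self.age_2020


def make_cohort(code: str, arm_modality: Optional[Modality] = None) -> CohortSpec:
    """Build a cohort spec; U-cohorts need the counterfactual arm modality."""
    if code not in COHORT_CODES:
        raise ConfigurationError(f"unknown cohort code {code!r}; valid: {COHORT_CODES}")
    if arm_modality is None:
        if code.startswith("U"):
            raise ConfigurationError(f"cohort {code} needs an explicit counterfactual modality")
        arm_modality = Modality.COLONOSCOPY if code.startswith("C") else Modality.FIT
    key = (code, arm_modality)
    if key not in _POST_PANDEMIC:
        raise ConfigurationError(f"cohort {code} has no {arm_modality.value} counterfactual arm")
    age = COHORT_AGES[code]
    if arm_modality is Modality.COLONOSCOPY:
        pol = ScreeningPolicy(Modality.COLONOSCOPY, start_age=50, stop_age=70, interval=10)
    else:
        pol = ScreeningPolicy(Modality.FIT, start_age=50, stop_age=75, interval=1)
    return CohortSpec(
        code=code,
        age_2020=float(age),
        arm_modality=arm_modality,
        pre_pandemic_exams=tuple(_PRE_PANDEMIC[code]),
        counterfactual_exam_ages=tuple(_POST_PANDEMIC[key]),
        policy=pol,
    )


def build_counterfactual_schedule(cohort: CohortSpec) -> List[PlannedExam]:
    """Planned routine exam sequence (pre- plus post-pandemic, no disruption)."""
    exams = [PlannedExam(float(a), m, ExamKind.SCREENING) for a, m in cohort.pre_pandemic_exams]
    exams += [
        PlannedExam(float(a), cohort.arm_modality, ExamKind.SCREENING)
        for a in cohort.counterfactual_exam_ages
    ]
    exams.sort(key=lambda e: e.age)
    return exams


def apply_disruption(
    schedule: Sequence[PlannedExam],
    disruption: Disruption,
    cohort: CohortSpec,
) -> List[PlannedExam]:
    """Disrupted routine backbone.

    Short delays shift the first post-pandemic exam and carry the shift
    forward; long delays replace the post-pandemic plan with explicit
    colonoscopies at the resume ages; switching replaces it with annual FIT
    (shifted by the switch's own delay); discontinuation empties it.
    """
    pandemic_age = cohort.age_2020
    pre = [e for e in schedule if e.age < pandemic_age - 1e-9]
    post = [e for e in schedule if e.age >= pandemic_age - 1e-9]
    d = disruption
    if d.type is DisruptionType.NONE:
        return list(schedule)
    if d.type is DisruptionType.SHORT_DELAY:
        shifted = [replace(e, age=e.age + d.delay_years) for e in post]
        return pre + shifted
    if d.type is DisruptionType.DISCONTINUE:
        return pre
    if d.type is DisruptionType.LONG_DELAY_TO_AGE:
        if cohort.arm_modality is not Modality.COLONOSCOPY:
            raise ConfigurationError("long delays are defined for colonoscopy arms")
        ages = [65.0, 75.0] if d.resume_age == 65 else [75.0]
        return pre + [PlannedExam(a, Modality.COLONOSCOPY, ExamKind.SCREENING) for a in ages]
    if d.type is DisruptionType.SWITCH_TO_FIT:
        if cohort.arm_modality is not Modality.COLONOSCOPY or not post:
            raise ConfigurationError("switching to FIT applies to colonoscopy cohorts")
        first_due = post[0].age
        fit_ages = [a + d.delay_years for a in np.arange(first_due, 75.0 + 1e-9, 1.0)]
        return pre + [PlannedExam(float(a), Modality.FIT, ExamKind.SCREENING) for a in fit_ages]
    raise ConfigurationError(f"unknown disruption {d.type}")


# --------------------------------------------------------------------------
# Scenario grammar
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    cohort: CohortSpec
    disruption: Disruption
    sensitivity_scenario: str = "high"

    def __post_init__(self) -> None:
        if self.sensitivity_scenario not in ("high", "low"):
            raise ConfigurationError("sensitivity scenario must be 'high' or 'low'")
        _validate_combination(self.cohort, self.disruption)

    @property
    def label(self) -> str:
        d = self.disruption
        arm = "C" if self.cohort.arm_modality is Modality.COLONOSCOPY else "F"
        if d.type is DisruptionType.NONE:
            tail = arm
        elif d.type is DisruptionType.SHORT_DELAY:
            tail = f"{arm}{d.delay_months}m"
        elif d.type is DisruptionType.SWITCH_TO_FIT:
            tail = f"F{d.delay_months}m"
        elif d.type is DisruptionType.LONG_DELAY_TO_AGE:
            tail = f"C@{d.resume_age}"
        else:
            tail = "U"
        return f"{self.cohort.code} | {tail}"


_SHORT_OR_SWITCH = re.compile(r"^([CF])(\d+)m$")
_LONG = re.compile(r"^C@(\d+)$")

#: Disruption families defined for each cohort by the study grammar.
_VALID_FAMILIES: Dict[str, tuple] = {
    "U50": ("Cdm", "C@65", "Fdm"),
    "U60": ("Cdm", "C@65", "Fdm"),
    "C60": ("Cdm", "Sdm", "C@65", "U"),
    "F60": ("Fdm", "U"),
    "f60": ("Fdm", "U"),
    "U70": ("Cdm", "C@75", "Fdm"),
    "C70": ("Cdm", "Sdm", "C@75", "U"),
    "F70": ("Fdm", "U"),
}


def _family(cohort_code: str, arm: Modality, d: Disruption) -> str:
    if d.type is DisruptionType.SHORT_DELAY:
        return "Cdm" if arm is Modality.COLONOSCOPY else "Fdm"
    if d.type is DisruptionType.SWITCH_TO_FIT:
        return "Sdm"
    if d.type is DisruptionType.LONG_DELAY_TO_AGE:
        return f"C@{d.resume_age}"
    if d.type is DisruptionType.DISCONTINUE:
        return "U"
    return "none"


def _validate_combination(cohort: CohortSpec, d: Disruption) -> None:
    fam = _family(cohort.code, cohort.arm_modality, d)
    if fam == "none":
        return
    if fam not in _VALID_FAMILIES[cohort.code]:
        raise ConfigurationError(
            f"disruption {fam!r} is not defined for cohort {cohort.code} in the study grammar"
        )


def parse_scenario_code(label: str, sensitivity_scenario: str = "high") -> Scenario:
    """Parse a ``"[cohort] | [disruption]"`` code into a Scenario.

    Examples: ``"C60 | F18m"`` (switch to FIT with an 18-month delay),
    ``"F70 | U"`` (discontinue), ``"U70 | C@75"`` (long delay),
    ``"U50 | C"`` (colonoscopy arm, no disruption).
    """
    parts = [p.strip() for p in label.split("|")]
    if len(parts) != 2 or parts[0] not in COHORT_CODES:
        raise ConfigurationError(
            f"malformed scenario code {label!r}; expected '[cohort] | [disruption]' with "
            f"cohort in {COHORT_CODES} and disruption like C3m/C9m/C18m, F3m/F9m/F18m, "
            "C@65, C@75, U, or a bare C/F for no disruption"
        )
    code, tail = parts
    own_fit = code[0] in ("F", "f")
    if tail == "U":
        arm = Modality.FIT if own_fit else Modality.COLONOSCOPY
        disr = Disruption(DisruptionType.DISCONTINUE)
    elif tail in ("C", "F"):
        arm = Modality.COLONOSCOPY if tail == "C" else Modality.FIT
        disr = Disruption(DisruptionType.NONE)
    elif m := _LONG.match(tail):
        arm = Modality.COLONOSCOPY
        disr = Disruption(DisruptionType.LONG_DELAY_TO_AGE, resume_age=int(m.group(1)))
    elif m := _SHORT_OR_SWITCH.match(tail):
        letter, months = m.group(1), int(m.group(2))
        if letter == "F" and code.startswith("C"):
            arm = Modality.COLONOSCOPY  # counterfactual stays colonoscopy; disruption switches
            disr = Disruption(DisruptionType.SWITCH_TO_FIT, delay_months=months)
        else:
            arm = Modality.COLONOSCOPY if letter == "C" else Modality.FIT
            disr = Disruption(DisruptionType.SHORT_DELAY, delay_months=months)
    else:
        raise ConfigurationError(f"malformed disruption code {tail!r} in {label!r}")
    cohort = make_cohort(code, arm)
    return Scenario(cohort=cohort, disruption=disr, sensitivity_scenario=sensitivity_scenario)


def all_scenario_labels() -> List[str]:
    """Every disruption scenario label defined by the study grammar."""
    labels = []
    for code, fams in _VALID_FAMILIES.items():
        for fam in fams:
            if fam in ("Cdm", "Fdm"):
                letter = fam[0]
                labels += [f"{code} | {letter}{d}m" for d in (3, 9, 18)]
            elif fam == "Sdm":
                labels += [f"{code} | F{d}m" for d in (3, 9, 18)]
            else:
                labels.append(f"{code} | {fam}")
    return labels


# --------------------------------------------------------------------------
# Replay engine
# --------------------------------------------------------------------------


_OUTCOME_COLUMNS = [
    "person_id",
    "death_age",
    "dx_age",
    "detection_mode",
    "crc_case",
    "crc_death",
    "pre_pandemic_dx",
    "n_colonoscopies",
]


def _replay_person(
    history: LifeHistory,
    backbone: List[PlannedExam],
    table: SurveillanceTable,
    colo_profile: TestProfile,
    fit_profile: TestProfile,
    preset: ModelPreset,
    rng: np.random.Generator,
    disruption: Disruption,
    pandemic_age: float,
) -> tuple:
    """Replay one person's latent history against a scenario's schedule.

    Returns (dx_age, detection_mode, n_colonoscopies).
    """
    machine = ScheduleMachine(backbone, table)
    removed: list = []
    ocd = history.other_cause_death_age
    now = -np.inf
    had_post_pandemic_exam = False
    n_colo = 0
    d = disruption
    while True:
        prop = machine.propose(now)
        if prop is not None and prop.kind is ExamKind.SURVEILLANCE and prop.age >= pandemic_age - 1e-9:
            if d.type is DisruptionType.DISCONTINUE:
                prop = None
            elif d.type is DisruptionType.LONG_DELAY_TO_AGE and prop.age < d.resume_age:
                prop = replace(prop, age=float(d.resume_age))
            elif (
                d.type in (DisruptionType.SHORT_DELAY, DisruptionType.SWITCH_TO_FIT)
                and not had_post_pandemic_exam
            ):
                prop = replace(prop, age=prop.age + d.delay_years)
        # earliest latent clinical surfacing among unremoved lesions
        removed_set = set(removed)
        dx_latent = min(
            (
                a.clinical_dx_age
                for a in history.adenomas
                if a.clinical_dx_age is not None and a.lesion_id not in removed_set
            ),
            default=np.inf,
        )
        exam_age = prop.age if prop is not None else np.inf
        if dx_latent < min(exam_age, ocd):
            return dx_latent, DetectionMode.CLINICAL, n_colo
        if prop is None or exam_age >= ocd:
            return None, None, n_colo
        # perform the exam
        if prop.modality is Modality.FIT:
            res = fit_exam(history, exam_age, fit_profile, rng, preset, removed=removed)
            colo_res = None
            if res.positive:
                colo_res = diagnostic_colonoscopy_after_positive_fit(
                    history, exam_age, colo_profile, rng, preset, removed=removed
                )
        else:
            colo_res = colonoscopy_exam(
                history, exam_age, colo_profile, rng, preset, removed=removed, exam_kind=prop.kind
            )
        if colo_res is not None:
            n_colo += 1
            if colo_res.detected_cancer:
                return exam_age, DetectionMode.SCREEN, n_colo
            removed.extend(a.lesion_id for a in colo_res.detected_adenomas)
            category = classify_findings(colo_res, preset)
            machine.record_colonoscopy(exam_age, category)
        machine.consume_backbone_exam(prop)
        had_post_pandemic_exam = had_post_pandemic_exam or exam_age >= pandemic_age - 1e-9
        now = exam_age + 1e-9


def _resolve_death(history: LifeHistory, preset: ModelPreset, dx_age, mode) -> tuple:
    """(death_age, crc_case, crc_death) from a replay's diagnosis event."""
    ocd = history.other_cause_death_age
    if dx_age is None:
        return ocd, False, False
    params = preset.survival_screen if mode is DetectionMode.SCREEN else preset.survival_clinical
    candidate = dx_age + survival_quantile(params, history.u_survival)
    if candidate < ocd:
        return candidate, True, True
    return ocd, True, False


def run_scenario(
    scenario: Scenario,
    population: Sequence[LifeHistory],
    colo_profiles: Dict[str, TestProfile],
    fit_profiles: Dict[str, TestProfile],
    preset: ModelPreset,
    seed: int,
    surveillance_table: Optional[SurveillanceTable] = None,
) -> pd.DataFrame:
    """Replay a whole population under one scenario.

    The per-person screening stream is keyed by (seed, person id) and is
    independent of the scenario, so identical schedules yield bit-identical
    outcomes and contrasts between scenarios are paired.
    """
    table = surveillance_table if surveillance_table is not None else default_surveillance_table()
    colo_profile = colo_profiles[scenario.sensitivity_scenario]
    fit_profile = fit_profiles[preset.fit_profile_key]
    cohort = scenario.cohort
    backbone = apply_disruption(build_counterfactual_schedule(cohort), scenario.disruption, cohort)
    pandemic_age = cohort.age_2020

    rows = []
    for h in population:
        if not h.adenomas:
            # screening cannot alter a lesion-free life course
            dx_age, mode, n_colo = None, None, 0
        else:
            rng = person_rng(seed, h.person_id, DOMAIN_SCREENING)
            dx_age, mode, n_colo = _replay_person(
                h, backbone, table, colo_profile, fit_profile, preset, rng, scenario.disruption, pandemic_age
            )
        death, crc_case, crc_death = _resolve_death(h, preset, dx_age, mode)
        rows.append(
            (
                h.person_id,
                death,
                dx_age if dx_age is not None else np.nan,
                mode.value if mode is not None else "",
                crc_case,
                crc_death,
                bool(dx_age is not None and dx_age < pandemic_age),
                n_colo,
            )
        )
    return pd.DataFrame(rows, columns=_OUTCOME_COLUMNS)


def unscreened_outcomes(population: Sequence[LifeHistory], pandemic_age: float) -> pd.DataFrame:
    """Per-person outcomes in the complete absence of screening."""
    rows = []
    for h in population:
        dx = h.clinical_dx_age
        rows.append(
            (
                h.person_id,
                h.death_age,
                dx if dx is not None else np.nan,
                DetectionMode.CLINICAL.value if dx is not None else "",
                dx is not None,
                h.cause == "CRC",
                bool(dx is not None and dx < pandemic_age),
                0,
            )
        )
    return pd.DataFrame(rows, columns=_OUTCOME_COLUMNS)
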