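"""Screening and surveillance scheduling.

Routine regimens (decennial colonoscopy 50-70, annual FIT 50-75) are planned
exam grids; surveillance after adenoma detection follows the Multi-Society
Task Force intervals, expressed as a lookup on the findings at the two most
recent colonoscopies.  Where the MSTF gives a range, the shortest interval is
used.  Persons remain on surveillance until age 85, except that surveillance
continues past 85 while the most recent exam detected adenomas.

A person whose first screening or diagnostic colonoscopy is normal does not
enter surveillance; they resume their original screening modality 10 years
after the normal colonoscopy (or after the routine interval when that
exceeds 10 years).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .detection import ExamKind, ExamResult, Modality
from .natural_history import ConfigurationError

__all__ = [
    "FindingsCategory",
    "SurveillanceTable",
    "ScreeningPolicy",
    "ExamRecord",
    "ExamHistory",
    "PlannedExam",
    "classify_findings",
    "surveillance_interval",
    "next_event",
    "apply_stopping_rules",
    "default_surveillance_table",
]

SURVEILLANCE_STOP_AGE = 85.0


class FindingsCategory(str, enum.Enum):
    """Colonoscopy findings categories used by the surveillance table.

    "Small" means <10 mm; the large category covers 5-10 small adenomas or
    any adenoma >=10 mm.
    """

    NO_PRIOR = "no_prior"
    NORMAL = "normal"
    ADENOMA_1_2_SMALL = "adenoma_1_2_small"
    ADENOMA_3_4_SMALL = "adenoma_3_4_small"
    ADENOMA_5_10_SMALL_OR_ANY_LARGE = "adenoma_5_10_small_or_any_large"
    ADENOMA_GT10 = "adenoma_gt10"
    CRC = "crc"


_ADENOMA_CATEGORIES = frozenset(
    {
        FindingsCategory.ADENOMA_1_2_SMALL,
        FindingsCategory.ADENOMA_3_4_SMALL,
        FindingsCategory.ADENOMA_5_10_SMALL_OR_ANY_LARGE,
        FindingsCategory.ADENOMA_GT10,
    }
)


def classify_findings(result: ExamResult, preset, age: Optional[float] = None) -> FindingsCategory:
    """Deterministic findings category of a colonoscopy result."""
    if result.modality is not Modality.COLONOSCOPY:
        raise ValueError("findings categories apply to colonoscopy results only")
    if result.detected_cancer:
        return FindingsCategory.CRC
    from .natural_history import SizeClass, lesion_size_class

    exam_age = result.exam_age if age is None else age
    n = len(result.detected_adenomas)
    if n == 0:
        return FindingsCategory.NORMAL
    if n > 10:
        return FindingsCategory.ADENOMA_GT10
    any_large = any(
        lesion_size_class(a, exam_age, preset) is SizeClass.LARGE for a in result.detected_adenomas
    )
    if any_large or n >= 5:
        return FindingsCategory.ADENOMA_5_10_SMALL_OR_ANY_LARGE
    if n >= 3:
        return FindingsCategory.ADENOMA_3_4_SMALL
    return FindingsCategory.ADENOMA_1_2_SMALL


# --------------------------------------------------------------------------
# Surveillance intervals
# --------------------------------------------------------------------------


class SurveillanceTable:
    """(second-most-recent finding, most-recent finding) -> interval in years."""

    def __init__(self, mapping: dict):
        self.mapping = dict(mapping)
        for (second, first), years in self.mapping.items():
            if years not in (1, 3, 5, 7, 10):
                raise ConfigurationError(f"interval {years} outside the MSTF set")
            if first in (FindingsCategory.CRC, FindingsCategory.NO_PRIOR):
                raise ConfigurationError("most-recent finding cannot be CRC/no-prior")

    def interval(self, second: FindingsCategory, first: FindingsCategory) -> int:
        try:
            return self.mapping[(second, first)]
        except KeyError:
            raise ConfigurationError(f"no surveillance interval defined for ({second.value}, {first.value})")

    def to_csv(self, path) -> None:
        rows = [
            {"second_category": s.value, "first_category": f.value, "interval_years": y}
            for (s, f), y in sorted(self.mapping.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SurveillanceTable":
        df = pd.read_csv(path_or_buf)
        mapping = {
            (FindingsCategory(r.second_category), FindingsCategory(r.first_category)): int(r.interval_years)
            for r in df.itertuples()
        }
        return cls(mapping)


def default_surveillance_table() -> SurveillanceTable:
    """The bundled MSTF interval table (shortest interval of each range)."""
    ref = resources.files("crc_disrupt.data").joinpath("surveillance_intervals.csv")
    with ref.open("r") as fh:
        return SurveillanceTable.from_csv(fh)


def surveillance_interval(
    second: FindingsCategory, first: FindingsCategory, table: SurveillanceTable
) -> int:
    """Years until the next colonoscopy given the last two findings."""
    if first is FindingsCategory.CRC:
        raise ConfigurationError("no surveillance after a CRC diagnosis")
    return table.interval(second, first)


# --------------------------------------------------------------------------
# Policies, exam history and the scheduling state machine
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningPolicy:
    """A routine screening regimen."""

    modality: Modality
    start_age: float
    stop_age: float
    interval: float  # 10 for colonoscopy, 1 or 2 for FIT
    surveillance_stop_age: float = SURVEILLANCE_STOP_AGE

    def __post_init__(self) -> None:
        if not (self.start_age < self.stop_age <= self.surveillance_stop_age):
            raise ConfigurationError("need start_age < stop_age <= surveillance_stop_age")
        if self.interval <= 0:
            raise ConfigurationError("interval must be positive")

    def routine_ages(self) -> list:
        """Planned routine exam ages (inclusive of stop_age when on grid)."""
        ages = []
        a = self.start_age
        while a <= self.stop_age + 1e-9:
            ages.append(round(a, 9))
            a += self.interval
        return ages


@dataclass(frozen=True)
class PlannedExam:
    age: float
    modality: Modality
    kind: ExamKind


@dataclass
class ExamRecord:
    age: float
    modality: Modality
    kind: ExamKind
    category: Optional[FindingsCategory]  # colonoscopies only
    positive: bool = False


@dataclass
class ExamHistory:
    """Chronological exam records; ends at first CRC diagnosis or death."""

    records: list = field(default_factory=list)

    def append(self, record: ExamRecord) -> None:
        if self.records and record.age < self.records[-1].age:
            raise ValueError("exam records must be chronological")
        self.records.append(record)

    def colonoscopies(self) -> list:
        return [r for r in self.records if r.modality is Modality.COLONOSCOPY]


class ScheduleMachine:
    """Incremental scheduler combining a routine backbone with surveillance.

    The backbone is an explicit list of planned routine exams (possibly
    disruption-adjusted).  Adenoma findings at any colonoscopy move the person
    onto the surveillance track, which supersedes the routine backbone for
    good; a normal first/diagnostic colonoscopy outside surveillance imposes a
    10-year blackout on the backbone instead.
    """

    def __init__(self, backbone, table: SurveillanceTable, surveillance_stop_age: float = SURVEILLANCE_STOP_AGE):
        self.backbone = sorted(backbone, key=lambda e: e.age)
        self.table = table
        self.surveillance_stop_age = surveillance_stop_age
        self.idx = 0
        self.in_surveillance = False
        self.prev_category: Optional[FindingsCategory] = None
        self.last_category: Optional[FindingsCategory] = None
        self.last_colo_age: Optional[float] = None
        self.blackout_until = -float("inf")
        self.last_exam_found_adenomas = False

    # -- proposals --------------------------------------------------------

    def propose(self, now: float) -> Optional[PlannedExam]:
        """Next exam at or after ``now``, before any disruption adjustments."""
        if self.in_surveillance:
            second = self.prev_category if self.prev_category is not None else FindingsCategory.NO_PRIOR
            years = surveillance_interval(second, self.last_category, self.table)
            age = self.last_colo_age + years
            proposal = PlannedExam(age=age, modality=Modality.COLONOSCOPY, kind=ExamKind.SURVEILLANCE)
            if not self._surveillance_allowed(proposal.age):
                return None
            return proposal
        while self.idx < len(self.backbone):
            exam = self.backbone[self.idx]
            if exam.age < now - 1e-9 or exam.age < self.blackout_until - 1e-9:
                self.idx += 1
                continue
            return exam
        return None

    def _surveillance_allowed(self, proposed_age: float) -> bool:
        if proposed_age <= self.surveillance_stop_age + 1e-9:
            return True
        return self.last_exam_found_adenomas

    # -- state updates ----------------------------------------------------

    def record_colonoscopy(self, age: float, category: FindingsCategory) -> None:
        """Feed a colonoscopy finding (screening, diagnostic or surveillance)."""
        first_colonoscopy = self.last_category is None
        self.prev_category = self.last_category
        self.last_category = category
        self.last_colo_age = age
        self.last_exam_found_adenomas = category in _ADENOMA_CATEGORIES
        if category in _ADENOMA_CATEGORIES:
            if not self.in_surveillance:
                self.in_surveillance = True
                self.idx = len(self.backbone)  # surveillance supersedes routine
        elif category is FindingsCategory.NORMAL and not self.in_surveillance:
            # resume original modality 10 years after a normal colonoscopy
            self.blackout_until = age + 10.0
        del first_colonoscopy

    def consume_backbone_exam(self, exam: PlannedExam) -> None:
        if self.idx < len(self.backbone) and self.backbone[self.idx] is exam:
            self.idx += 1


# --------------------------------------------------------------------------
# Spec-level operations built on the machine
# --------------------------------------------------------------------------


def _machine_from_history(history: ExamHistory, policy: ScreeningPolicy, table: SurveillanceTable) -> ScheduleMachine:
    backbone = [PlannedExam(a, policy.modality, ExamKind.SCREENING) for a in policy.routine_ages()]
    machine = ScheduleMachine(backbone, table, policy.surveillance_stop_age)
    for rec in history.records:
        if rec.modality is Modality.COLONOSCOPY:
            if rec.category is None:
                raise ValueError("colonoscopy record lacks a findings category")
            if rec.category is FindingsCategory.CRC:
                raise ValueError("no scheduling after CRC detection")
            machine.record_colonoscopy(rec.age, rec.category)
        # negative FIT results do not touch the surveillance state
    return machine


def next_event(
    history: ExamHistory,
    policy: ScreeningPolicy,
    now: float,
    table: Optional[SurveillanceTable] = None,
) -> Optional[PlannedExam]:
    """Next scheduled exam for an alive, undiagnosed person, or ``None``.

    Pure function of (history, policy, now): routine exams at policy
    intervals until stop age, surveillance intervals after adenoma findings,
    the 10-year resume rule after a normal first/diagnostic colonoscopy, and
    the age-85 surveillance stopping rule.
    """
    table = table if table is not None else default_surveillance_table()
    machine = _machine_from_history(history, policy, table)
    proposal = machine.propose(now)
    if proposal is None:
        return None
    if apply_stopping_rules(history, policy, proposal, machine=machine) == "drop":
        return None
    return proposal


def apply_stopping_rules(
    history: ExamHistory,
    policy: ScreeningPolicy,
    proposed,
    machine: Optional[ScheduleMachine] = None,
) -> str:
    """Return ``"schedule"`` or ``"drop"`` for a proposed exam.

    Routine exams stop after the policy stop age; surveillance continues past
    age 85 only while the most recent exam detected adenomas.
    """
    if isinstance(proposed, PlannedExam):
        age, kind = proposed.age, proposed.kind
    else:  # bare age => routine proposal
        age, kind = float(proposed), ExamKind.SCREENING
    if kind is ExamKind.SURVEILLANCE:
        if age <= policy.surveillance_stop_age + 1e-9:
            return "schedule"
        if machine is not None:
            return "schedule" if machine.last_exam_found_adenomas else "drop"
        last_colo = history.colonoscopies()[-1] if history.colonoscopies() else None
        found = last_colo is not None and last_colo.category in _ADENOMA_CATEGORIES
        return "schedule" if found else "drop"
    return "schedule" if age <= policy.stop_age + 1e-9 else "drop"
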