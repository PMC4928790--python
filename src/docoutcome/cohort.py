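"""Domain model for an acute disorders-of-consciousness (DOC) cohort.

The Coma Recovery Scale-Revised (CRS-R) rates six behavioural functions on
ordinal subscales; the first five (auditory, visual, motor, oromotor/verbal,
communication) carry the diagnostic criteria for Unresponsive Wakefulness
Syndrome (UWS) versus the Minimally Conscious State (MCS), while the arousal
subscale and the total score do not and are excluded from all analyses here.

Emergence from DOC is defined by functional object use (motor score 6) or
functional communication (communication score 2).  Patients are grouped into
two primary outcome classes — emerged from DOC (class 1) versus remaining in
DOC (class 2) — and six subclasses (a)–(f) crossing the initial diagnosis
with the discharge outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SUBSCALES",
    "SUBSCALE_MAX",
    "REFLEX_LEVEL",
    "MCS_THRESHOLDS",
    "Diagnosis",
    "Outcome",
    "SubscaleProfile",
    "MBTAssessment",
    "CRSRAssessment",
    "PatientRecord",
    "OutcomeClassification",
    "Comparison",
    "diagnose",
    "classify_outcome",
    "enumerate_comparisons",
]

#: The five analysed CRS-R subscales, in canonical order.
SUBSCALES = ("auditory", "visual", "motor", "oromotor", "communication")

#: Top ordinal level of each subscale.
SUBSCALE_MAX = {
    "auditory": 4,
    "visual": 5,
    "motor": 6,
    "oromotor": 3,
    "communication": 2,
}

#: Score that denotes purely reflexive behaviour on each subscale
#: (communication has no reflex level proper; "none" = 0 plays that role).
REFLEX_LEVEL = {
    "auditory": 1,
    "visual": 1,
    "motor": 2,
    "oromotor": 1,
    "communication": 0,
}

#: Minimal subscale scores that indicate at least MCS.  The convention is the
#: standard CRS-R scoring rule: the first level above the reflex band that
#: requires a reproducible, non-reflex behavioural response.  Overridable in
#: :func:`diagnose` for sensitivity analyses.
MCS_THRESHOLDS = {
    "auditory": 3,
    "visual": 2,
    "motor": 3,
    "oromotor": 3,
    "communication": 1,
}


class Diagnosis(str, Enum):
    """Behavioural diagnosis derived from one CRS-R assessment."""

    UWS = "UWS"
    MCS = "MCS"
    EMERGED = "EMERGED"


class Outcome(str, Enum):
    """Discharge outcome category as recorded in the cohort table."""

    NON_DOC = "Non DOC"
    MCS = "MCS"
    UWS = "UWS"


@dataclass(frozen=True)
class SubscaleProfile:
    """Scores of the five analysed CRS-R subscales at one assessment.

    ``arousal`` is stored when recorded but deliberately excluded from every
    analysis: the UWS/MCS criteria rest on the first five subscales only.
    """

    auditory: int
    visual: int
    motor: int
    oromotor: int
    communication: int
    arousal: Optional[int] = None

    def __post_init__(self) -> None:
        for name in SUBSCALES:
            score = getattr(self, name)
            if not isinstance(score, (int,)) or isinstance(score, bool):
                raise ValueError(f"{name} score must be an integer, got {score!r}")
            if not 0 <= score <= SUBSCALE_MAX[name]:
                raise ValueError(
                    f"{name} score {score} outside its range 0..{SUBSCALE_MAX[name]}"
                )
        if self.arousal is not None and not 0 <= self.arousal <= 3:
            raise ValueError(f"arousal score {self.arousal} outside its range 0..3")

    def scores(self) -> tuple[int, int, int, int, int]:
        """The five analysed scores in canonical subscale order."""
        return tuple(getattr(self, name) for name in SUBSCALES)


#: Fixed role labels of the ten Motor Behaviour Tool items (1-based index).
MBT_POSITIVE_ITEMS = (1, 2, 3, 4, 5)
MBT_NEGATIVE_ITEMS = (6, 7)
MBT_REFLEX_ITEMS = (8, 9, 10)


@dataclass(frozen=True)
class MBTAssessment:
    """One Motor Behaviour Tool (MBT) evaluation: 10 binary items.

    Items 1–5 are positive motor signs that standard CRS-R quoting may
    overlook, items 6–7 flag masking medical conditions (negative signs),
    items 8–10 are pathological reflex signs.  Scoring is non-cumulative:
    each item is independently present (1) or absent (0).
    """

    items: tuple[int, ...]
    day: int = 0

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != 10:
            raise ValueError(f"MBT has exactly 10 items, got {len(items)}")
        if any(v not in (0, 1) for v in items):
            raise ValueError("MBT items must be binary (0 or 1)")
        object.__setattr__(self, "items", items)

    def item(self, index: int) -> int:
        """Value of item ``index`` (1-based, matching the instrument sheet)."""
        if not 1 <= index <= 10:
            raise ValueError(f"MBT item index must be 1..10, got {index}")
        return self.items[index - 1]

    def combined_with(self, other: "MBTAssessment") -> "MBTAssessment":
        """Item-wise OR with a confirmatory re-evaluation."""
        merged = tuple(max(a, b) for a, b in zip(self.items, other.items))
        return MBTAssessment(items=merged, day=min(self.day, other.day))


@dataclass(frozen=True)
class CRSRAssessment:
    """A dated CRS-R assessment (days counted from the brain insult)."""

    profile: SubscaleProfile
    day: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"assessment day must be >= 0, got {self.day}")


@dataclass
class PatientRecord:
    """One patient: demographics, longitudinal assessments and endpoints.

    ``assessments`` may be empty for records parsed from a demographics-only
    table (the per-patient summary columns still support the descriptive and
    classification analyses); when present, at least three dated assessments
    are required, mirroring the study's inclusion criterion, and days must be
    strictly increasing.
    """

    id: str
    initial_diagnosis: Diagnosis
    discharge_outcome: Outcome
    age: Optional[float] = None
    lesion_sites: frozenset = frozenset()
    aetiology: str = ""
    aetiology_raw: str = ""
    assessments: tuple[CRSRAssessment, ...] = ()
    mbt: tuple[MBTAssessment, ...] = ()
    delay_first_crsr: Optional[float] = None
    n_crsr: Optional[int] = None
    delay_last_crsr: Optional[float] = None
    rehabilitation_duration: Optional[float] = None
    returned_home: Optional[bool] = None  # None encodes NA
    walks: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.initial_diagnosis is Diagnosis.EMERGED:
            raise ValueError("initial diagnosis must be UWS or MCS (inclusion criterion)")
        self.assessments = tuple(self.assessments)
        self.mbt = tuple(self.mbt)
        if self.assessments:
            if len(self.assessments) < 3:
                raise ValueError(
                    f"patient {self.id}: fewer than three assessments"
                )
            days = [a.day for a in self.assessments]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError(f"patient {self.id}: assessment days must strictly increase")

    # -- convenience accessors -------------------------------------------------

    @property
    def first_assessment(self) -> CRSRAssessment:
        if not self.assessments:
            raise ValueError(f"patient {self.id} carries no longitudinal assessments")
        return self.assessments[0]

    @property
    def last_assessment(self) -> CRSRAssessment:
        if not self.assessments:
            raise ValueError(f"patient {self.id} carries no longitudinal assessments")
        return self.assessments[-1]

    def first_mbt(self, combine: str = "or") -> MBTAssessment:
        """The acute-phase MBT evaluation.

        The instrument is administered at the first CRS-R evaluation and again
        two days later for confirmation.  ``combine="or"`` merges the two by
        item-wise OR (a sign observed at either sitting counts as present);
        ``combine="first"`` uses the first sitting alone.
        """
        if not self.mbt:
            raise ValueError(f"patient {self.id} carries no MBT assessment")
        if combine == "first" or len(self.mbt) == 1:
            return self.mbt[0]
        if combine == "or":
            merged = self.mbt[0]
            for extra in self.mbt[1:]:
                merged = merged.combined_with(extra)
            return merged
        raise ValueError(f"unknown MBT combination rule {combine!r}")

    def validate_consistency(self) -> None:
        """Cross-check recorded fields against the assessment trajectory."""
        if not self.assessments:
            return
        first = diagnose(self.first_assessment.profile)
        if first is not self.initial_diagnosis:
            raise ValueError(
                f"patient {self.id}: first assessment diagnoses {first.value}, "
                f"recorded initial diagnosis is {self.initial_diagnosis.value}"
            )
        last = diagnose(self.last_assessment.profile)
        emerged_recorded = self.discharge_outcome is Outcome.NON_DOC
        if emerged_recorded != (last is Diagnosis.EMERGED):
            raise ValueError(
                f"patient {self.id}: last assessment ({last.value}) inconsistent "
                f"with recorded outcome {self.discharge_outcome.value}"
            )


class PrimaryClass(str, Enum):
    EMERGED = "class1_emerged"
    REMAINING = "class2_remaining"


@dataclass(frozen=True)
class OutcomeClassification:
    """Primary class (emerged vs remaining in DOC) and subclass (a)–(f)."""

    primary_class: PrimaryClass
    subclass: str

    def __post_init__(self) -> None:
        if self.subclass not in "abcdef":
            raise ValueError(f"subclass must be one of a..f, got {self.subclass!r}")
        expected = PrimaryClass.EMERGED if self.subclass in "ab" else PrimaryClass.REMAINING
        if self.primary_class is not expected:
            raise ValueError(
                f"subclass {self.subclass!r} belongs to {expected.value}, "
                f"got {self.primary_class.value}"
            )


def diagnose(
    profile: SubscaleProfile,
    thresholds: Mapping[str, int] = MCS_THRESHOLDS,
) -> Diagnosis:
    """Behavioural diagnosis from a single CRS-R assessment.

    Emergence from DOC requires functional object use (motor = 6) or
    functional communication (communication = 2).  Otherwise the profile is
    MCS when any subscale reaches its MCS threshold, else UWS.  Coma is
    outside the taxonomy (inclusion required UWS or MCS at entry); profiles
    below every threshold are labelled UWS.
    """
    if profile.motor == SUBSCALE_MAX["motor"] or profile.communication == SUBSCALE_MAX["communication"]:
        return Diagnosis.EMERGED
    for name in SUBSCALES:
        if getattr(profile, name) >= thresholds[name]:
            return Diagnosis.MCS
    return Diagnosis.UWS


_SUBCLASS_TABLE = {
    (Diagnosis.UWS, Outcome.NON_DOC): "a",
    (Diagnosis.MCS, Outcome.NON_DOC): "b",
    (Diagnosis.UWS, Outcome.UWS): "c",
    (Diagnosis.UWS, Outcome.MCS): "d",
    (Diagnosis.MCS, Outcome.UWS): "e",
    (Diagnosis.MCS, Outcome.MCS): "f",
}


def classify_outcome(patient: PatientRecord, validate: bool = False) -> OutcomeClassification:
    """Map (initial diagnosis, discharge outcome) onto the subclass taxonomy.

    The discharge outcome is taken from the recorded field; with
    ``validate=True`` it is first cross-checked against the last assessment.
    """
    if validate:
        patient.validate_consistency()
    subclass = _SUBCLASS_TABLE[(patient.initial_diagnosis, patient.discharge_outcome)]
    primary = PrimaryClass.EMERGED if subclass in "ab" else PrimaryClass.REMAINING
    return OutcomeClassification(primary_class=primary, subclass=subclass)


@dataclass(frozen=True)
class Comparison:
    """A labelled two-group outcome comparison over patient ids."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    @property
    def degenerate(self) -> bool:
        """True when either side is empty; such comparisons are reported
        but never tested."""
        return len(self.group_a) == 0 or len(self.group_b) == 0

    @property
    def sizes(self) -> tuple[int, int]:
        return (len(self.group_a), len(self.group_b))


def enumerate_comparisons(patients: Sequence[PatientRecord]) -> list[Comparison]:
    """The nine outcome comparisons of the analysis plan.

    One global contrast between the two primary classes, then four contrasts
    within the initially-UWS patients (a vs c, a vs d, c vs d, a vs c∪d) and
    four within the initially-MCS patients (b vs e, b vs f, e vs f, b vs e∪f).
    Comparisons with an empty side (e.g. subclass (e) when no MCS patient
    worsened) are returned flagged as degenerate, never dropped.
    """
    by_subclass: dict[str, list[str]] = {s: [] for s in "abcdef"}
    class1: list[str] = []
    class2: list[str] = []
    for patient in patients:
        cls = classify_outcome(patient)
        by_subclass[cls.subclass].append(patient.id)
        (class1 if cls.primary_class is PrimaryClass.EMERGED else class2).append(patient.id)

    def grp(*subclasses: str) -> tuple[str, ...]:
        ids: list[str] = []
        for s in subclasses:
            ids.extend(by_subclass[s])
        return tuple(ids)

    return [
        Comparison("class1_vs_class2", tuple(class1), tuple(class2)),
        Comparison("uws_a_vs_c", grp("a"), grp("c")),
        Comparison("uws_a_vs_d", grp("a"), grp("d")),
        Comparison("uws_c_vs_d", grp("c"), grp("d")),
        Comparison("uws_a_vs_cd", grp("a"), grp("c", "d")),
        Comparison("mcs_b_vs_e", grp("b"), grp("e")),
        Comparison("mcs_b_vs_f", grp("b"), grp("f")),
        Comparison("mcs_e_vs_f", grp("e"), grp("f")),
        Comparison("mcs_b_vs_ef", grp("b"), grp("e", "f")),
    ]
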