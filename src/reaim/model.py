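"""Core data model for a multisite weight-management program evaluation.

A cohort consists of participant records (demographics plus body
measurements at up to three timepoints: enrollment, end of the 12-week
intervention phase, and end of the 1-year benefit) and site records
(facility type, approval date, the 14 protocol components each site
implements, and whether the site still accepts participants).  An
eligibility model describes the insured population the program draws
from; it supplies the denominator for participation-rate calculations.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Sex",
    "SiteType",
    "Timepoint",
    "MeasurementSet",
    "ParticipantRecord",
    "SiteRecord",
    "EligibilityModel",
    "CohortDataset",
    "AGE_BIN_EDGES",
    "AGE_GROUP_LABELS",
    "N_COMPONENTS",
    "PHASE1_DAYS",
    "PHASE2_DAYS",
    "assign_age_group",
    "phase_eligible",
    "ValidationError",
]

N_COMPONENTS = 14

#: phase windows in days: 12 weeks and 1 calendar year, boundary inclusive
PHASE1_DAYS = 84
PHASE2_DAYS = 365

#: six half-open ten-year age bins starting at the adult threshold
AGE_BIN_EDGES: tuple[float, ...] = (18.0, 25.0, 35.0, 45.0, 55.0, 65.0)
AGE_GROUP_LABELS: tuple[str, ...] = (
    "18-24.9",
    "25-34.9",
    "35-44.9",
    "45-54.9",
    "55-64.9",
    "65+",
)


class ValidationError(ValueError):
    """Input data violates the documented cohort contract."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class SiteType(str, Enum):
    CARDIAC_REHAB = "cardiac_rehab"
    PHYSICAL_THERAPY = "physical_therapy"
    HOSPITAL = "hospital"
    FITNESS_CENTER = "fitness_center"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    END_PHASE1 = "end_phase1"
    END_PHASE2 = "end_phase2"


@dataclass
class MeasurementSet:
    """Body measurements at one timepoint; ``None`` marks a missing cell.

    ``bmi_consistent`` is a soft flag: when weight, height and BMI are all
    present, BMI should agree with 703 * weight_lb / height_in**2 within
    ``tolerance`` units.  Inconsistent records are flagged, never rejected,
    because measurement protocols vary between sites.
    """

    weight_lb: float | None = None
    height_in: float | None = None
    bmi_kg_m2: float | None = None
    systolic_mmHg: float | None = None
    diastolic_mmHg: float | None = None
    body_fat_pct: float | None = None
    waist_in: float | None = None

    def __post_init__(self) -> None:
        for name in ("weight_lb", "height_in", "bmi_kg_m2", "waist_in"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")
        if self.body_fat_pct is not None and not (0 < self.body_fat_pct < 100):
            raise ValidationError(
                f"body_fat_pct must lie in (0, 100), got {self.body_fat_pct!r}"
            )

    def bmi_consistent(self, tolerance: float = 0.5) -> bool:
        """True unless weight, height and BMI all disagree beyond tolerance."""
        if None in (self.weight_lb, self.height_in, self.bmi_kg_m2):
            return True
        implied = 703.0 * self.weight_lb / self.height_in**2
        return abs(implied - self.bmi_kg_m2) <= tolerance


@dataclass
class ParticipantRecord:
    participant_id: str
    site_id: str
    sex: Sex
    age_years: float
    enrollment_date: _dt.date
    measurements: dict[Timepoint, MeasurementSet] = field(default_factory=dict)
    completed_phase1: bool = False
    completed_phase2: bool = False

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.age_years < 18:
            raise ValidationError(
                f"participant {self.participant_id}: age_years must be >= 18, "
                f"got {self.age_years}"
            )
        if self.completed_phase2 and not self.completed_phase1:
            raise ValidationError(
                f"participant {self.participant_id}: completed_phase2 implies "
                "completed_phase1"
            )
        for flag, tp in (
            (self.completed_phase1, Timepoint.END_PHASE1),
            (self.completed_phase2, Timepoint.END_PHASE2),
        ):
            if flag:
                ms = self.measurements.get(tp)
                if ms is None or ms.weight_lb is None:
                    raise ValidationError(
                        f"participant {self.participant_id}: completed "
                        f"{tp.value} but has no {tp.value} weight"
                    )

    @property
    def age_group(self) -> str:
        return assign_age_group(self.age_years)

    def measurement(self, timepoint: Timepoint) -> MeasurementSet:
        return self.measurements.get(timepoint, MeasurementSet())


@dataclass
class SiteRecord:
    site_id: str
    site_type: SiteType
    approval_date: _dt.date
    components_implemented: tuple[bool, ...]
    still_accepting: bool

    def __post_init__(self) -> None:
        self.site_type = SiteType(self.site_type)
        self.components_implemented = tuple(bool(c) for c in self.components_implemented)
        if len(self.components_implemented) != N_COMPONENTS:
            raise ValidationError(
                f"site {self.site_id}: expected {N_COMPONENTS} implementation "
                f"components, got {len(self.components_implemented)}"
            )

    @property
    def n_components(self) -> int:
        return sum(self.components_implemented)


@dataclass
class EligibilityModel:
    """Insured population and prevalence rates defining who is eligible.

    The eligible denominator is ``n_adult_members * (p_obese +
    p_overweight * p_comorbid_overweight)``: all obese adults plus
    overweight adults with at least one comorbid condition.
    """

    n_adult_members: int
    p_obese: float
    p_overweight: float
    p_comorbid_overweight: float
    eligible_sex_split: float  # proportion female
    eligible_age_distribution: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_adult_members <= 0:
            raise ValidationError("n_adult_members must be positive")
        for name in ("p_obese", "p_overweight", "p_comorbid_overweight",
                     "eligible_sex_split"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        dist = tuple(float(p) for p in self.eligible_age_distribution)
        if len(dist) != len(AGE_GROUP_LABELS):
            raise ValidationError(
                f"eligible_age_distribution needs {len(AGE_GROUP_LABELS)} "
                f"entries, got {len(dist)}"
            )
        if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-9:
            raise ValidationError("eligible_age_distribution must be a "
                                  "probability vector summing to 1")
        self.eligible_age_distribution = dist


@dataclass
class CohortDataset:
    participants: list[ParticipantRecord]
    sites: list[SiteRecord]
    data_collection_date: _dt.date
    eligibility: EligibilityModel
    n_potential_sites: int

    def __post_init__(self) -> None:
        if self.n_potential_sites <= 0:
            raise ValidationError("n_potential_sites must be positive")
        known = {s.site_id for s in self.sites}
        orphans = [p.participant_id for p in self.participants
                   if p.site_id not in known]
        if orphans:
            raise ValidationError(
                f"participants reference unknown sites: {orphans[:5]}"
                + ("..." if len(orphans) > 5 else "")
            )
        late = [p.participant_id for p in self.participants
                if p.enrollment_date > self.data_collection_date]
        if late:
            raise ValidationError(
                f"enrollment after data collection for: {late[:5]}"
            )
        seen: set[str] = set()
        for p in self.participants:
            if p.participant_id in seen:
                raise ValidationError(
                    f"duplicate participant_id {p.participant_id!r}"
                )
            seen.add(p.participant_id)

    def phase_eligible_participants(self, phase: int) -> list[ParticipantRecord]:
        return [p for p in self.participants
                if phase_eligible(p, phase, self.data_collection_date)]


def assign_age_group(age_years: float) -> str:
    """Bin an adult age into one of six half-open ten-year groups.

    Decimal ages bin by half-open interval: 54.9 falls in 45-54.9 while
    55.0 starts the next bin; 65.0 and above share a single open-ended bin.
    """
    if age_years < 18:
        raise ValidationError(f"age_years must be >= 18, got {age_years}")
    idx = int(np.searchsorted(AGE_BIN_EDGES, age_years, side="right")) - 1
    return AGE_GROUP_LABELS[idx]


def phase_eligible(record: ParticipantRecord, phase: int,
                   data_collection_date: _dt.date) -> bool:
    """Whether a participant enrolled early enough to have finished a phase.

    Phase 1 requires enrollment at least 84 days (12 weeks) before the data
    collection date; phase 2 at least 365 days.  Both bounds are inclusive.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase!r}")
    window = PHASE1_DAYS if phase == 1 else PHASE2_DAYS
    return (data_collection_date - record.enrollment_date).days >= window
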