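"""Core domain types for pathway-driven chronic-disease management.

The data model mirrors a telehealth deployment in which patients with
hypertension (HTN), type 2 diabetes (T2DM), chronic obstructive pulmonary
disease (COPD), or hypertension-with-diabetes multimorbidity (HM) submit
self-monitoring records from home while a care team (specialist, general
practitioner, case manager) intervenes according to a disease-specific care
pathway.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Any, Optional


class Disease(str, enum.Enum):
    HTN = "HTN"
    T2DM = "T2DM"
    COPD = "COPD"


class DiseaseScope(str, enum.Enum):
    """Rule applicability: a single disease, the HM multimorbidity, or all."""

    HTN = "HTN"
    T2DM = "T2DM"
    COPD = "COPD"
    HM = "HM"
    ALL = "ALL"


class TaskKind(str, enum.Enum):
    """The eight in-engine pathway tasks (diagnosis is performed in hospital,
    outside the engine's remit)."""

    RiskAssessment = "RiskAssessment"
    HierarchicalManagement = "HierarchicalManagement"
    RegularFollowUp = "RegularFollowUp"
    AbnormalConditionIntervention = "AbnormalConditionIntervention"
    MedicationGuidance = "MedicationGuidance"
    LifestyleGuidance = "LifestyleGuidance"
    HealthEducation = "HealthEducation"
    ComplianceManagement = "ComplianceManagement"


class RecordKind(str, enum.Enum):
    BP = "BP"
    BG = "BG"
    PEF = "PEF"
    diet = "diet"
    exercise = "exercise"
    psychological = "psychological"
    medication = "medication"
    discomfort = "discomfort"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Education(str, enum.Enum):
    secondary_or_below = "secondary_or_below"
    high_school = "high_school"
    graduate_or_above = "graduate_or_above"
    unknown = "unknown"


class WarningKind(str, enum.Enum):
    single_value = "single_value"
    weekly_aggregate = "weekly_aggregate"
    ketone = "ketone"
    acute_exacerbation = "acute_exacerbation"
    scale = "scale"
    low_compliance = "low_compliance"


class Severity(str, enum.Enum):
    notice = "notice"
    urgent = "urgent"


class InterventionKind(str, enum.Enum):
    regular_followup = "regular_followup"
    warning_intervention = "warning_intervention"
    sms = "sms"
    app_message = "app_message"


class CarepathError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(CarepathError):
    pass


class DomainError(CarepathError):
    pass


class InsufficientDataError(CarepathError):
    pass


def disease_scope_of(diseases: frozenset[Disease]) -> DiseaseScope:
    """Map a patient's disease set to the ruleset scope that manages it."""
    if diseases == {Disease.HTN, Disease.T2DM}:
        return DiseaseScope.HM
    if len(diseases) == 1:
        return DiseaseScope[next(iter(diseases)).value]
    raise DomainError(f"unsupported disease combination: {sorted(d.value for d in diseases)}")


@dataclass
class PatientProfile:
    """Demographics, disease set, targets and current stratification level.

    ``bp_target`` is (SBP, DBP) in mmHg; ``bg_target`` is (FBG, PBG) in
    mmol/L; ``pef_personal_best`` in L/min is required for COPD patients,
    whose warning zones are expressed as fractions of the personal best.
    """

    patient_id: str
    age: float
    sex: Sex
    diseases: frozenset[Disease]
    enrollment_date: date
    education: Education = Education.unknown
    bp_target: tuple[float, float] = (140.0, 90.0)
    bg_target: tuple[float, float] = (7.0, 10.0)
    pef_personal_best: Optional[float] = None
    current_levels: dict[Disease, str] = field(default_factory=dict)
    smoker: bool = False
    obese: bool = False
    organ_damage: bool = False
    comorbidity: bool = False

    def __post_init__(self) -> None:
        self.diseases = frozenset(Disease(d) for d in self.diseases)
        if self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be positive")
        if not self.diseases:
            raise ValidationError(f"{self.patient_id}: empty disease set")
        if len(self.diseases) > 1 and self.diseases != {Disease.HTN, Disease.T2DM}:
            raise ValidationError(
                f"{self.patient_id}: only HTN+T2DM multimorbidity is supported"
            )
        if Disease.COPD in self.diseases and self.pef_personal_best is None:
            raise ValidationError(f"{self.patient_id}: COPD profile needs pef_personal_best")

    @property
    def scope(self) -> DiseaseScope:
        return disease_scope_of(self.diseases)


@dataclass
class SelfMonitoringRecord:
    """One timestamped self-monitoring entry (measurement or event).

    ``values`` is kind-specific: BP carries sbp/dbp (mmHg) and optionally
    heart_rate; BG carries measurement ("FBG"/"PBG"), value (mmol/L) and a
    ketone flag; PEF carries value (L/min); psychological carries scale
    ("CAT"/"other") and score; discomfort may carry acute_exacerbation.
    """

    patient_id: str
    timestamp: datetime
    kind: RecordKind
    values: dict[str, Any] = field(default_factory=dict)
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.kind = RecordKind(self.kind)
        v = self.values
        if self.kind is RecordKind.BP:
            sbp, dbp = float(v["sbp"]), float(v["dbp"])
            if not sbp > dbp > 0:
                raise ValidationError(
                    f"{self.patient_id}@{self.timestamp}: BP requires sbp > dbp > 0, "
                    f"got {sbp}/{dbp}"
                )
        elif self.kind is RecordKind.BG:
            if float(v["value"]) <= 0:
                raise ValidationError(f"{self.patient_id}@{self.timestamp}: BG value must be > 0")
            if v.get("measurement") not in ("FBG", "PBG"):
                raise ValidationError(
                    f"{self.patient_id}@{self.timestamp}: BG measurement must be FBG or PBG"
                )
        elif self.kind is RecordKind.PEF:
            if float(v["value"]) <= 0:
                raise ValidationError(f"{self.patient_id}@{self.timestamp}: PEF value must be > 0")
        elif self.kind is RecordKind.psychological:
            if v.get("scale") == "CAT" and not 0 <= float(v["score"]) <= 40:
                raise ValidationError(
                    f"{self.patient_id}@{self.timestamp}: CAT score must lie in [0, 40]"
                )


@dataclass
class Warning:
    warning_id: str
    patient_id: str
    kind: WarningKind
    severity: Severity
    triggering_evidence: list[str]
    raised_at: datetime
    status: str = "open"

    def __post_init__(self) -> None:
        if self.severity is Severity.urgent and not self.triggering_evidence:
            raise ValidationError(f"{self.warning_id}: urgent warning requires evidence")

    def handle(self) -> None:
        if self.status != "open":
            raise DomainError(f"{self.warning_id}: only open warnings can be handled")
        self.status = "handled"


@dataclass
class RiskAssessment:
    disease: Disease
    factors: dict[str, Any]
    category: str
    assessed_at: date


@dataclass
class ManagementLevel:
    disease: Disease
    level: str
    basis: dict[str, Any]
    effective_date: date
    provisional: bool = False


@dataclass
class DoctorPlan:
    followup_interval_days: int
    next_followup: date
    pending_warning_reminders: list[str] = field(default_factory=list)
    low_compliance_reminders: list[str] = field(default_factory=list)


@dataclass
class SelfPlan:
    monitoring_schedule: dict[RecordKind, float]  # submissions per day
    medication_items: list[str] = field(default_factory=list)
    lifestyle_items: frozenset[str] = frozenset()
    education_items: list[str] = field(default_factory=list)


@dataclass
class ManagementPlan:
    doctor_plan: DoctorPlan
    self_plan: SelfPlan
    provenance: list[tuple[Disease, str]]  # contributing (disease, level) pairs

    def __post_init__(self) -> None:
        if not self.self_plan.monitoring_schedule:
            raise ValidationError("monitoring_schedule must be non-empty")


@dataclass
class ComplianceState:
    patient_id: str
    date: date
    scheduled_tasks: int
    completed_tasks: int
    compliance: float
    flagged_low: bool


@dataclass
class InterventionRecord:
    """A care-provider action completing an engine-generated request."""

    provider_id: str
    patient_id: str
    kind: InterventionKind
    requested_at: date
    completed_at: date
    notes: str = ""

    def __post_init__(self) -> None:
        self.kind = InterventionKind(self.kind)
        if self.completed_at < self.requested_at:
            raise ValidationError(
                f"{self.provider_id}/{self.patient_id}: completed_at precedes requested_at"
            )
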