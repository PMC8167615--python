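"""Disease-specific care-pathway logic.

Implements the clinical content of the pathway tasks for hypertension,
type 2 diabetes and COPD: risk assessment, hierarchical (level) assignment,
follow-up scheduling, warning detection, compliance tracking, management-
plan generation and multimorbidity plan merging.  Every clinical threshold
lives in :class:`EngineConfig` and is configurable; the defaults are
standard guideline values.

Level semantics: hypertension has 2 levels (I: at BP target, II: not),
type 2 diabetes 3 (by fasting/postprandial glucose target attainment), and
COPD 4 (directly from the symptom-burden x exacerbation-risk grid of the
risk assessment).  Higher levels mean more intensive follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Any, Iterable, Optional, Sequence

from .knowledge import Rule, builtin_ruleset
from .models import (
    ComplianceState,
    Disease,
    DoctorPlan,
    DomainError,
    InsufficientDataError,
    ManagementLevel,
    ManagementPlan,
    PatientProfile,
    RecordKind,
    RiskAssessment,
    SelfPlan,
    SelfMonitoringRecord,
    Severity,
    ValidationError,
    Warning,
    WarningKind,
)

#: most intensive level per disease, used when data are insufficient
MOST_INTENSIVE = {Disease.HTN: "II", Disease.T2DM: "III", Disease.COPD: "IV"}

LEVELS = {
    Disease.HTN: ("I", "II"),
    Disease.T2DM: ("I", "II", "III"),
    Disease.COPD: ("I", "II", "III", "IV"),
}

#: record kinds admissible per disease (lifestyle/medication/discomfort are
#: universal; physiological indices are disease-specific)
_UNIVERSAL_KINDS = {
    RecordKind.diet,
    RecordKind.exercise,
    RecordKind.medication,
    RecordKind.discomfort,
}
KINDS_BY_DISEASE = {
    Disease.HTN: _UNIVERSAL_KINDS | {RecordKind.BP},
    Disease.T2DM: _UNIVERSAL_KINDS | {RecordKind.BP, RecordKind.BG},
    Disease.COPD: _UNIVERSAL_KINDS | {RecordKind.PEF, RecordKind.psychological},
}

LIFESTYLE_ITEMS = {
    Disease.HTN: frozenset(
        {"reduce_sodium", "control_weight", "no_smoking_drinking",
         "increase_exercise", "reduce_stress"}
    ),
    Disease.T2DM: frozenset(
        {"control_weight", "balanced_diet", "reduce_sodium",
         "no_smoking_drinking", "moderate_exercise", "reduce_stress"}
    ),
    Disease.COPD: frozenset(
        {"avoid_smoking", "increase_regular_exercise", "rehabilitation_exercises"}
    ),
}

MEDICATION_ITEMS = {
    Disease.HTN: ["review_antihypertensive_therapy"],
    Disease.T2DM: ["review_hypoglycemic_therapy_or_insulin"],
    Disease.COPD: [],  # not generated by the engine; providers act manually
}

EDUCATION_ITEMS = {
    Disease.HTN: ["hypertension_basics"],
    Disease.T2DM: ["diabetes_basics"],
    Disease.COPD: ["copd_basics"],
}

#: self-monitoring frequencies (submissions per day) per disease and level
_MONITORING = {
    (Disease.HTN, "I"): {RecordKind.BP: 3 / 7, RecordKind.medication: 1.0},
    (Disease.HTN, "II"): {RecordKind.BP: 1.0, RecordKind.medication: 1.0},
    (Disease.T2DM, "I"): {RecordKind.BG: 2 / 7, RecordKind.medication: 1.0},
    (Disease.T2DM, "II"): {RecordKind.BG: 4 / 7, RecordKind.medication: 1.0},
    (Disease.T2DM, "III"): {RecordKind.BG: 1.0, RecordKind.medication: 1.0},
}
for _lvl in LEVELS[Disease.COPD]:
    _MONITORING[(Disease.COPD, _lvl)] = {
        RecordKind.PEF: 1.0,
        RecordKind.psychological: 1 / 7,
        RecordKind.medication: 1.0,
    }


@dataclass
class EngineConfig:
    """All clinical thresholds, targets and scheduling constants.

    BP in mmHg, BG in mmol/L, PEF zones as fractions of personal best,
    intervals and windows in days.
    """

    bp_target: tuple[float, float] = (140.0, 90.0)
    urgent_sbp_high: float = 180.0
    urgent_dbp_high: float = 110.0
    urgent_sbp_low: float = 90.0
    urgent_dbp_low: float = 60.0
    fbg_target: float = 7.0
    pbg_target: float = 10.0
    hypoglycemia: float = 3.9
    severe_hyperglycemia: float = 16.7
    pef_notice_fraction: float = 0.80
    pef_urgent_fraction: float = 0.60
    cat_warning_score: float = 10.0
    htn_level2_interval_days: int = 14  # configurable within [14, 28]
    aggregate_window_days: int = 7
    min_readings_for_level: int = 3
    compliance_window_days: int = 7
    compliance_low_threshold: float = 0.5
    stratify_every_days: int = 7

    def __post_init__(self) -> None:
        if not 14 <= self.htn_level2_interval_days <= 28:
            raise ValidationError("htn_level2_interval_days must lie in [14, 28]")


DEFAULT_CONFIG = EngineConfig()


def followup_interval_days(
    disease: Disease, level: str, config: EngineConfig = DEFAULT_CONFIG
) -> int:
    disease = Disease(disease)
    if level not in LEVELS[disease]:
        raise DomainError(f"no level {level!r} for {disease.value}")
    if disease is Disease.HTN:
        return 90 if level == "I" else config.htn_level2_interval_days
    if disease is Disease.T2DM:
        return {"I": 90, "II": 30, "III": 14}[level]
    return 14  # COPD: every 2 weeks at every level


def schedule_followup(
    disease: Disease,
    level: str,
    reference_date: date,
    config: EngineConfig = DEFAULT_CONFIG,
) -> tuple[int, date]:
    """Follow-up interval and next date for a (disease, level) pair."""
    interval = followup_interval_days(disease, level, config)
    return interval, reference_date + timedelta(days=interval)


# ---------------------------------------------------------------------------
# windowed record helpers

def _window(
    records: Iterable[SelfMonitoringRecord],
    kind: RecordKind,
    as_of: date,
    days: int,
) -> list[SelfMonitoringRecord]:
    """Records of ``kind`` with timestamp in the half-open [as_of - days, as_of)."""
    start = datetime.combine(as_of - timedelta(days=days), datetime.min.time())
    end = datetime.combine(as_of, datetime.min.time())
    return [r for r in records if r.kind is kind and start <= r.timestamp < end]


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


# ---------------------------------------------------------------------------
# risk assessment

def assess_risk(
    profile: PatientProfile,
    records: Sequence[SelfMonitoringRecord],
    disease: Disease,
    as_of: date,
    config: EngineConfig = DEFAULT_CONFIG,
    lipid_controlled: bool = True,
) -> RiskAssessment:
    """Disease-specific risk assessment from the profile and record window.

    ``lipid_controlled`` is supplied externally for diabetes (lipid panels
    come from clinic data, not self-monitoring).
    """
    disease = Disease(disease)
    if disease not in profile.diseases:
        raise DomainError(f"{profile.patient_id} is not managed for {disease.value}")

    if disease is Disease.HTN:
        age_cut = 55 if profile.sex.value == "male" else 65
        factor_flags = {
            "age": profile.age > age_cut,
            "smoking": profile.smoker,
            "obesity": profile.obese,
            "diabetes_comorbidity": Disease.T2DM in profile.diseases,
        }
        count = sum(factor_flags.values())
        if profile.organ_damage or profile.comorbidity or count >= 3:
            category = "high"
        elif count >= 1:
            category = "moderate"
        else:
            category = "low"
        factors: dict[str, Any] = {
            "cardiovascular_risk_count": count,
            **factor_flags,
            "organ_damage": profile.organ_damage,
            "comorbidity": profile.comorbidity,
        }
        return RiskAssessment(disease, factors, category, as_of)

    if disease is Disease.T2DM:
        win = config.aggregate_window_days
        bps = _window(records, RecordKind.BP, as_of, win)
        bp_controlled = (
            _mean([r.values["sbp"] for r in bps]) < profile.bp_target[0]
            and _mean([r.values["dbp"] for r in bps]) < profile.bp_target[1]
            if bps
            else True
        )
        bgs = _window(records, RecordKind.BG, as_of, win)
        fbg = [r.values["value"] for r in bgs if r.values["measurement"] == "FBG"]
        pbg = [r.values["value"] for r in bgs if r.values["measurement"] == "PBG"]
        bg_controlled = (not fbg or _mean(fbg) < profile.bg_target[0]) and (
            not pbg or _mean(pbg) < profile.bg_target[1]
        )
        n_controlled = sum([bp_controlled, bg_controlled, lipid_controlled])
        category = {3: "all_controlled", 0: "uncontrolled"}.get(
            n_controlled, "partially_controlled"
        )
        factors = {
            "bp_controlled": bp_controlled,
            "bg_controlled": bg_controlled,
            "lipid_controlled": lipid_controlled,
        }
        return RiskAssessment(disease, factors, category, as_of)

    # COPD: symptom burden (CAT) x exacerbation risk grid, cells A-D
    pefs = [r for r in records if r.kind is RecordKind.PEF and r.timestamp.date() < as_of]
    cats = [
        r
        for r in records
        if r.kind is RecordKind.psychological
        and r.values.get("scale") == "CAT"
        and r.timestamp.date() < as_of
    ]
    if not pefs and not cats:
        raise InsufficientDataError(
            f"{profile.patient_id}: COPD risk assessment needs PEF or CAT data"
        )
    year = [
        r
        for r in records
        if as_of - timedelta(days=365) <= r.timestamp.date() < as_of
    ]
    exac = sum(
        1
        for r in year
        if r.kind is RecordKind.discomfort and r.values.get("acute_exacerbation")
    )
    hosp = sum(
        1 for r in year if r.kind is RecordKind.discomfort and r.values.get("hospitalization")
    )
    cat_score = max(cats, key=lambda r: r.timestamp).values["score"] if cats else 0.0
    pef_percent = (
        max(pefs, key=lambda r: r.timestamp).values["value"]
        / profile.pef_personal_best
        * 100
        if pefs
        else None
    )
    high_symptoms = cat_score >= config.cat_warning_score
    high_risk = exac >= 2 or hosp >= 1
    category = {
        (False, False): "A",
        (True, False): "B",
        (False, True): "C",
        (True, True): "D",
    }[(high_symptoms, high_risk)]
    factors = {
        "pef_percent_best": pef_percent,
        "cat_score": cat_score,
        "exacerbations_12m": exac,
        "hospitalizations_12m": hosp,
    }
    return RiskAssessment(disease, factors, category, as_of)


# ---------------------------------------------------------------------------
# hierarchical management

_COPD_LEVEL = {"A": "I", "B": "II", "C": "III", "D": "IV"}


def assign_level(
    profile: PatientProfile,
    risk: Optional[RiskAssessment],
    records: Sequence[SelfMonitoringRecord],
    disease: Disease,
    as_of: date,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ManagementLevel:
    """Assign the management level from the trailing record window.

    With fewer than ``config.min_readings_for_level`` relevant readings
    (hypertension/diabetes) the most intensive level is assigned and the
    result flagged provisional, mirroring the initial management period
    before formal classification.
    """
    disease = Disease(disease)
    if disease not in profile.diseases:
        raise DomainError(f"{profile.patient_id} is not managed for {disease.value}")
    win = config.aggregate_window_days

    if disease is Disease.COPD:
        if risk is None:
            raise DomainError("COPD level assignment requires a risk assessment")
        level = ManagementLevel(
            disease, _COPD_LEVEL[risk.category], {"risk_category": risk.category}, as_of
        )
        profile.current_levels[disease] = level.level
        return level

    if disease is Disease.HTN:
        bps = _window(records, RecordKind.BP, as_of, win)
        if len(bps) < config.min_readings_for_level:
            level = ManagementLevel(
                disease, MOST_INTENSIVE[disease], {"n_readings": len(bps)}, as_of,
                provisional=True,
            )
        else:
            msbp = _mean([r.values["sbp"] for r in bps])
            mdbp = _mean([r.values["dbp"] for r in bps])
            at_target = msbp < profile.bp_target[0] and mdbp < profile.bp_target[1]
            level = ManagementLevel(
                disease,
                "I" if at_target else "II",
                {"mean_sbp": msbp, "mean_dbp": mdbp, "n_readings": len(bps)},
                as_of,
            )
    else:  # T2DM
        bgs = _window(records, RecordKind.BG, as_of, win)
        if len(bgs) < config.min_readings_for_level:
            level = ManagementLevel(
                disease, MOST_INTENSIVE[disease], {"n_readings": len(bgs)}, as_of,
                provisional=True,
            )
        else:
            fbg = [r.values["value"] for r in bgs if r.values["measurement"] == "FBG"]
            pbg = [r.values["value"] for r in bgs if r.values["measurement"] == "PBG"]
            hypo = any(r.values["value"] < config.hypoglycemia for r in bgs)
            fbg_ok = not fbg or _mean(fbg) < profile.bg_target[0]
            pbg_ok = not pbg or _mean(pbg) < profile.bg_target[1]
            if hypo or (not fbg_ok and not pbg_ok):
                lab = "III"
            elif fbg_ok and pbg_ok:
                lab = "I"
            else:
                lab = "II"
            level = ManagementLevel(
                disease,
                lab,
                {
                    "mean_fbg": _mean(fbg) if fbg else None,
                    "mean_pbg": _mean(pbg) if pbg else None,
                    "hypoglycemia": hypo,
                    "n_readings": len(bgs),
                },
                as_of,
            )
    profile.current_levels[disease] = level.level
    return level


# ---------------------------------------------------------------------------
# warnings

def _check_record(
    r: SelfMonitoringRecord, profile: PatientProfile, config: EngineConfig
) -> list[tuple[WarningKind, Severity]]:
    out: list[tuple[WarningKind, Severity]] = []
    if r.kind is RecordKind.BP:
        sbp, dbp = r.values["sbp"], r.values["dbp"]
        if (
            sbp >= config.urgent_sbp_high
            or dbp >= config.urgent_dbp_high
            or sbp < config.urgent_sbp_low
            or dbp < config.urgent_dbp_low
        ):
            out.append((WarningKind.single_value, Severity.urgent))
    elif r.kind is RecordKind.BG:
        v = r.values["value"]
        if v < config.hypoglycemia or v >= config.severe_hyperglycemia:
            out.append((WarningKind.single_value, Severity.urgent))
        if r.values.get("ketone"):
            out.append((WarningKind.ketone, Severity.urgent))
    elif r.kind is RecordKind.PEF:
        frac = r.values["value"] / profile.pef_personal_best
        if frac < config.pef_urgent_fraction:
            out.append((WarningKind.single_value, Severity.urgent))
        elif frac < config.pef_notice_fraction:
            out.append((WarningKind.single_value, Severity.notice))
    elif r.kind is RecordKind.psychological:
        if r.values.get("scale") == "CAT" and r.values["score"] >= config.cat_warning_score:
            out.append((WarningKind.scale, Severity.urgent))
    elif r.kind is RecordKind.discomfort:
        if r.values.get("acute_exacerbation"):
            out.append((WarningKind.acute_exacerbation, Severity.urgent))
    return out


def detect_warnings(
    records: Sequence[SelfMonitoringRecord],
    profile: PatientProfile,
    as_of: datetime,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[Warning]:
    """Apply single-value checks per record and the weekly BP aggregate check.

    Raising any threshold can only shrink the warning list (monotone in the
    thresholds), which the property tests rely on.
    """
    allowed = set().union(*(KINDS_BY_DISEASE[d] for d in profile.diseases))
    warnings: list[Warning] = []
    n = 0
    for r in records:
        if r.kind not in allowed:
            raise DomainError(
                f"{profile.patient_id}: record kind {r.kind.value} inconsistent "
                f"with diseases {sorted(d.value for d in profile.diseases)}"
            )
        for kind, severity in _check_record(r, profile, config):
            n += 1
            warnings.append(
                Warning(
                    warning_id=f"{profile.patient_id}-{as_of.date().isoformat()}-{n}",
                    patient_id=profile.patient_id,
                    kind=kind,
                    severity=severity,
                    triggering_evidence=[r.record_id or f"{r.kind.value}@{r.timestamp}"],
                    raised_at=as_of,
                )
            )
    if Disease.HTN in profile.diseases:
        bps = _window(records, RecordKind.BP, as_of.date(), config.aggregate_window_days)
        if len(bps) >= 3:
            msbp = _mean([r.values["sbp"] for r in bps])
            mdbp = _mean([r.values["dbp"] for r in bps])
            if msbp >= profile.bp_target[0] or mdbp >= profile.bp_target[1]:
                n += 1
                warnings.append(
                    Warning(
                        warning_id=f"{profile.patient_id}-{as_of.date().isoformat()}-{n}",
                        patient_id=profile.patient_id,
                        kind=WarningKind.weekly_aggregate,
                        severity=Severity.notice,
                        triggering_evidence=[
                            f"7d mean {msbp:.1f}/{mdbp:.1f} over {len(bps)} readings"
                        ],
                        raised_at=as_of,
                    )
                )
    return warnings


# ---------------------------------------------------------------------------
# compliance

def update_compliance(
    plan: ManagementPlan,
    records: Sequence[SelfMonitoringRecord],
    state_history: Sequence[ComplianceState],
    day: date,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ComplianceState:
    """Daily compliance: completed / scheduled self-monitoring items over the
    trailing window.  ``records`` may span any range; only the window
    [day - window, day) counts."""
    win = config.compliance_window_days
    schedule = plan.self_plan.monitoring_schedule
    scheduled = sum(max(1, round(freq * win)) for freq in schedule.values())
    if scheduled == 0:
        raise ValidationError("monitoring schedule yields zero scheduled items")
    completed = 0
    for kind, freq in schedule.items():
        due = max(1, round(freq * win))
        got = len(_window(records, kind, day, win))
        completed += min(due, got)
    compliance = completed / scheduled
    flagged = compliance < config.compliance_low_threshold
    return ComplianceState(
        patient_id=records[0].patient_id if records else "",
        date=day,
        scheduled_tasks=scheduled,
        completed_tasks=completed,
        compliance=compliance,
        flagged_low=flagged,
    )


# ---------------------------------------------------------------------------
# plans

def generate_plan(
    profile: PatientProfile,
    level: ManagementLevel,
    risk: Optional[RiskAssessment] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ManagementPlan:
    """Single-disease management plan: doctor follow-up plan plus the patient
    self-management plan (monitoring schedule, medication and lifestyle
    prescriptions, education).  COPD plans carry no engine-generated
    medication items."""
    disease = level.disease
    if disease not in profile.diseases:
        raise DomainError(f"{profile.patient_id} is not managed for {disease.value}")
    interval, nxt = schedule_followup(disease, level.level, level.effective_date, config)
    return ManagementPlan(
        doctor_plan=DoctorPlan(followup_interval_days=interval, next_followup=nxt),
        self_plan=SelfPlan(
            monitoring_schedule=dict(_MONITORING[(disease, level.level)]),
            medication_items=list(MEDICATION_ITEMS[disease]),
            lifestyle_items=LIFESTYLE_ITEMS[disease],
            education_items=list(EDUCATION_ITEMS[disease]),
        ),
        provenance=[(disease, level.level)],
    )


def _conflict_groups(mcc_rules: Optional[Sequence[Rule]]) -> list[list[str]]:
    rules = mcc_rules if mcc_rules is not None else builtin_ruleset("HM")
    groups: list[list[str]] = []
    for r in rules:
        groups.extend(r.parameters.get("conflict_groups", []))
    return groups


def merge_plans(
    plans: Sequence[ManagementPlan],
    mcc_rules: Optional[Sequence[Rule]] = None,
) -> ManagementPlan:
    """Merge single-disease plans for a multimorbid patient.

    Follow-up interval is the minimum over components; the monitoring
    schedule is a per-kind maximum; lifestyle items are a set union with
    conflicting prescriptions resolved to the most conservative variant as
    declared in the MCC merge ruleset.  A single-element input is returned
    unchanged."""
    if not plans:
        raise DomainError("merge_plans requires at least one plan")
    if len(plans) == 1:
        return plans[0]
    diseases = frozenset(d for p in plans for d, _ in p.provenance)
    if diseases != {Disease.HTN, Disease.T2DM}:
        raise DomainError(
            f"unsupported multimorbidity: {sorted(d.value for d in diseases)}"
        )
    interval = min(p.doctor_plan.followup_interval_days for p in plans)
    nxt = min(p.doctor_plan.next_followup for p in plans)
    schedule: dict[RecordKind, float] = {}
    for p in plans:
        for kind, freq in p.self_plan.monitoring_schedule.items():
            schedule[kind] = max(schedule.get(kind, 0.0), freq)
    lifestyle = frozenset().union(*(p.self_plan.lifestyle_items for p in plans))
    for group in _conflict_groups(mcc_rules):
        present = [item for item in group if item in lifestyle]
        if len(present) > 1:  # keep the most conservative (first listed) only
            lifestyle = (lifestyle - set(present)) | {present[0]}
    # merged lists are canonicalized (sorted, deduplicated) so the merge
    # commutes regardless of input order
    meds = sorted({m for p in plans for m in p.self_plan.medication_items})
    edu = sorted({e for p in plans for e in p.self_plan.education_items})
    warn_rem = sorted({x for p in plans for x in p.doctor_plan.pending_warning_reminders})
    comp_rem = sorted({x for p in plans for x in p.doctor_plan.low_compliance_reminders})
    return ManagementPlan(
        doctor_plan=DoctorPlan(
            followup_interval_days=interval,
            next_followup=nxt,
            pending_warning_reminders=warn_rem,
            low_compliance_reminders=comp_rem,
        ),
        self_plan=SelfPlan(
            monitoring_schedule=schedule,
            medication_items=meds,
            lifestyle_items=lifestyle,
            education_items=edu,
        ),
        provenance=sorted(
            {pr for p in plans for pr in p.provenance}, key=lambda t: t[0].value
        ),
    )
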