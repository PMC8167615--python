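"""Stateful care engine driving the rule evaluator in two trigger modes.

``on_record`` is the immediate-feedback path: a freshly uploaded
self-monitoring record is validated, single-value warnings are raised, and
event-triggered rules run to fixpoint.  ``on_schedule`` is the periodic
path: advancing the engine day by day performs daily compliance updates,
periodic re-stratification (with plan regeneration on level changes) and
evaluation of all periodic rules that fall due, at their task-specific
frequencies anchored on each patient's enrollment date.

All emitted events are appended to a structured event log (plain dicts, so
the log serializes to JSONL); identical record streams under an identical
configuration replay to identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Any, Optional, Sequence

from .knowledge import FactBase, Rule, builtin_ruleset, evaluate_to_fixpoint, expire_tasks
from .models import (
    ComplianceState,
    Disease,
    DiseaseScope,
    DomainError,
    InsufficientDataError,
    ManagementLevel,
    ManagementPlan,
    PatientProfile,
    RecordKind,
    RiskAssessment,
    SelfMonitoringRecord,
    Severity,
    TaskKind,
    Warning,
)
from .pathway import (
    DEFAULT_CONFIG,
    MOST_INTENSIVE,
    EngineConfig,
    _mean,
    _window,
    assess_risk,
    assign_level,
    detect_warnings,
    generate_plan,
    merge_plans,
    update_compliance,
)


@dataclass
class PatientState:
    profile: PatientProfile
    records: list[SelfMonitoringRecord] = field(default_factory=list)
    record_ids: set[str] = field(default_factory=set)
    factbase: FactBase = field(default_factory=FactBase)
    risk: dict[Disease, RiskAssessment] = field(default_factory=dict)
    levels: dict[Disease, ManagementLevel] = field(default_factory=dict)
    plan: Optional[ManagementPlan] = None
    open_warnings: list[Warning] = field(default_factory=list)
    compliance_history: list[ComplianceState] = field(default_factory=list)


class CareEngine:
    """Replayable decision-support engine over a set of enrolled patients."""

    def __init__(
        self,
        profiles: Sequence[PatientProfile],
        config: EngineConfig = DEFAULT_CONFIG,
        rulesets: Optional[dict[DiseaseScope, list[Rule]]] = None,
    ) -> None:
        self.config = config
        self.rulesets = rulesets or {
            scope: builtin_ruleset(scope)
            for scope in (DiseaseScope.HTN, DiseaseScope.T2DM, DiseaseScope.COPD, DiseaseScope.HM)
        }
        self.patients: dict[str, PatientState] = {
            p.patient_id: PatientState(profile=p) for p in profiles
        }
        if len(self.patients) != len(profiles):
            raise DomainError("duplicate patient_id among profiles")
        self.last_processed: Optional[date] = None
        self.event_log: list[dict[str, Any]] = []

    # -- ruleset selection --------------------------------------------------

    def _rules_for(self, profile: PatientProfile) -> list[Rule]:
        scope = profile.scope
        if scope is DiseaseScope.HM:
            rules = (
                self.rulesets[DiseaseScope.HTN]
                + self.rulesets[DiseaseScope.T2DM]
                + self.rulesets[DiseaseScope.HM]
            )
        else:
            rules = self.rulesets[scope]
        return rules

    # -- fact construction ---------------------------------------------------

    def _build_facts(self, st: PatientState, as_of: date) -> dict[str, Any]:
        p = st.profile
        cfg = self.config
        facts: dict[str, Any] = {
            "profile.age": p.age,
            "profile.sex": p.sex.value,
            "profile.enrollment_date": p.enrollment_date.isoformat(),
            "profile.enrollment_days": (as_of - p.enrollment_date).days,
            "profile.smoker": p.smoker,
            "profile.obese": p.obese,
            "profile.organ_damage": p.organ_damage,
            "profile.comorbidity": p.comorbidity,
        }
        for d in Disease:
            facts[f"profile.disease.{d.value}"] = d in p.diseases
        for d, lvl in st.levels.items():
            facts[f"level.{d.value}"] = lvl.level
        facts["level.provisional"] = any(l.provisional for l in st.levels.values())
        for d, r in st.risk.items():
            facts[f"risk.{d.value}.category"] = r.category

        win = cfg.aggregate_window_days
        bps = _window(st.records, RecordKind.BP, as_of, win)
        facts["agg.bp.n_7d"] = len(bps)
        facts["no_bp_record_7d"] = not bps
        if bps:
            msbp = _mean([r.values["sbp"] for r in bps])
            mdbp = _mean([r.values["dbp"] for r in bps])
            facts["agg.bp.mean_sbp_7d"] = msbp
            facts["agg.bp.mean_dbp_7d"] = mdbp
            facts["agg.bp.weekly_warning"] = len(bps) >= 3 and (
                msbp >= p.bp_target[0] or mdbp >= p.bp_target[1]
            )
        bgs = _window(st.records, RecordKind.BG, as_of, win)
        facts["agg.bg.n_7d"] = len(bgs)
        facts["no_bg_record_7d"] = not bgs
        fbg = [r.values["value"] for r in bgs if r.values["measurement"] == "FBG"]
        pbg = [r.values["value"] for r in bgs if r.values["measurement"] == "PBG"]
        if fbg:
            facts["agg.bg.mean_fbg_7d"] = _mean(fbg)
        if pbg:
            facts["agg.bg.mean_pbg_7d"] = _mean(pbg)
        pefs = _window(st.records, RecordKind.PEF, as_of, win)
        facts["no_pef_record_7d"] = not pefs
        if pefs and p.pef_personal_best:
            latest = max(pefs, key=lambda r: r.timestamp)
            facts["agg.pef.latest_percent_best"] = (
                latest.values["value"] / p.pef_personal_best * 100
            )
        cats = [
            r
            for r in st.records
            if r.kind is RecordKind.psychological and r.values.get("scale") == "CAT"
        ]
        if cats:
            facts["agg.cat.latest"] = max(cats, key=lambda r: r.timestamp).values["score"]

        facts["warning.open_count"] = sum(1 for w in st.open_warnings if w.status == "open")
        facts["warning.any_urgent"] = any(
            w.status == "open" and w.severity is Severity.urgent for w in st.open_warnings
        )
        if st.compliance_history:
            last = st.compliance_history[-1]
            facts["compliance.value"] = last.compliance
            facts["compliance.low"] = last.flagged_low
        return facts

    # -- event helpers -------------------------------------------------------

    def _emit(self, events: list[dict], typ: str, pid: str, when: str, payload: dict) -> None:
        ev = {"type": typ, "timestamp": when, "patient_id": pid, "payload": payload}
        self.event_log.append(ev)
        events.append(ev)

    # -- on-upload trigger mode ----------------------------------------------

    def on_record(self, record: SelfMonitoringRecord) -> list[dict]:
        """Ingest one uploaded record: store it, raise warnings, run
        event-triggered rules to fixpoint.  Returns the emitted events."""
        st = self.patients.get(record.patient_id)
        if st is None:
            raise DomainError(f"unknown patient {record.patient_id!r}")
        if record.record_id is not None and record.record_id in st.record_ids:
            raise DomainError(f"duplicate record id {record.record_id!r}")
        events: list[dict] = []
        new_warnings = detect_warnings(
            [record], st.profile, record.timestamp, self.config
        )
        st.records.append(record)
        if record.record_id is not None:
            st.record_ids.add(record.record_id)
        for w in new_warnings:
            st.open_warnings.append(w)
            self._emit(
                events,
                "warning",
                st.profile.patient_id,
                record.timestamp.isoformat(),
                {
                    "warning_id": w.warning_id,
                    "kind": w.kind.value,
                    "severity": w.severity.value,
                    "evidence": w.triggering_evidence,
                },
            )
        event_rules = [
            r for r in self._rules_for(st.profile) if r.matches_event(record.kind)
        ]
        st.factbase.patient_facts = self._build_facts(st, record.timestamp.date())
        st.factbase.patient_facts["record.kind"] = record.kind.value
        fired = evaluate_to_fixpoint(st.factbase, event_rules, record.timestamp.date())
        for t in fired:
            self._emit(
                events,
                "task",
                st.profile.patient_id,
                record.timestamp.isoformat(),
                {"task_kind": t.task_kind.value, "dedup_key": t.dedup_key, "rule": t.provenance},
            )
        # an abnormal-condition intervention responds to (and closes) the
        # open urgent warnings that triggered it
        if any(t.task_kind is TaskKind.AbnormalConditionIntervention for t in fired):
            for w in st.open_warnings:
                if w.status == "open" and w.severity is Severity.urgent:
                    w.handle()
        return events

    # -- periodic trigger mode -----------------------------------------------

    def on_schedule(self, day: date) -> list[dict]:
        """Advance the engine to ``day``, processing every intermediate day so
        that no periodic evaluation is skipped.  Returns the events emitted by
        this call."""
        if self.last_processed is not None and day < self.last_processed:
            raise DomainError(
                f"date regression: {day} < last processed {self.last_processed}"
            )
        events: list[dict] = []
        if self.last_processed is None:
            days = [day]
        else:
            span = (day - self.last_processed).days
            days = [self.last_processed + timedelta(days=i) for i in range(1, span + 1)]
        for d in days:
            self._process_day(d, events)
            self.last_processed = d
        return events

    def _process_day(self, d: date, events: list[dict]) -> None:
        for pid in sorted(self.patients):
            st = self.patients[pid]
            p = st.profile
            if p.enrollment_date > d:
                continue
            expire_tasks(st.factbase, d)
            days_since = (d - p.enrollment_date).days

            if days_since % self.config.stratify_every_days == 0:
                self._restratify(st, d, events)

            if st.plan is not None:
                state = update_compliance(
                    st.plan, st.records, st.compliance_history, d, self.config
                )
                state.patient_id = pid
                st.compliance_history.append(state)
                self._emit(
                    events,
                    "compliance",
                    pid,
                    d.isoformat(),
                    {
                        "compliance": state.compliance,
                        "scheduled": state.scheduled_tasks,
                        "completed": state.completed_tasks,
                        "flagged_low": state.flagged_low,
                    },
                )

            due = [
                r
                for r in self._rules_for(p)
                if r.trigger.mode == "periodic" and r.trigger.is_due(d, p.enrollment_date)
            ]
            st.factbase.patient_facts = self._build_facts(st, d)
            fired = evaluate_to_fixpoint(st.factbase, due, d)
            for t in fired:
                self._emit(
                    events,
                    "task",
                    pid,
                    d.isoformat(),
                    {"task_kind": t.task_kind.value, "dedup_key": t.dedup_key, "rule": t.provenance},
                )

    def _restratify(self, st: PatientState, d: date, events: list[dict]) -> None:
        p = st.profile
        changed = False
        for disease in sorted(p.diseases, key=lambda x: x.value):
            try:
                risk = assess_risk(p, st.records, disease, d, self.config)
            except InsufficientDataError:
                risk = None
            if risk is not None:
                st.risk[disease] = risk
            if disease is Disease.COPD and risk is None:
                level = ManagementLevel(
                    disease, MOST_INTENSIVE[disease], {"n_readings": 0}, d, provisional=True
                )
                p.current_levels[disease] = level.level
            else:
                level = assign_level(p, risk, st.records, disease, d, self.config)
            prev = st.levels.get(disease)
            if prev is None or prev.level != level.level:
                changed = True
                self._emit(
                    events,
                    "level",
                    p.patient_id,
                    d.isoformat(),
                    {
                        "disease": disease.value,
                        "level": level.level,
                        "previous": prev.level if prev else None,
                        "provisional": level.provisional,
                    },
                )
            st.levels[disease] = level
        if changed or st.plan is None:
            singles = [
                generate_plan(p, st.levels[dz], st.risk.get(dz), self.config)
                for dz in sorted(p.diseases, key=lambda x: x.value)
            ]
            st.plan = merge_plans(singles, self.rulesets.get(DiseaseScope.HM))
            self._emit(
                events,
                "plan",
                p.patient_id,
                d.isoformat(),
                {
                    "followup_interval_days": st.plan.doctor_plan.followup_interval_days,
                    "next_followup": st.plan.doctor_plan.next_followup.isoformat(),
                    "monitoring": {
                        k.value: v for k, v in st.plan.self_plan.monitoring_schedule.items()
                    },
                    "lifestyle": sorted(st.plan.self_plan.lifestyle_items),
                },
            )
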