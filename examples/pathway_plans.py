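"""Risk assessment, stratification and plan generation for one patient.

Builds a hypertensive-diabetic (HM) patient with a week of self-monitoring,
assesses risk, assigns a management level per disease, generates the two
single-disease plans and merges them into one multimorbidity plan.
"""

from datetime import date, datetime, timedelta

from carepath import (
    Disease,
    PatientProfile,
    RecordKind,
    SelfMonitoringRecord,
    Sex,
    assess_risk,
    assign_level,
    generate_plan,
    merge_plans,
)

enroll = date(2021, 3, 1)
as_of = enroll + timedelta(days=30)

patient = PatientProfile(
    patient_id="DEMO",
    age=62,
    sex=Sex.female,
    diseases=frozenset({Disease.HTN, Disease.T2DM}),
    enrollment_date=enroll,
    smoker=True,
)

records = []
for i in range(6):
    ts = datetime(2021, 3, 25 + i, 8, 0)
    records.append(
        SelfMonitoringRecord("DEMO", ts, RecordKind.BP, {"sbp": 152 + i, "dbp": 92})
    )
    records.append(
        SelfMonitoringRecord(
            "DEMO", ts.replace(hour=7), RecordKind.BG,
            {"measurement": "FBG", "value": 6.3, "ketone": False},
        )
    )

plans = []
for disease in sorted(patient.diseases, key=lambda d: d.value):
    risk = assess_risk(patient, records, disease, as_of)
    level = assign_level(patient, risk, records, disease, as_of)
    plan = generate_plan(patient, level, risk)
    plans.append(plan)
    print(f"{disease.value}: risk={risk.category!r}  level={level.level} "
          f"(follow-up every {plan.doctor_plan.followup_interval_days} d)")

merged = merge_plans(plans)
print("\nMerged multimorbidity plan")
print("  follow-up interval:", merged.doctor_plan.followup_interval_days, "days",
      "(minimum over the single-disease plans)")
print("  monitoring:", {k.value: round(v, 2) for k, v in
                        merged.self_plan.monitoring_schedule.items()},
      "(submissions per day, per-kind maximum)")
print("  lifestyle:", ", ".join(sorted(merged.self_plan.lifestyle_items)))
print("  -> shared items appear once; conflicting exercise prescriptions "
      "resolve to the more conservative variant")
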