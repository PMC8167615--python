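# Type 2 diabetes care pathway: 11 rules covering the 8 in-engine task
# kinds.  Stratification into 3 levels by fasting/postprandial glucose
# target attainment; follow-up q3mo / q1mo / q2wk for levels I / II / III.
- rule_id: t2dm-risk-assessment
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 90}}
  condition:
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: RiskAssessment
    parameters: {factors: [bp_control, bg_control, lipid_control]}
  priority: 0

- rule_id: t2dm-stratify
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 7}}
  condition:
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: HierarchicalManagement
    parameters: {levels: ["I", "II", "III"], basis: bg_target_attainment}
  priority: 1

- rule_id: t2dm-followup-level1
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 90}}
  condition:
    - {fact: level.T2DM, op: "==", value: "I"}
    - {fact: tasks.HierarchicalManagement, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 90}
  valid_duration_days: 90
  priority: 2

- rule_id: t2dm-followup-level2
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: level.T2DM, op: "==", value: "II"}
    - {fact: tasks.HierarchicalManagement, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 30}
  valid_duration_days: 30
  priority: 2

- rule_id: t2dm-followup-level3
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 14}}
  condition:
    - {fact: level.T2DM, op: "==", value: "III"}
    - {fact: tasks.HierarchicalManagement, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 14}
  valid_duration_days: 14
  priority: 2

- rule_id: t2dm-abnormal-single
  disease_scope: T2DM
  trigger: {event: {record_kinds: [BG]}}
  condition:
    - {fact: warning.any_urgent, op: "==", value: true}
  action:
    task_kind: AbnormalConditionIntervention
    parameters: {source: single_value_or_ketone}
  priority: 0

- rule_id: t2dm-medication-guidance
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: MedicationGuidance
    parameters: {guidance: review_hypoglycemic_therapy_or_insulin}
  priority: 3

- rule_id: t2dm-lifestyle-guidance
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: LifestyleGuidance
    parameters:
      items: [control_weight, balanced_diet, reduce_sodium, no_smoking_drinking, moderate_exercise, reduce_stress]
  priority: 3

- rule_id: t2dm-health-education
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: HealthEducation
    parameters: {topic: diabetes_basics}
  priority: 4

- rule_id: t2dm-compliance
  disease_scope: T2DM
  trigger: {periodic: {frequency_days: 1}}
  condition:
    - {fact: compliance.low, op: "==", value: true}
  action:
    task_kind: ComplianceManagement
    parameters: {extra_followup: true}
  priority: 5

- rule_id: t2dm-hypoglycemia-education
  disease_scope: T2DM
  trigger: {event: {record_kinds: [BG]}}
  condition:
    - {fact: tasks.AbnormalConditionIntervention, op: exists}
  action:
    task_kind: HealthEducation
    parameters: {topic: hypoglycemia_recognition}
  priority: 6
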