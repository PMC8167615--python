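# Hypertension care pathway: 10 rules covering the 8 in-engine task kinds.
# Risk assessment quarterly; stratification weekly into 2 levels by target
# attainment; follow-up q3mo (level I) / q2wk (level II); abnormal-condition
# intervention on urgent single values and weekly aggregates; monthly
# medication review, lifestyle prescription and education; daily compliance
# management with extra follow-ups when compliance is low.
- rule_id: htn-risk-assessment
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 90}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
  action:
    task_kind: RiskAssessment
    parameters: {factors: [cardiovascular_risk, target_organ_damage, comorbidity]}
  priority: 0

- rule_id: htn-stratify
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 7}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
  action:
    task_kind: HierarchicalManagement
    parameters: {levels: ["I", "II"], basis: bp_target_attainment}
  priority: 1

- rule_id: htn-followup-level1
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 90}}
  condition:
    - {fact: level.HTN, op: "==", value: "I"}
    - {fact: tasks.HierarchicalManagement, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 90}
  valid_duration_days: 90
  priority: 2

- rule_id: htn-followup-level2
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 14}}
  condition:
    - {fact: level.HTN, op: "==", value: "II"}
    - {fact: tasks.HierarchicalManagement, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 14}
  valid_duration_days: 14
  priority: 2

- rule_id: htn-abnormal-single
  disease_scope: HTN
  trigger: {event: {record_kinds: [BP]}}
  condition:
    - {fact: warning.any_urgent, op: "==", value: true}
  action:
    task_kind: AbnormalConditionIntervention
    parameters: {source: single_value}
  priority: 0

- rule_id: htn-abnormal-weekly
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 7}}
  condition:
    - {fact: agg.bp.weekly_warning, op: "==", value: true}
  action:
    task_kind: AbnormalConditionIntervention
    parameters: {source: weekly_aggregate}
  priority: 2

- rule_id: htn-medication-guidance
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
  action:
    task_kind: MedicationGuidance
    parameters: {guidance: review_antihypertensive_therapy}
  priority: 3

- rule_id: htn-lifestyle-guidance
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
  action:
    task_kind: LifestyleGuidance
    parameters:
      items: [reduce_sodium, control_weight, no_smoking_drinking, increase_exercise, reduce_stress]
  priority: 3

- rule_id: htn-health-education
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
  action:
    task_kind: HealthEducation
    parameters: {topic: hypertension_basics}
  priority: 4

- rule_id: htn-compliance
  disease_scope: HTN
  trigger: {periodic: {frequency_days: 1}}
  condition:
    - {fact: compliance.low, op: "==", value: true}
  action:
    task_kind: ComplianceManagement
    parameters: {extra_followup: true}
  priority: 5
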