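# COPD care pathway.  No separate stratification task: the management level
# (I-IV) is taken directly from the risk-assessment grid, and medication
# guidance is handled manually by care providers, not by the engine.
# Follow-up is every 2 weeks for every level.
- rule_id: copd-risk-assessment
  disease_scope: COPD
  trigger: {periodic: {frequency_days: 14}}
  condition:
    - {fact: profile.disease.COPD, op: "==", value: true}
  action:
    task_kind: RiskAssessment
    parameters: {factors: [pef_percent_best, cat_score, exacerbations, hospitalizations]}
  priority: 0

- rule_id: copd-followup
  disease_scope: COPD
  trigger: {periodic: {frequency_days: 14}}
  condition:
    - {fact: profile.disease.COPD, op: "==", value: true}
    - {fact: tasks.RiskAssessment, op: exists}
  action:
    task_kind: RegularFollowUp
    parameters: {interval_days: 14}
  valid_duration_days: 14
  priority: 2

- rule_id: copd-abnormal-single
  disease_scope: COPD
  trigger: {event: {record_kinds: [PEF, psychological, discomfort]}}
  condition:
    - {fact: warning.any_urgent, op: "==", value: true}
  action:
    task_kind: AbnormalConditionIntervention
    parameters: {source: pef_scale_or_exacerbation}
  priority: 0

- rule_id: copd-lifestyle-guidance
  disease_scope: COPD
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.COPD, op: "==", value: true}
  action:
    task_kind: LifestyleGuidance
    parameters:
      items: [avoid_smoking, increase_regular_exercise, rehabilitation_exercises]
  priority: 3

- rule_id: copd-health-education
  disease_scope: COPD
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.COPD, op: "==", value: true}
  action:
    task_kind: HealthEducation
    parameters: {topic: copd_basics}
  priority: 4

- rule_id: copd-compliance
  disease_scope: COPD
  trigger: {periodic: {frequency_days: 1}}
  condition:
    - {fact: compliance.low, op: "==", value: true}
  action:
    task_kind: ComplianceManagement
    parameters: {extra_followup: true}
  priority: 5
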