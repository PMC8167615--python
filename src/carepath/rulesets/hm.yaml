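# Multimorbidity (hypertension + type 2 diabetes) merge ruleset.
# Single-disease pathways run separately; these rules govern merging of the
# resulting plans: redundant lifestyle items collapse (set union) and
# conflicting prescriptions resolve to the most conservative variant —
# the first element of each conflict group below wins.
- rule_id: hm-merge-lifestyle
  disease_scope: HM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: LifestyleGuidance
    parameters:
      conflict_groups:
        - [moderate_exercise, increase_exercise]
        - [balanced_diet, reduce_sodium_only]
  priority: 1

- rule_id: hm-health-education
  disease_scope: HM
  trigger: {periodic: {frequency_days: 30}}
  condition:
    - {fact: profile.disease.HTN, op: "==", value: true}
    - {fact: profile.disease.T2DM, op: "==", value: true}
  action:
    task_kind: HealthEducation
    parameters: {topic: multimorbidity_self_management}
  priority: 4
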