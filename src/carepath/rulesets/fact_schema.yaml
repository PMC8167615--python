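# Published fact schema: every fact_path a rule condition may reference.
# Paths under `tasks.` (derived pathway tasks, tested with `exists`) are
# implicit and not listed here.
profile.age: {type: number, unit: years, description: patient age}
profile.sex: {type: string, description: male | female}
profile.enrollment_date: {type: date, description: ISO-8601 enrollment date}
profile.enrollment_days: {type: integer, unit: days, description: days since enrollment}
profile.disease.HTN: {type: boolean, description: hypertension diagnosed}
profile.disease.T2DM: {type: boolean, description: type 2 diabetes diagnosed}
profile.disease.COPD: {type: boolean, description: COPD diagnosed}
profile.smoker: {type: boolean}
profile.obese: {type: boolean}
profile.organ_damage: {type: boolean, description: target organ damage}
profile.comorbidity: {type: boolean, description: clinical comorbidity}
level.HTN: {type: string, description: current HTN level (I-II)}
level.T2DM: {type: string, description: current T2DM level (I-III)}
level.COPD: {type: string, description: current COPD level (I-IV)}
level.provisional: {type: boolean, description: level assigned on insufficient data}
risk.HTN.category: {type: string}
risk.T2DM.category: {type: string}
risk.COPD.category: {type: string}
agg.bp.mean_sbp_7d: {type: number, unit: mmHg, description: trailing 7-day mean SBP}
agg.bp.mean_dbp_7d: {type: number, unit: mmHg, description: trailing 7-day mean DBP}
agg.bp.n_7d: {type: integer, description: BP readings in trailing 7 days}
agg.bp.weekly_warning: {type: boolean, description: weekly-aggregate BP warning active}
agg.bg.mean_fbg_7d: {type: number, unit: mmol/L}
agg.bg.mean_pbg_7d: {type: number, unit: mmol/L}
agg.bg.n_7d: {type: integer}
agg.pef.latest_percent_best: {type: number, unit: percent, description: latest PEF as % of personal best}
agg.cat.latest: {type: number, description: latest CAT score (0-40)}
agg.exacerbations_12m: {type: integer, description: acute exacerbations in 12 months}
agg.hospitalizations_12m: {type: integer}
warning.open_count: {type: integer, description: currently open warnings}
warning.any_urgent: {type: boolean, description: any open urgent warning}
compliance.value: {type: number, description: trailing-window compliance fraction}
compliance.low: {type: boolean, description: compliance below threshold}
no_bp_record_7d: {type: boolean, description: pre-computed absence fact}
no_bg_record_7d: {type: boolean, description: pre-computed absence fact}
no_pef_record_7d: {type: boolean, description: pre-computed absence fact}
record.kind: {type: string, description: kind of the record being uploaded (event rules)}
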