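"""Disease-specific pathway logic: risk, levels, scheduling, warnings,
compliance, plans and multimorbidity merging."""

import itertools
from datetime import date, datetime, timedelta

import pytest

from carepath import (
    Disease,
    DomainError,
    EngineConfig,
    InsufficientDataError,
    LEVELS,
    ManagementLevel,
    RecordKind,
    ValidationError,
    assess_risk,
    assign_level,
    detect_warnings,
    generate_plan,
    merge_plans,
    schedule_followup,
    update_compliance,
)
from conftest import ENROLL, bg, bp, cat, discomfort, pef

AS_OF = ENROLL + timedelta(days=30)
AS_OF_DT = datetime.combine(AS_OF, datetime.min.time())


# -- follow-up scheduling -----------------------------------------------------

INTERVAL_TABLE = {
    (Disease.HTN, "I"): 90,
    (Disease.HTN, "II"): 14,
    (Disease.T2DM, "I"): 90,
    (Disease.T2DM, "II"): 30,
    (Disease.T2DM, "III"): 14,
    (Disease.COPD, "I"): 14,
    (Disease.COPD, "II"): 14,
    (Disease.COPD, "III"): 14,
    (Disease.COPD, "IV"): 14,
}


@pytest.mark.parametrize("disease,level", list(INTERVAL_TABLE))
def test_followup_intervals_match_pathway_table(disease, level):
    interval, nxt = schedule_followup(disease, level, date(2021, 1, 1))
    assert interval == INTERVAL_TABLE[(disease, level)]
    assert nxt == date(2021, 1, 1) + timedelta(days=interval)


def test_unknown_level_is_domain_error():
    with pytest.raises(DomainError):
        schedule_followup(Disease.HTN, "III", date(2021, 1, 1))


def test_htn_level2_interval_configurable_within_range():
    cfg = EngineConfig(htn_level2_interval_days=28)
    assert schedule_followup(Disease.HTN, "II", date(2021, 1, 1), cfg)[0] == 28
    with pytest.raises(ValidationError):
        EngineConfig(htn_level2_interval_days=35)


# -- risk assessment ----------------------------------------------------------

def test_htn_no_risk_factors_is_lowest_category(htn_profile):
    htn_profile.age = 50  # below the male age cutoff
    risk = assess_risk(htn_profile, [], Disease.HTN, AS_OF)
    assert risk.category == "low"
    assert risk.factors["cardiovascular_risk_count"] == 0


def test_htn_organ_damage_forces_high(htn_profile):
    htn_profile.organ_damage = True
    assert assess_risk(htn_profile, [], Disease.HTN, AS_OF).category == "high"


def test_t2dm_all_controlled_category(t2dm_profile):
    records = [bp("D001", 25, 125, 80), bp("D001", 26, 128, 82)] + [
        bg("D001", 24 + i, 6.0) for i in range(4)
    ]
    risk = assess_risk(t2dm_profile, records, Disease.T2DM, AS_OF)
    assert risk.factors == {
        "bp_controlled": True,
        "bg_controlled": True,
        "lipid_controlled": True,
    }
    assert risk.category == "all_controlled"


@pytest.mark.parametrize(
    "cat_score,n_exac,expected",
    [
        (5, 0, "A"),
        (15, 0, "B"),
        (5, 2, "C"),
        (15, 2, "D"),  # high symptom burden and high exacerbation risk
    ],
)
def test_copd_risk_grid_exhaustive(copd_profile, cat_score, n_exac, expected):
    records = [cat("C001", 25, cat_score)] + [
        discomfort("C001", 10 + i, exacerbation=True) for i in range(n_exac)
    ]
    risk = assess_risk(copd_profile, records, Disease.COPD, AS_OF)
    assert risk.category == expected


def test_copd_without_pef_or_cat_is_insufficient(copd_profile):
    with pytest.raises(InsufficientDataError):
        assess_risk(copd_profile, [discomfort("C001", 5)], Disease.COPD, AS_OF)


def test_risk_for_unmanaged_disease_is_domain_error(htn_profile):
    with pytest.raises(DomainError):
        assess_risk(htn_profile, [], Disease.T2DM, AS_OF)


# -- level assignment ---------------------------------------------------------

def test_htn_at_target_is_level_one(htn_profile):
    records = [bp("H001", 24 + i, 132, 82) for i in range(5)]
    lvl = assign_level(htn_profile, None, records, Disease.HTN, AS_OF)
    assert (lvl.level, lvl.provisional) == ("I", False)
    assert htn_profile.current_levels[Disease.HTN] == "I"


def test_htn_above_target_is_level_two(htn_profile):
    records = [bp("H001", 24 + i, 152, 96) for i in range(5)]
    assert assign_level(htn_profile, None, records, Disease.HTN, AS_OF).level == "II"


def _t2dm_oracle(fbg_mean, pbg_mean, fbg_target=7.0, pbg_target=10.0):
    """Explicit banding-table lookup."""
    fbg_ok, pbg_ok = fbg_mean < fbg_target, pbg_mean < pbg_target
    return {(True, True): "I", (True, False): "II", (False, True): "II",
            (False, False): "III"}[(fbg_ok, pbg_ok)]


@pytest.mark.parametrize("fbg_val", [5.5, 6.2, 7.5, 8.5, 10.0])
@pytest.mark.parametrize("pbg_val", [8.0, 8.9, 10.5, 12.0])
def test_t2dm_banding_matches_lookup_oracle(t2dm_profile, fbg_val, pbg_val):
    records = [bg("D001", 24 + i, fbg_val, "FBG") for i in range(3)] + [
        bg("D001", 24 + i, pbg_val, "PBG") for i in range(3)
    ]
    lvl = assign_level(t2dm_profile, None, records, Disease.T2DM, AS_OF)
    assert lvl.level == _t2dm_oracle(fbg_val, pbg_val)


def test_t2dm_single_exceeded_measure_is_level_two(t2dm_profile):
    records = [bg("D001", 24 + i, 8.5, "FBG") for i in range(3)]
    assert assign_level(t2dm_profile, None, records, Disease.T2DM, AS_OF).level == "II"


def test_empty_window_assigns_provisional_most_intensive(htn_profile, t2dm_profile):
    for profile, disease, expected in [
        (htn_profile, Disease.HTN, "II"),
        (t2dm_profile, Disease.T2DM, "III"),
    ]:
        lvl = assign_level(profile, None, [], disease, AS_OF)
        assert (lvl.level, lvl.provisional) == (expected, True)


def test_copd_level_comes_from_risk_grid(copd_profile):
    risk = assess_risk(copd_profile, [cat("C001", 25, 15)] +
                       [discomfort("C001", 10 + i, exacerbation=True) for i in range(2)],
                       Disease.COPD, AS_OF)
    lvl = assign_level(copd_profile, risk, [], Disease.COPD, AS_OF)
    assert lvl.level == "IV"


def test_level_cardinalities():
    assert tuple(len(LEVELS[d]) for d in (Disease.HTN, Disease.T2DM, Disease.COPD)) == (2, 3, 4)


# -- warnings -----------------------------------------------------------------

def test_urgent_single_value_bp(htn_profile):
    ws = detect_warnings([bp("H001", 29, 185, 100)], htn_profile, AS_OF_DT)
    assert [(w.kind.value, w.severity.value) for w in ws] == [("single_value", "urgent")]
    assert ws[0].triggering_evidence


def test_weekly_aggregate_bp_warning(htn_profile):
    records = [bp("H001", 24 + i, 150, 85) for i in range(5)]
    ws = detect_warnings(records, htn_profile, AS_OF_DT)
    assert [w.kind.value for w in ws] == ["weekly_aggregate"]


def test_in_range_bp_raises_nothing(htn_profile):
    assert detect_warnings([bp("H001", 29, 125, 80)], htn_profile, AS_OF_DT) == []


def test_ketone_and_hypoglycemia_are_urgent(t2dm_profile):
    ws = detect_warnings([bg("D001", 29, 3.0, ketone=True)], t2dm_profile, AS_OF_DT)
    assert {w.kind.value for w in ws} == {"single_value", "ketone"}
    assert all(w.severity.value == "urgent" for w in ws)


def test_pef_zones(copd_profile):
    # personal best 500: <80% notice, <60% urgent
    notice = detect_warnings([pef("C001", 29, 380)], copd_profile, AS_OF_DT)
    urgent = detect_warnings([pef("C001", 29, 280)], copd_profile, AS_OF_DT)
    assert [w.severity.value for w in notice] == ["notice"]
    assert [w.severity.value for w in urgent] == ["urgent"]


def test_record_kind_inconsistent_with_disease(copd_profile):
    with pytest.raises(DomainError):
        detect_warnings([bp("C001", 29, 120, 80)], copd_profile, AS_OF_DT)


def test_raising_thresholds_never_increases_warning_count(htn_profile):
    records = [bp("H001", 22 + i, 150 + 8 * i, 95) for i in range(7)]
    base = EngineConfig()
    stricter = EngineConfig(urgent_sbp_high=200.0, urgent_dbp_high=130.0)
    n_base = len(detect_warnings(records, htn_profile, AS_OF_DT, base))
    n_strict = len(detect_warnings(records, htn_profile, AS_OF_DT, stricter))
    assert n_strict <= n_base


# -- compliance ---------------------------------------------------------------

def _htn_plan(htn_profile, level="II"):
    lvl = ManagementLevel(Disease.HTN, level, {}, AS_OF)
    return generate_plan(htn_profile, lvl)


def test_full_compliance_not_flagged(htn_profile):
    from carepath import SelfMonitoringRecord

    plan = _htn_plan(htn_profile)
    records = [bp("H001", 23 + i, 125, 80) for i in range(7)]
    records += [
        SelfMonitoringRecord("H001", r.timestamp.replace(hour=20), RecordKind.medication, {})
        for r in records[:7]
    ]
    state = update_compliance(plan, records, [], AS_OF)
    assert state.compliance == 1.0 and not state.flagged_low


def test_zero_compliance_flagged(htn_profile):
    plan = _htn_plan(htn_profile)
    state = update_compliance(plan, [], [], AS_OF)
    assert state.compliance == 0.0 and state.flagged_low


def test_partial_compliance_ratio_vs_threshold(htn_profile):
    # 3 of 14 scheduled items (7 BP + 7 medication) completed -> flagged
    plan = _htn_plan(htn_profile)
    records = [bp("H001", 23 + i, 125, 80) for i in range(3)]
    state = update_compliance(plan, records, [], AS_OF)
    assert state.scheduled_tasks == 14 and state.completed_tasks == 3
    assert state.compliance == pytest.approx(3 / 14)
    assert state.flagged_low


# -- plans and merging --------------------------------------------------------

def test_htn_level1_plan_contents(htn_profile):
    plan = generate_plan(htn_profile, ManagementLevel(Disease.HTN, "I", {}, AS_OF))
    assert plan.self_plan.lifestyle_items == {
        "reduce_sodium", "control_weight", "no_smoking_drinking",
        "increase_exercise", "reduce_stress",
    }
    assert RecordKind.BP in plan.self_plan.monitoring_schedule
    assert plan.doctor_plan.followup_interval_days == 90


def test_copd_plan_has_no_engine_medication(copd_profile):
    for level in LEVELS[Disease.COPD]:
        plan = generate_plan(copd_profile, ManagementLevel(Disease.COPD, level, {}, AS_OF))
        assert plan.self_plan.medication_items == []


def test_t2dm_level3_monitors_bg_at_highest_frequency(t2dm_profile):
    freqs = [
        generate_plan(t2dm_profile, ManagementLevel(Disease.T2DM, lvl, {}, AS_OF))
        .self_plan.monitoring_schedule[RecordKind.BG]
        for lvl in LEVELS[Disease.T2DM]
    ]
    assert freqs[-1] == max(freqs)
    plan3 = generate_plan(t2dm_profile, ManagementLevel(Disease.T2DM, "III", {}, AS_OF))
    assert plan3.doctor_plan.followup_interval_days == 14


def test_merge_single_plan_is_identity(htn_profile):
    plan = _htn_plan(htn_profile, "I")
    assert merge_plans([plan]) is plan


def test_merge_worked_example(hm_profile):
    htn = generate_plan(hm_profile, ManagementLevel(Disease.HTN, "I", {}, AS_OF))
    t2dm = generate_plan(hm_profile, ManagementLevel(Disease.T2DM, "III", {}, AS_OF))
    merged = merge_plans([htn, t2dm])
    # min follow-up interval; shared lifestyle items collapse; both indices monitored
    assert merged.doctor_plan.followup_interval_days == 14
    assert sorted(merged.self_plan.lifestyle_items).count("reduce_sodium") == 1
    assert sorted(merged.self_plan.lifestyle_items).count("control_weight") == 1
    assert {RecordKind.BP, RecordKind.BG} <= set(merged.self_plan.monitoring_schedule)


def test_merge_conflicting_exercise_keeps_conservative(hm_profile):
    htn = generate_plan(hm_profile, ManagementLevel(Disease.HTN, "I", {}, AS_OF))
    t2dm = generate_plan(hm_profile, ManagementLevel(Disease.T2DM, "I", {}, AS_OF))
    merged = merge_plans([htn, t2dm])
    assert "moderate_exercise" in merged.self_plan.lifestyle_items
    assert "increase_exercise" not in merged.self_plan.lifestyle_items


def test_merge_min_interval_law_exhaustive(hm_profile):
    """Over the full 2x3 HM level grid the merged interval is the minimum
    of the component intervals, and merging commutes."""
    for h_lvl, d_lvl in itertools.product(LEVELS[Disease.HTN], LEVELS[Disease.T2DM]):
        htn = generate_plan(hm_profile, ManagementLevel(Disease.HTN, h_lvl, {}, AS_OF))
        t2dm = generate_plan(hm_profile, ManagementLevel(Disease.T2DM, d_lvl, {}, AS_OF))
        ab = merge_plans([htn, t2dm])
        ba = merge_plans([t2dm, htn])
        assert ab.doctor_plan.followup_interval_days == min(
            htn.doctor_plan.followup_interval_days, t2dm.doctor_plan.followup_interval_days
        )
        assert ab == ba


def test_merge_unsupported_combination(copd_profile, htn_profile):
    copd = generate_plan(copd_profile, ManagementLevel(Disease.COPD, "I", {}, AS_OF))
    htn = _htn_plan(htn_profile, "I")
    with pytest.raises(DomainError):
        merge_plans([copd, htn])
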