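"""Retrospective evaluation: paired t, before/after windows, causal
extraction, propensity estimators, refuters, efficiency metrics."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

from carepath import (
    CausalRow,
    Disease,
    DomainError,
    InsufficientDataError,
    InterventionKind,
    InterventionRecord,
    PatientProfile,
    Sex,
    ValidationError,
    before_after,
    descriptive_summary,
    efficiency,
    estimate_ate_naive,
    estimate_ate_psm,
    estimate_ate_pss,
    extract_causal_dataset,
    fit_propensity,
    paired_t,
    refute,
    simulate_causal_rows,
)
from conftest import ENROLL, bp


def make_row(t, y, age=60.0, level=2, warning=False, mtime=100.0):
    return CausalRow(t, y, age, level, warning, mtime)


# -- paired t -----------------------------------------------------------------

def test_paired_t_closed_form_worked_example():
    t, df, p = paired_t([2, 4, 3])
    assert t == pytest.approx(5.196152, abs=1e-5)
    assert df == 2
    assert p == pytest.approx(0.0351, abs=1e-3)


def test_paired_t_symmetry_gives_zero_statistic():
    t, _, p = paired_t([-1, 1])
    assert t == 0 and p == 1


def test_paired_t_preconditions():
    with pytest.raises(InsufficientDataError):
        paired_t([3.0])
    with pytest.raises(ValidationError):
        paired_t([2.0, 2.0, 2.0])


def test_paired_t_agrees_with_scipy_on_grid():
    rng = np.random.default_rng(1)
    for n in (2, 5, 20, 100):
        before = rng.normal(130, 10, n)
        after = before + rng.normal(-2, 4, n)
        t, df, p = paired_t(after - before)
        ref = stats.ttest_rel(after, before)
        assert t == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


# -- before/after -------------------------------------------------------------

def test_constant_outcome_has_zero_difference():
    enr = {"A": ENROLL, "B": ENROLL}
    records = [bp(pid, d, 140, 85) for pid in "AB" for d in (0, 5, 30, 35)]
    with pytest.raises(ValidationError):
        # zero variance in differences is degenerate for the paired test
        before_after(records, "SBP", 30, enr)


def test_before_after_hand_computed_t():
    enr = {p: ENROLL for p in ("A", "B", "C")}
    befores = {"A": 120, "B": 130, "C": 140}
    afters = {"A": 118, "B": 126, "C": 137}
    records = [bp(p, 1, befores[p], 75) for p in enr]
    records += [bp(p, 31, afters[p], 75) for p in enr]
    cmp = before_after(records, "SBP", 30, enr)
    assert cmp.n_patients == 3
    assert cmp.mean_before == pytest.approx(130.0)
    assert cmp.mean_after == pytest.approx(127.0)
    assert cmp.t_statistic == pytest.approx(-5.196152, abs=1e-5)
    assert cmp.p_value == pytest.approx(0.0351, abs=1e-3)


def test_patient_without_after_records_excluded():
    enr = {p: ENROLL for p in ("A", "B", "C")}
    records = [bp(p, 1, 130 + i, 75) for i, p in enumerate(enr)]
    records += [bp(p, 31, 128 + 2 * i, 75) for i, p in enumerate(["A", "B"])]
    cmp = before_after(records, "SBP", 30, enr)
    assert cmp.n_patients == 2


def test_window_boundaries_are_half_open():
    """A record exactly at enrollment + 14 d falls outside the before
    window; one exactly at enrollment + span + 14 d falls outside the
    after window."""
    enr = {"A": ENROLL, "B": ENROLL}
    offset = {"A": 0, "B": 4}
    inside = [bp(p, 0, 130 + offset[p], 80) for p in enr]
    inside += [bp(p, 13, 132 + offset[p], 80) for p in enr]
    boundary = [bp(p, 14, 170, 100) for p in enr]  # excluded from both windows
    after_in = [bp(p, 30, 120, 75) for p in enr] + [bp(p, 43, 124 + offset[p], 75) for p in enr]
    after_out = [bp(p, 44, 170, 100) for p in enr]  # excluded
    cmp = before_after(inside + boundary + after_in + after_out, "SBP", 30, enr)
    assert cmp.mean_before == pytest.approx(133.0)
    assert cmp.mean_after == pytest.approx(123.0)


# -- causal extraction --------------------------------------------------------

def _profile(pid="A", age=60.0):
    return PatientProfile(
        patient_id=pid, age=age, sex=Sex.male,
        diseases=frozenset({Disease.HTN}), enrollment_date=ENROLL,
    )


def test_no_interventions_gives_only_control_rows():
    records = [bp("A", d, 130, 80) for d in range(0, 90, 3)]
    rows, _ = extract_causal_dataset(records, [], [_profile()], outcome="SBP")
    assert rows and all(not r.treatment for r in rows)


def test_treated_row_outcome_is_windowed_mean():
    iv_day = ENROLL + timedelta(days=100)
    records = [bp("A", 110, 150, 90), bp("A", 120, 140, 85)]
    records += [bp("A", d, 135, 82) for d in range(0, 14, 3)]  # keep patient active
    ivs = [
        InterventionRecord("GP1", "A", InterventionKind.regular_followup, iv_day, iv_day)
    ]
    rows, log = extract_causal_dataset(records, ivs, [_profile()], outcome="SBP")
    treated = [r for r in rows if r.treatment]
    assert len(treated) == 1
    assert treated[0].outcome == pytest.approx(145.0)
    assert treated[0].management_time == 100.0


def test_intervention_with_no_following_records_is_dropped():
    iv_day = ENROLL + timedelta(days=100)
    records = [bp("A", d, 135, 82) for d in range(0, 90, 3)]  # all before day 100
    ivs = [
        InterventionRecord("GP1", "A", InterventionKind.regular_followup, iv_day, iv_day)
    ]
    rows, log = extract_causal_dataset(records, ivs, [_profile()], outcome="SBP")
    assert not any(r.treatment for r in rows)
    assert log["dropped_empty_episodes"] >= 1


# -- propensity model ---------------------------------------------------------

def test_random_treatment_scores_concentrate_at_treated_fraction():
    rng = np.random.default_rng(2)
    rows = [
        make_row(bool(rng.random() < 0.4), float(rng.normal(140, 10)),
                 age=float(rng.normal(58, 12)), level=int(rng.integers(1, 4)),
                 warning=bool(rng.random() < 0.3), mtime=float(rng.uniform(0, 700)))
        for _ in range(3000)
    ]
    scores = fit_propensity(rows)
    frac = np.mean([r.treatment for r in rows])
    assert abs(scores.mean() - frac) < 0.02
    assert scores.std() < 0.05


def test_single_class_data_rejected():
    rows = [make_row(True, 140.0) for _ in range(10)]
    with pytest.raises(DomainError):
        fit_propensity(rows)


def test_propensity_matches_brute_force_mle():
    """Coefficients (via the predicted scores) agree with direct numeric
    maximization of the logistic likelihood."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(4)
    rows = [
        make_row(
            bool(rng.random() < 1 / (1 + math.exp(-(0.5 * w - 0.2 * (a - 58) / 12.3)))),
            140.0,
            age=float(a), level=int(l), warning=bool(w), mtime=float(m),
        )
        for a, l, w, m in zip(
            rng.normal(58, 12, 200), rng.integers(1, 4, 200),
            rng.random(200) < 0.5, rng.uniform(0, 700, 200),
        )
    ]
    from carepath.evaluate import _design

    X, t = _design(rows)
    Xc = np.column_stack([np.ones(len(t)), X])

    def nll(beta):
        z = Xc @ beta
        return np.sum(np.logaddexp(0, z) - t * z)

    res = minimize(nll, np.zeros(5), method="BFGS",
                   jac=lambda b: Xc.T @ (1 / (1 + np.exp(-(Xc @ b))) - t),
                   options={"gtol": 1e-10})
    oracle_scores = 1 / (1 + np.exp(-(Xc @ res.x)))
    assert np.allclose(fit_propensity(rows), oracle_scores, atol=1e-4)


# -- ATE estimators -----------------------------------------------------------

def test_psm_null_effect_randomized_within_half_mmhg():
    from carepath import SimConfig

    rows, tau = simulate_causal_rows(
        2000, SimConfig(true_ate={"SBP": 0.0, "FBG": 0.0, "PEF": 0.0}),
        seed=21, confounded=False,
    )
    scores = fit_propensity(rows)
    assert abs(estimate_ate_psm(rows, scores, seed=21).estimate) < 0.5


def test_psm_positivity_error_with_disjoint_scores():
    rows = [make_row(True, 150.0) for _ in range(5)] + [
        make_row(False, 140.0) for _ in range(5)
    ]
    scores = np.array([0.9] * 5 + [0.1] * 5)
    with pytest.raises(DomainError, match="positivity"):
        estimate_ate_psm(rows, scores, caliper=0.2)


def test_pss_requires_at_least_two_strata():
    rows, _ = simulate_causal_rows(100, seed=1)
    with pytest.raises(ValidationError):
        estimate_ate_pss(rows, fit_propensity(rows), n_strata=1)


def test_pss_homogeneous_scores_null_effect():
    from carepath import SimConfig

    rows, _ = simulate_causal_rows(
        2000, SimConfig(true_ate={"SBP": 0.0, "FBG": 0.0, "PEF": 0.0}),
        seed=5, confounded=False,
    )
    scores = fit_propensity(rows)
    assert abs(estimate_ate_pss(rows, scores).estimate) < 0.5


def test_estimators_agree_without_confounding():
    rows, tau = simulate_causal_rows(3000, seed=17, confounded=False)
    scores = fit_propensity(rows)
    naive = estimate_ate_naive(rows).estimate
    psm = estimate_ate_psm(rows, scores, seed=17).estimate
    pss = estimate_ate_pss(rows, scores).estimate
    assert max(abs(naive - psm), abs(naive - pss), abs(psm - pss)) < 1.0
    assert abs(naive - tau) < 0.5


def test_refuter_preconditions():
    rows, _ = simulate_causal_rows(500, seed=2)
    with pytest.raises(ValidationError):
        refute(rows, "PSM", "subset", reps=1)
    with pytest.raises(ValidationError):
        refute(rows, "naive", "subset", reps=3)


def test_subset_refuter_is_stable():
    rows, _ = simulate_causal_rows(3000, seed=19)
    out = refute(rows, "PSM", "subset", reps=4, seed=19, tolerance=1.0)
    assert out["passed"]


# -- descriptive and efficiency ----------------------------------------------

def test_descriptive_counts_single_patient():
    from carepath import RecordKind, SelfMonitoringRecord

    p = _profile()
    records = [bp("A", d, 130, 80) for d in range(10)]
    records += [
        SelfMonitoringRecord("A", records[0].timestamp.replace(hour=20 - i),
                             RecordKind.medication, {})
        for i in range(5)
    ]
    out = descriptive_summary([p], records)
    assert out["counts"].loc["BP", "HTN"] == 10
    assert out["counts"].loc["medication", "HTN"] == 5
    assert out["counts"]["total"].sum() == 15
    assert out["percent"]["HTN"].sum() == pytest.approx(100.0)


def test_empty_records_all_zero():
    out = descriptive_summary([_profile()], [])
    assert out["counts"]["total"].sum() == 0


def test_efficiency_histogram_and_response_days():
    d = date(2021, 5, 3)
    ivs = [
        InterventionRecord("GP1", f"P{i}", InterventionKind.regular_followup, d, d)
        for i in range(3)
    ]
    ivs.append(
        InterventionRecord("GP1", "P9", InterventionKind.regular_followup,
                           date(2021, 5, 10), date(2021, 5, 13))
    )
    rep = efficiency(ivs)
    gp = rep.per_provider["GP1"]
    assert gp.followups_per_day == {3: 1, 1: 1}
    assert gp.mean_per_active_day == 2.0
    assert gp.monthly_response_days["2021-05"]["n"] == 4
    assert 3.0 in [
        x for x in (gp.monthly_response_days["2021-05"]["median"],)
    ] or max(gp.monthly_response_days["2021-05"]["outliers"], default=0) == 3.0


def test_efficiency_conservation():
    rng = np.random.default_rng(3)
    base = date(2021, 1, 1)
    ivs = [
        InterventionRecord(
            f"GP{int(rng.integers(3))}", f"P{i}",
            InterventionKind.regular_followup,
            base + timedelta(days=int(rng.integers(100))),
            base + timedelta(days=int(rng.integers(100, 110))),
        )
        for i in range(200)
    ]
    ivs += [
        InterventionRecord("GP0", "PX", InterventionKind.sms, base, base)
        for _ in range(17)
    ]
    rep = efficiency(ivs)
    assert rep.total_followups == 200
    total_days_counts = sum(
        n * c for gp in rep.per_provider.values() for n, c in gp.followups_per_day.items()
    )
    assert total_days_counts == 200
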