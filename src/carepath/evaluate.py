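"""Retrospective evaluation of pathway-driven management.

Four families of procedure:

* descriptive summaries (record counts by kind and disease, demographics);
* windowed before/after outcome comparison with a paired Student t test —
  the "before" window is the first 2 weeks after enrollment and the
  "after" window the 2 weeks following a given time span;
* causal treatment-effect estimation: episodes of (treatment, outcome,
  four confounders) are extracted from records and intervention logs, a
  logistic propensity model is fitted, and the average treatment effect is
  estimated by 1:1 propensity-score matching (PSM, with replacement) and
  by propensity-score stratification (PSS, equal-frequency strata), with
  placebo-treatment / random-common-cause / subset refutation checks;
* care-provider work-efficiency metrics (follow-ups per active day and
  monthly response-day distributions).

p-values are reported uncorrected for multiple comparisons (flagged in the
report metadata); all tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    DomainError,
    InsufficientDataError,
    InterventionKind,
    InterventionRecord,
    PatientProfile,
    RecordKind,
    SelfMonitoringRecord,
    ValidationError,
    Warning,
)

#: maps an analysis outcome name to the record kind and value extractor
OUTCOME_EXTRACTORS: dict[str, tuple[RecordKind, Callable[[dict], Optional[float]]]] = {
    "SBP": (RecordKind.BP, lambda v: float(v["sbp"])),
    "FBG": (
        RecordKind.BG,
        lambda v: float(v["value"]) if v.get("measurement") == "FBG" else None,
    ),
    "PEF": (RecordKind.PEF, lambda v: float(v["value"])),
}

LEVEL_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class CausalRow:
    """One treated or control episode with the four confounders of the
    causal graph (age, management level, abnormal warning, management
    time)."""

    treatment: bool
    outcome: float
    age: float
    management_level: int
    abnormal_warning: bool
    management_time: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.outcome):
            raise ValidationError("outcome must be finite")


@dataclass
class ATEEstimate:
    method: str  # "PSM" | "PSS" | "naive"
    estimate: float
    n_treated: int
    n_control: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SpanComparison:
    span_days: int
    n_patients: int
    mean_before: float
    mean_after: float
    t_statistic: float
    p_value: float


@dataclass
class ProviderEfficiency:
    followups_per_day: dict[int, int]  # count of follow-ups -> number of days
    mean_per_active_day: float
    monthly_response_days: dict[str, dict]  # "YYYY-MM" -> median/q1/q3/outliers


@dataclass
class EfficiencyReport:
    per_provider: dict[str, ProviderEfficiency]
    total_followups: int


# ---------------------------------------------------------------------------
# descriptive statistics

def descriptive_summary(
    profiles: Sequence[PatientProfile], records: Sequence[SelfMonitoringRecord]
) -> dict:
    """Record counts by kind x disease group plus demographic summaries.

    Returns a dict with a ``counts`` DataFrame (rows: record kinds,
    columns: HTN/T2DM/HM/COPD plus a total), ``percent`` (column
    percentages) and a ``demographics`` dict."""
    scope_of = {p.patient_id: p.scope.value for p in profiles}
    groups = ["HTN", "T2DM", "HM", "COPD"]
    kinds = [k.value for k in RecordKind]
    counts = pd.DataFrame(0, index=kinds, columns=groups, dtype=int)
    for r in records:
        if r.patient_id not in scope_of:
            raise DomainError(f"record for unknown patient {r.patient_id!r}")
        counts.loc[r.kind.value, scope_of[r.patient_id]] += 1
    counts["total"] = counts.sum(axis=1)
    col_sums = counts[groups].sum(axis=0)
    percent = counts[groups].div(col_sums.replace(0, np.nan), axis=1) * 100
    ages = [p.age for p in profiles]
    demo = {
        "n_patients": len(profiles),
        "age_mean": float(np.mean(ages)) if ages else float("nan"),
        "age_sd": float(np.std(ages, ddof=1)) if len(ages) > 1 else float("nan"),
        "male_fraction": (
            sum(1 for p in profiles if p.sex.value == "male") / len(profiles)
            if profiles
            else float("nan")
        ),
        "disease_mix": {
            g: int((pd.Series(list(scope_of.values())) == g).sum()) for g in groups
        }
        if profiles
        else {},
    }
    return {"counts": counts, "percent": percent, "demographics": demo}


# ---------------------------------------------------------------------------
# paired t test and before/after comparison

def paired_t(differences: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired Student t test from per-pair differences.

    t = mean / (sd / sqrt(n)), df = n - 1, p from the t distribution."""
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired t test needs at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("paired t test undefined for zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _patient_window_mean(
    records: Sequence[SelfMonitoringRecord],
    outcome: str,
    start: date,
    end: date,
) -> Optional[float]:
    """Mean outcome value over the half-open window [start, end)."""
    kind, extract = OUTCOME_EXTRACTORS[outcome]
    vals = [
        v
        for r in records
        if r.kind is kind and start <= r.timestamp.date() < end
        for v in [extract(r.values)]
        if v is not None
    ]
    return float(np.mean(vals)) if vals else None


def before_after(
    records: Sequence[SelfMonitoringRecord],
    outcome: str,
    span_days: int,
    enrollment_dates: dict[str, date],
    window_days: int = 14,
) -> SpanComparison:
    """Before/after comparison over one time span.

    Before window: [enrollment, enrollment + 14 d); after window:
    [enrollment + span, enrollment + span + 14 d).  Patients lacking
    records in either window are excluded; the paired t test runs on
    per-patient window means."""
    if span_days < window_days:
        raise ValidationError(f"span_days must be >= {window_days}")
    by_patient: dict[str, list[SelfMonitoringRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    befores, afters = [], []
    for pid, enr in sorted(enrollment_dates.items()):
        rs = by_patient.get(pid, [])
        b = _patient_window_mean(rs, outcome, enr, enr + timedelta(days=window_days))
        a = _patient_window_mean(
            rs,
            outcome,
            enr + timedelta(days=span_days),
            enr + timedelta(days=span_days + window_days),
        )
        if b is not None and a is not None:
            befores.append(b)
            afters.append(a)
    if len(befores) < 2:
        raise InsufficientDataError(
            f"only {len(befores)} patients with records in both windows"
        )
    diffs = np.array(afters) - np.array(befores)
    t, _, p = paired_t(diffs)
    return SpanComparison(
        span_days=span_days,
        n_patients=len(befores),
        mean_before=float(np.mean(befores)),
        mean_after=float(np.mean(afters)),
        t_statistic=t,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# causal dataset extraction

def extract_causal_dataset(
    records: Sequence[SelfMonitoringRecord],
    interventions: Sequence[InterventionRecord],
    profiles: Sequence[PatientProfile],
    outcome: str = "SBP",
    warnings: Sequence[Warning] = (),
    level_lookup: Optional[Callable[[str, date], int]] = None,
    treated_window_days: int = 30,
    control_window_days: int = 14,
    seed: int = 0,
) -> tuple[list[CausalRow], dict]:
    """Build the (T, Y, confounders) table from raw logs.

    Treated episode per intervention: Y is the mean outcome in the
    half-open month after completion.  Control episodes: intervention-free
    2-week windows, one per patient per 30-day block, chosen
    deterministically from ``seed``.  Confounders are evaluated at the
    episode's initial time point; episodes with no outcome records in the
    window are dropped (the count is returned in the log)."""
    rng = np.random.default_rng(seed)
    prof = {p.patient_id: p for p in profiles}
    by_patient: dict[str, list[SelfMonitoringRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    iv_days: dict[str, list[date]] = {}
    for iv in interventions:
        iv_days.setdefault(iv.patient_id, []).append(iv.completed_at)

    def level_at(pid: str, when: date) -> int:
        if level_lookup is not None:
            return level_lookup(pid, when)
        p = prof[pid]
        if p.current_levels:
            return max(LEVEL_ORDINAL[v] for v in p.current_levels.values())
        return 2

    # abnormal-condition dates: from the warning log when supplied, else
    # re-derived from the records (any value crossing an urgent threshold)
    abnormal_dates: dict[str, set[date]] = {}
    if warnings:
        for w in warnings:
            abnormal_dates.setdefault(w.patient_id, set()).add(w.raised_at.date())
    else:
        from .pathway import DEFAULT_CONFIG, _check_record

        for pid, rs in by_patient.items():
            p = prof.get(pid)
            if p is None:
                continue
            days = {
                r.timestamp.date()
                for r in rs
                if _check_record(r, p, DEFAULT_CONFIG)
            }
            if days:
                abnormal_dates[pid] = days

    def warned(pid: str, start: date, end: date) -> bool:
        return any(start <= d < end for d in abnormal_dates.get(pid, ()))

    rows: list[CausalRow] = []
    dropped = 0
    for iv in interventions:
        p = prof.get(iv.patient_id)
        if p is None:
            raise DomainError(f"intervention for unknown patient {iv.patient_id!r}")
        start = iv.completed_at
        end = start + timedelta(days=treated_window_days)
        y = _patient_window_mean(
            by_patient.get(iv.patient_id, []), outcome, start + timedelta(days=1), end + timedelta(days=1)
        )
        if y is None:
            dropped += 1
            continue
        rows.append(
            CausalRow(
                treatment=True,
                outcome=y,
                age=p.age,
                management_level=level_at(p.patient_id, start),
                abnormal_warning=warned(p.patient_id, start, end),
                management_time=float((start - p.enrollment_date).days),
            )
        )

    # control episodes: one intervention-free window per patient per block
    for pid in sorted(by_patient):
        p = prof.get(pid)
        if p is None:
            continue
        rs = by_patient[pid]
        last = max(r.timestamp.date() for r in rs)
        horizon = (last - p.enrollment_date).days
        ivs = iv_days.get(pid, [])
        for block_start in range(0, max(0, horizon - control_window_days) + 1, 30):
            offset = int(rng.integers(0, max(1, 30 - control_window_days)))
            start = p.enrollment_date + timedelta(days=block_start + offset)
            end = start + timedelta(days=control_window_days)
            if any(start - timedelta(days=control_window_days) <= d < end for d in ivs):
                continue
            y = _patient_window_mean(rs, outcome, start, end)
            if y is None:
                dropped += 1
                continue
            rows.append(
                CausalRow(
                    treatment=False,
                    outcome=y,
                    age=p.age,
                    management_level=level_at(pid, start),
                    abnormal_warning=warned(pid, start, end),
                    management_time=float((start - p.enrollment_date).days),
                )
            )
    return rows, {"dropped_empty_episodes": dropped, "n_rows": len(rows)}


# ---------------------------------------------------------------------------
# propensity scores and ATE estimators

def _design(rows: Sequence[CausalRow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [
            [(r.age - 58.0) / 12.3 for r in rows],
            [float(r.management_level) for r in rows],
            [1.0 if r.abnormal_warning else 0.0 for r in rows],
            [(r.management_time - 360.0) / 210.0 for r in rows],
        ]
    )
    t = np.array([1.0 if r.treatment else 0.0 for r in rows])
    return X, t


def fit_propensity(rows: Sequence[CausalRow]) -> np.ndarray:
    """Propensity scores from a main-effects logistic model on the four
    confounders (age and management time standardized, level ordinal,
    warning 0/1)."""
    import statsmodels.api as sm

    X, t = _design(rows)
    if t.min() == t.max():
        raise DomainError("both treatment classes must be present")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with _warnings.catch_warnings():
            _warnings.simplefilter("error", ConvergenceWarning)
            try:
                res = sm.Logit(t, Xc).fit(disp=0, maxiter=200)
            except (ConvergenceWarning, Exception) as first:
                if isinstance(first, ConvergenceWarning) or "Singular" in str(first):
                    # quasi-separation or collinearity: BFGS is more forgiving
                    _warnings.simplefilter("ignore", ConvergenceWarning)
                    res = sm.Logit(t, Xc).fit(method="bfgs", disp=0, maxiter=1000)
                else:
                    raise
    except DomainError:
        raise
    except Exception as e:  # includes perfect-separation errors
        raise DomainError(f"propensity model failed to fit: {e}") from e
    scores = np.asarray(res.predict(Xc))
    if not np.all(np.isfinite(scores)) or scores.min() <= 0 or scores.max() >= 1:
        raise DomainError("propensity model produced degenerate scores (separation?)")
    return scores


def estimate_ate_naive(rows: Sequence[CausalRow]) -> ATEEstimate:
    """Unadjusted difference in mean outcomes between treated and control."""
    y = np.array([r.outcome for r in rows])
    t = np.array([r.treatment for r in rows])
    if t.all() or not t.any():
        raise DomainError("both treatment classes must be present")
    return ATEEstimate(
        method="naive",
        estimate=float(y[t].mean() - y[~t].mean()),
        n_treated=int(t.sum()),
        n_control=int((~t).sum()),
    )


def estimate_ate_psm(
    rows: Sequence[CausalRow],
    scores: np.ndarray,
    seed: int = 0,
    caliper: Optional[float] = None,
) -> ATEEstimate:
    """1:1 nearest-neighbor propensity matching with replacement.

    ATE is the mean over treated units of (Y_treated - Y_matched_control);
    equidistant controls are broken by a seed-controlled shuffle.  With a
    caliper, a treated unit with no control within the caliper raises a
    positivity error."""
    y = np.array([r.outcome for r in rows])
    t = np.array([r.treatment for r in rows])
    scores = np.asarray(scores, dtype=float)
    if t.all() or not t.any():
        raise DomainError("both treatment classes must be present")
    rng = np.random.default_rng(seed)
    c_idx = np.flatnonzero(~t)
    c_idx = c_idx[rng.permutation(c_idx.size)]  # tie-break order
    order = np.argsort(scores[c_idx], kind="stable")
    c_idx = c_idx[order]
    c_scores = scores[c_idx]
    diffs = []
    match_use: dict[int, int] = {}
    for i in np.flatnonzero(t):
        pos = np.searchsorted(c_scores, scores[i])
        cands = [j for j in (pos - 1, pos) if 0 <= j < c_scores.size]
        best = min(cands, key=lambda j: abs(c_scores[j] - scores[i]))
        dist = abs(c_scores[best] - scores[i])
        if caliper is not None and dist > caliper:
            raise DomainError(
                f"positivity violation: treated score {scores[i]:.3f} has no "
                f"control within caliper {caliper}"
            )
        diffs.append(y[i] - y[c_idx[best]])
        match_use[int(c_idx[best])] = match_use.get(int(c_idx[best]), 0) + 1
    return ATEEstimate(
        method="PSM",
        estimate=float(np.mean(diffs)),
        n_treated=int(t.sum()),
        n_control=int((~t).sum()),
        diagnostics={
            "distinct_controls_used": len(match_use),
            "max_control_reuse": max(match_use.values()),
            "score_overlap": (
                float(max(scores[t].min(), scores[~t].min())),
                float(min(scores[t].max(), scores[~t].max())),
            ),
        },
    )


def estimate_ate_pss(
    rows: Sequence[CausalRow], scores: np.ndarray, n_strata: int = 5
) -> ATEEstimate:
    """Propensity-score stratification on equal-frequency strata.

    Strata missing either class are dropped (count reported); the ATE is
    the retained-sample share-weighted mean of stratum effects."""
    if n_strata < 2:
        raise ValidationError("n_strata must be >= 2")
    y = np.array([r.outcome for r in rows])
    t = np.array([r.treatment for r in rows])
    scores = np.asarray(scores, dtype=float)
    if t.all() or not t.any():
        raise DomainError("both treatment classes must be present")
    edges = np.quantile(scores, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, n_strata - 1)
    effects, weights, dropped = [], [], 0
    for s in range(n_strata):
        mask = strata == s
        ts, ys = t[mask], y[mask]
        if not ts.any() or ts.all():
            dropped += 1
            continue
        effects.append(ys[ts].mean() - ys[~ts].mean())
        weights.append(mask.sum())
    if not effects:
        raise DomainError("all strata lack one treatment class")
    w = np.array(weights, dtype=float)
    w /= w.sum()
    return ATEEstimate(
        method="PSS",
        estimate=float(np.dot(w, effects)),
        n_treated=int(t.sum()),
        n_control=int((~t).sum()),
        diagnostics={"n_strata": n_strata, "strata_dropped": dropped},
    )


# ---------------------------------------------------------------------------
# refutation

def _estimate(rows: Sequence[CausalRow], estimator: str, seed: int) -> float:
    scores = fit_propensity(rows)
    if estimator == "PSM":
        return estimate_ate_psm(rows, scores, seed=seed).estimate
    if estimator == "PSS":
        return estimate_ate_pss(rows, scores).estimate
    raise ValidationError(f"unknown estimator {estimator!r}")


def refute(
    rows: Sequence[CausalRow],
    estimator: str = "PSM",
    method: str = "placebo_treatment",
    reps: int = 5,
    seed: int = 0,
    tolerance: float = 0.5,
) -> dict:
    """Robustness checks on a causal estimate.

    placebo_treatment: permute treatment labels; a valid design drives the
    refuted estimate to ~0.  random_common_cause: add an independent noise
    covariate to the propensity model; the estimate should barely move.
    subset: re-estimate on random 80% subsets; the estimate should be
    stable.  ``tolerance`` is the pass threshold in outcome units."""
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    if estimator not in ("PSM", "PSS"):
        raise ValidationError(f"estimator must be PSM or PSS, got {estimator!r}")
    rng = np.random.default_rng(seed)
    base = _estimate(rows, estimator, seed)
    estimates = []
    for rep in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if method == "placebo_treatment":
            perm = np.random.default_rng(rep_seed).permutation(len(rows))
            shuffled = [
                CausalRow(
                    treatment=rows[perm[i]].treatment,
                    outcome=r.outcome,
                    age=r.age,
                    management_level=r.management_level,
                    abnormal_warning=r.abnormal_warning,
                    management_time=r.management_time,
                )
                for i, r in enumerate(rows)
            ]
            estimates.append(_estimate(shuffled, estimator, rep_seed))
        elif method == "random_common_cause":
            noise = np.random.default_rng(rep_seed).normal(size=len(rows))
            estimates.append(_estimate_with_extra(rows, noise, estimator, rep_seed))
        elif method == "subset":
            idx = np.random.default_rng(rep_seed).choice(
                len(rows), size=int(0.8 * len(rows)), replace=False
            )
            sub = [rows[i] for i in idx]
            estimates.append(_estimate(sub, estimator, rep_seed))
        else:
            raise ValidationError(f"unknown refuter {method!r}")
    mean_ref = float(np.mean(estimates))
    if method == "placebo_treatment":
        passed = abs(mean_ref) <= tolerance
    else:
        passed = abs(mean_ref - base) <= tolerance
    return {
        "method": method,
        "estimator": estimator,
        "base_estimate": base,
        "refuted_estimate": mean_ref,
        "per_rep": [float(e) for e in estimates],
        "passed": bool(passed),
        "tolerance": tolerance,
    }


def _estimate_with_extra(
    rows: Sequence[CausalRow], extra: np.ndarray, estimator: str, seed: int
) -> float:
    """Propensity fit with an additional (independent) covariate column."""
    import statsmodels.api as sm

    X, t = _design(rows)
    Xc = sm.add_constant(np.column_stack([X, extra]), has_constant="add")
    res = sm.Logit(t, Xc).fit(disp=0, maxiter=200)
    scores = np.asarray(res.predict(Xc))
    if estimator == "PSM":
        return estimate_ate_psm(rows, scores, seed=seed).estimate
    return estimate_ate_pss(rows, scores).estimate


# ---------------------------------------------------------------------------
# provider efficiency

def efficiency(interventions: Sequence[InterventionRecord]) -> EfficiencyReport:
    """Per-provider follow-up throughput and responsiveness.

    Follow-ups per active day (histogram over days with >= 1 completed
    follow-up) and the distribution of response days (completed - requested)
    grouped by calendar month of the request."""
    per: dict[str, ProviderEfficiency] = {}
    followups = [
        iv for iv in interventions if iv.kind is InterventionKind.regular_followup
    ]
    by_provider: dict[str, list[InterventionRecord]] = {}
    for iv in followups:
        by_provider.setdefault(iv.provider_id, []).append(iv)
    for provider in sorted(by_provider):
        ivs = by_provider[provider]
        per_day: dict[date, int] = {}
        for iv in ivs:
            per_day[iv.completed_at] = per_day.get(iv.completed_at, 0) + 1
        hist: dict[int, int] = {}
        for n in per_day.values():
            hist[n] = hist.get(n, 0) + 1
        monthly: dict[str, list[int]] = {}
        for iv in ivs:
            month = iv.requested_at.strftime("%Y-%m")
            monthly.setdefault(month, []).append((iv.completed_at - iv.requested_at).days)
        monthly_stats = {}
        for month in sorted(monthly):
            arr = np.array(monthly[month], dtype=float)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            iqr = q3 - q1
            outliers = arr[(arr < q1 - 1.5 * iqr) | (arr > q3 + 1.5 * iqr)]
            monthly_stats[month] = {
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "mean": float(arr.mean()),
                "n": int(arr.size),
                "outliers": [float(x) for x in outliers],
            }
        per[provider] = ProviderEfficiency(
            followups_per_day=hist,
            mean_per_active_day=float(np.mean(list(per_day.values()))),
            monthly_response_days=monthly_stats,
        )
    return EfficiencyReport(per_provider=per, total_followups=len(followups))
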