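"""Synthetic longitudinal cohort generator with known causal ground truth.

Emulates the statistical shape of a real chronic-disease telehealth cohort:
demographics (age 58 +/- 12.3 years, 57.1% male), a disease mix of 77.3%
hypertension / 12.9% type 2 diabetes / 4.4% HTN+T2DM / 5.4% COPD, per-
disease self-monitoring streams, and provider intervention logs.

Outcome dynamics are a patient baseline plus confounder effects plus an
injected treatment effect plus AR(1) measurement deviations.  Treatment
(provider intervention) propensity is logistic in four confounders — age,
management level, abnormal warning, and management time — each of which
also enters the outcome, so the naive treated-vs-control contrast is biased
while propensity-based estimators can recover the injected effect.  The
ground truth (true effects, latent baselines, treatment log) is emitted in
a separate manifest that the engine and estimators never read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .models import (
    Disease,
    DiseaseScope,
    Education,
    InterventionKind,
    InterventionRecord,
    PatientProfile,
    RecordKind,
    SelfMonitoringRecord,
    Sex,
    ValidationError,
)

OUTCOME_BY_SCOPE = {
    DiseaseScope.HTN: "SBP",
    DiseaseScope.T2DM: "FBG",
    DiseaseScope.HM: "SBP",
    DiseaseScope.COPD: "PEF",
}

#: population scale used to standardize confounders inside the propensity
_AGE_MEAN, _AGE_SD = 58.0, 12.3
_MTIME_MEAN, _MTIME_SD = 360.0, 210.0


@dataclass
class ConfounderEffect:
    """Coefficients of one confounder on the treatment propensity (logit
    scale, per standardized unit) and on the outcome (outcome units)."""

    on_treatment: float
    on_outcome: float


@dataclass
class SimConfig:
    n_patients: int = 100
    disease_mix: dict[DiseaseScope, float] = field(
        default_factory=lambda: {
            DiseaseScope.HTN: 0.773,
            DiseaseScope.T2DM: 0.129,
            DiseaseScope.HM: 0.044,
            DiseaseScope.COPD: 0.054,
        }
    )
    age_mean: float = 58.0
    age_sd: float = 12.3
    male_fraction: float = 0.571
    horizon_days: int = 180
    start_date: date = date(2020, 1, 1)
    true_ate: dict[str, float] = field(
        default_factory=lambda: {"SBP": -5.0, "FBG": -1.5, "PEF": 5.0}
    )
    confounding_strengths: dict[str, ConfounderEffect] = field(
        default_factory=lambda: {
            "age": ConfounderEffect(0.4, 2.0),
            "management_level": ConfounderEffect(0.4, 2.0),
            "abnormal_warning": ConfounderEffect(0.8, 4.0),
            "management_time": ConfounderEffect(0.3, -1.5),
        }
    )
    propensity_intercept: float = -0.5  # episode-level structural model
    weekly_intervention_intercept: float = -2.5  # weekly hazard in the cohort sim
    compliance_mean: float = 0.7
    compliance_sd: float = 0.15
    measurement_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"SBP": 8.0, "FBG": 1.0, "PEF": 25.0}
    )
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"SBP": 145.0, "FBG": 8.5, "PEF": 320.0}
    )
    baseline_sd: dict[str, float] = field(
        default_factory=lambda: {"SBP": 10.0, "FBG": 1.5, "PEF": 40.0}
    )
    ar_coefficient: float = 0.7
    effect_ramp_days: int = 30  # intervention effect phases in over this many days
    provider_count: int = 3
    delay_choices: tuple[int, ...] = (1, 2, 3, 4, 5)  # follow-up response days
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not math.isclose(sum(self.disease_mix.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("disease_mix must sum to 1")
        if self.age_sd <= 0 or self.compliance_sd < 0:
            raise ValidationError("scale parameters must be positive")
        if any(sd <= 0 for sd in self.measurement_noise_sd.values()):
            raise ValidationError("measurement_noise_sd values must be positive")
        if self.horizon_days < 60:
            raise ValidationError("horizon_days must be >= 60")
        if not 0.0 < self.compliance_mean <= 1.0:
            raise ValidationError("compliance_mean must lie in (0, 1]")


@dataclass
class GroundTruth:
    true_ate: dict[str, float]
    baselines: dict[str, float]  # patient_id -> latent outcome baseline
    treatment_log: list[dict]  # one entry per patient-week propensity draw


@dataclass
class SimCohort:
    profiles: list[PatientProfile]
    records: list[SelfMonitoringRecord]
    interventions: list[InterventionRecord]
    ground_truth: GroundTruth


def _draw_profile(i: int, scope: DiseaseScope, cfg: SimConfig, rng: np.random.Generator) -> PatientProfile:
    diseases = {
        DiseaseScope.HTN: {Disease.HTN},
        DiseaseScope.T2DM: {Disease.T2DM},
        DiseaseScope.HM: {Disease.HTN, Disease.T2DM},
        DiseaseScope.COPD: {Disease.COPD},
    }[scope]
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 20.0, 95.0))
    sex = Sex.male if rng.random() < cfg.male_fraction else Sex.female
    edu_levels = [
        Education.secondary_or_below,
        Education.high_school,
        Education.graduate_or_above,
        Education.unknown,
    ]
    edu = edu_levels[int(rng.choice(4, p=[0.429, 0.125, 0.199, 0.247]))]
    return PatientProfile(
        patient_id=f"P{i:05d}",
        age=round(age, 1),
        sex=sex,
        education=Education(edu),
        diseases=frozenset(diseases),
        enrollment_date=cfg.start_date + timedelta(days=int(rng.integers(0, 30))),
        pef_personal_best=(
            round(float(rng.normal(480, 40)), 1) if Disease.COPD in diseases else None
        ),
        smoker=bool(rng.random() < 0.3),
        obese=bool(rng.random() < 0.25),
    )


def _scheduled_kinds(scope: DiseaseScope) -> dict[RecordKind, float]:
    """Record kinds a patient is asked to submit, per day."""
    if scope is DiseaseScope.HTN:
        return {RecordKind.BP: 1.0, RecordKind.medication: 1.0, RecordKind.diet: 0.5}
    if scope is DiseaseScope.T2DM:
        return {RecordKind.BG: 1.0, RecordKind.medication: 1.0}
    if scope is DiseaseScope.HM:
        return {RecordKind.BP: 1.0, RecordKind.BG: 0.5, RecordKind.medication: 1.0}
    return {
        RecordKind.PEF: 1.0,
        RecordKind.medication: 1.0,
        RecordKind.psychological: 1 / 7,
    }


def simulate_trajectory(
    profile: PatientProfile,
    baseline: float,
    compliance_p: float,
    effect_schedule: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[SelfMonitoringRecord]:
    """Daily self-monitoring stream for one patient.

    ``effect_schedule`` holds the cumulative treatment shift applied to the
    primary outcome on each study day (0 where no intervention has taken
    effect yet).  Submission of each scheduled kind is Bernoulli with the
    patient's compliance probability; the primary physiological index
    follows baseline + shift + AR(1) noise.
    """
    scope = profile.scope
    outcome = OUTCOME_BY_SCOPE[scope]
    noise_sd = cfg.measurement_noise_sd[outcome]
    innov_sd = noise_sd * math.sqrt(max(1e-12, 1 - cfg.ar_coefficient**2))
    records: list[SelfMonitoringRecord] = []
    deviation = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
    rid = 0
    for day in range(cfg.horizon_days):
        ts_date = profile.enrollment_date + timedelta(days=day)
        deviation = cfg.ar_coefficient * deviation + (
            rng.normal(0, innov_sd) if noise_sd > 0 else 0.0
        )
        for kind, per_day in _scheduled_kinds(scope).items():
            if rng.random() >= compliance_p * min(1.0, per_day):
                continue
            ts = datetime.combine(ts_date, time(8, 0)) + timedelta(
                minutes=int(rng.integers(0, 600))
            )
            rid += 1
            record_id = f"{profile.patient_id}-r{rid:05d}"
            if kind is RecordKind.BP:
                sbp = baseline + effect_schedule[day] + deviation
                if outcome != "SBP":  # diabetic patient's BP stream
                    sbp = 130 + rng.normal(0, 8)
                dbp = sbp * 0.6 + rng.normal(0, 4)
                records.append(
                    SelfMonitoringRecord(
                        profile.patient_id, ts, kind,
                        {"sbp": round(float(sbp), 1), "dbp": round(float(dbp), 1),
                         "heart_rate": int(rng.integers(60, 95))},
                        record_id,
                    )
                )
            elif kind is RecordKind.BG:
                meas = "FBG" if ts.hour < 10 else "PBG"
                val = baseline + effect_schedule[day] + deviation
                if outcome != "FBG":
                    val = 6.0 + rng.normal(0, 1.0)
                if meas == "PBG":
                    val += 2.0
                records.append(
                    SelfMonitoringRecord(
                        profile.patient_id, ts, kind,
                        {"measurement": meas, "value": round(max(1.0, float(val)), 1),
                         "ketone": False},
                        record_id,
                    )
                )
            elif kind is RecordKind.PEF:
                val = baseline + effect_schedule[day] + deviation
                records.append(
                    SelfMonitoringRecord(
                        profile.patient_id, ts, kind,
                        {"value": round(max(50.0, float(val)), 1)},
                        record_id,
                    )
                )
            elif kind is RecordKind.psychological:
                score = float(np.clip(rng.normal(12, 6), 0, 40))
                records.append(
                    SelfMonitoringRecord(
                        profile.patient_id, ts, kind,
                        {"scale": "CAT", "score": round(score, 0)},
                        record_id,
                    )
                )
            else:
                records.append(
                    SelfMonitoringRecord(profile.patient_id, ts, kind, {}, record_id)
                )
    return records


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate profiles, record streams, provider interventions and the
    ground-truth manifest.  Identical seeds give identical cohorts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    scopes = list(config.disease_mix)
    probs = np.array([config.disease_mix[s] for s in scopes])
    draws = rng.choice(len(scopes), size=config.n_patients, p=probs)

    profiles: list[PatientProfile] = []
    records: list[SelfMonitoringRecord] = []
    truth = GroundTruth(true_ate=dict(config.true_ate), baselines={}, treatment_log=[])
    requests: list[tuple[str, date]] = []  # (patient_id, requested_at)

    cs = config.confounding_strengths
    for i, k in enumerate(draws):
        scope = scopes[int(k)]
        profile = _draw_profile(i, scope, config, rng)
        profiles.append(profile)
        outcome = OUTCOME_BY_SCOPE[scope]
        baseline = rng.normal(config.baseline_mean[outcome], config.baseline_sd[outcome])
        truth.baselines[profile.patient_id] = float(baseline)
        compliance_p = float(
            np.clip(rng.normal(config.compliance_mean, config.compliance_sd), 0.05, 1.0)
        )

        # latent confounders for the weekly intervention propensity
        age_z = (profile.age - _AGE_MEAN) / _AGE_SD
        level = int(rng.integers(1, 4))
        from .pathway import LEVELS  # late import to avoid a cycle at module load

        for dz in profile.diseases:
            labels = LEVELS[dz]
            profile.current_levels[dz] = labels[min(level, len(labels)) - 1]
        tau = config.true_ate[outcome]
        shift = np.zeros(config.horizon_days + config.effect_ramp_days)
        sign = 1.0 if tau >= 0 else -1.0
        for week_start in range(0, config.horizon_days, 7):
            warning = bool(rng.random() < 0.25)
            mtime_z = (week_start - _MTIME_MEAN) / _MTIME_SD
            logit = (
                config.weekly_intervention_intercept
                + cs["age"].on_treatment * age_z
                + cs["management_level"].on_treatment * (level - 2)
                + cs["abnormal_warning"].on_treatment * warning
                + cs["management_time"].on_treatment * mtime_z
            )
            treated = bool(rng.random() < _sigmoid(logit))
            truth.treatment_log.append(
                {
                    "patient_id": profile.patient_id,
                    "day": week_start,
                    "treated": treated,
                    "age": profile.age,
                    "management_level": level,
                    "abnormal_warning": warning,
                    "management_time": week_start,
                }
            )
            if treated:
                requests.append(
                    (profile.patient_id, profile.enrollment_date + timedelta(days=week_start))
                )
                ramp = np.linspace(0, tau, config.effect_ramp_days)
                end = week_start + config.effect_ramp_days
                shift[week_start:end] = sign * np.maximum(
                    sign * shift[week_start:end], sign * ramp
                )
                shift[end:] = sign * np.maximum(sign * shift[end:], sign * tau)
        # confounder contribution to the outcome level (time-constant part)
        baseline_adj = (
            baseline
            + cs["age"].on_outcome * age_z
            + cs["management_level"].on_outcome * (level - 2)
        )
        records.extend(
            simulate_trajectory(
                profile,
                float(baseline_adj),
                compliance_p,
                shift[: config.horizon_days],
                config,
                rng,
            )
        )

    interventions = simulate_provider_log(requests, config, rng)
    records.sort(key=lambda r: (r.timestamp, r.patient_id, r.record_id or ""))
    return SimCohort(profiles, records, interventions, truth)


def simulate_provider_log(
    requests: Sequence[tuple[str, date]],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[InterventionRecord]:
    """Completion log for engine-generated follow-up requests: each request
    is assigned to a provider and completed after a random delay drawn from
    ``config.delay_choices`` (all delays >= 0)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out: list[InterventionRecord] = []
    for i, (pid, requested) in enumerate(requests):
        provider = f"GP{i % config.provider_count:02d}"
        delay = int(rng.choice(config.delay_choices))
        out.append(
            InterventionRecord(
                provider_id=provider,
                patient_id=pid,
                kind=InterventionKind.regular_followup,
                requested_at=requested,
                completed_at=requested + timedelta(days=delay),
            )
        )
    return out


# ---------------------------------------------------------------------------
# episode-level structural model (the causal-graph conditions distilled to
# one row per treated/control episode, for estimator validation at scale)

def simulate_causal_rows(
    n_episodes: int,
    config: Optional[SimConfig] = None,
    outcome: str = "SBP",
    seed: Optional[int] = None,
    confounded: bool = True,
):
    """Draw causal episodes directly from the structural model.

    Each episode has the four confounders (age, management level, abnormal
    warning, management time), a treatment drawn from the logistic
    propensity, and an outcome equal to baseline + confounder effects +
    true effect x treatment + noise.  With ``confounded=False`` all
    confounder coefficients are zeroed (randomized treatment).

    Returns ``(rows, true_ate)`` where rows is a list of
    :class:`carepath.evaluate.CausalRow`.
    """
    from .evaluate import CausalRow

    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cs = cfg.confounding_strengths
    tau = cfg.true_ate[outcome]
    mu = cfg.baseline_mean[outcome]
    noise_sd = 5.0 if outcome == "SBP" else cfg.measurement_noise_sd[outcome]

    age = rng.normal(cfg.age_mean, cfg.age_sd, n_episodes)
    level = rng.integers(1, 4, n_episodes)
    warning = rng.random(n_episodes) < 0.25
    mtime = rng.uniform(0, 720, n_episodes)
    age_z = (age - _AGE_MEAN) / _AGE_SD
    mtime_z = (mtime - _MTIME_MEAN) / _MTIME_SD
    strength = 1.0 if confounded else 0.0
    logit = cfg.propensity_intercept + strength * (
        cs["age"].on_treatment * age_z
        + cs["management_level"].on_treatment * (level - 2)
        + cs["abnormal_warning"].on_treatment * warning
        + cs["management_time"].on_treatment * mtime_z
    )
    t = rng.random(n_episodes) < 1.0 / (1.0 + np.exp(-logit))
    y = (
        mu
        + strength
        * (
            cs["age"].on_outcome * age_z
            + cs["management_level"].on_outcome * (level - 2)
            + cs["abnormal_warning"].on_outcome * warning
            + cs["management_time"].on_outcome * mtime_z
        )
        + tau * t
        + rng.normal(0, noise_sd, n_episodes)
    )
    rows = [
        CausalRow(
            treatment=bool(t[i]),
            outcome=float(y[i]),
            age=float(age[i]),
            management_level=int(level[i]),
            abnormal_warning=bool(warning[i]),
            management_time=float(mtime[i]),
        )
        for i in range(n_episodes)
    ]
    return rows, tau
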