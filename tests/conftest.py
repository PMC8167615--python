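from datetime import date, datetime, timedelta

import pytest

from carepath import (
    Disease,
    PatientProfile,
    RecordKind,
    SelfMonitoringRecord,
    Sex,
)

ENROLL = date(2021, 3, 1)


@pytest.fixture
def htn_profile() -> PatientProfile:
    return PatientProfile(
        patient_id="H001",
        age=60,
        sex=Sex.male,
        diseases=frozenset({Disease.HTN}),
        enrollment_date=ENROLL,
    )


@pytest.fixture
def t2dm_profile() -> PatientProfile:
    return PatientProfile(
        patient_id="D001",
        age=55,
        sex=Sex.female,
        diseases=frozenset({Disease.T2DM}),
        enrollment_date=ENROLL,
    )


@pytest.fixture
def copd_profile() -> PatientProfile:
    return PatientProfile(
        patient_id="C001",
        age=67,
        sex=Sex.male,
        diseases=frozenset({Disease.COPD}),
        enrollment_date=ENROLL,
        pef_personal_best=500.0,
    )


@pytest.fixture
def hm_profile() -> PatientProfile:
    return PatientProfile(
        patient_id="M001",
        age=62,
        sex=Sex.female,
        diseases=frozenset({Disease.HTN, Disease.T2DM}),
        enrollment_date=ENROLL,
    )


def bp(pid: str, day: int, sbp: float, dbp: float, base: date = ENROLL, rid=None):
    return SelfMonitoringRecord(
        pid,
        datetime.combine(base + timedelta(days=day), datetime.min.time()).replace(hour=8),
        RecordKind.BP,
        {"sbp": sbp, "dbp": dbp},
        record_id=rid,
    )


def bg(pid: str, day: int, value: float, measurement="FBG", ketone=False, base: date = ENROLL):
    return SelfMonitoringRecord(
        pid,
        datetime.combine(base + timedelta(days=day), datetime.min.time()).replace(hour=7),
        RecordKind.BG,
        {"measurement": measurement, "value": value, "ketone": ketone},
    )


def pef(pid: str, day: int, value: float, base: date = ENROLL):
    return SelfMonitoringRecord(
        pid,
        datetime.combine(base + timedelta(days=day), datetime.min.time()).replace(hour=9),
        RecordKind.PEF,
        {"value": value},
    )


def cat(pid: str, day: int, score: float, base: date = ENROLL):
    return SelfMonitoringRecord(
        pid,
        datetime.combine(base + timedelta(days=day), datetime.min.time()).replace(hour=10),
        RecordKind.psychological,
        {"scale": "CAT", "score": score},
    )


def discomfort(pid: str, day: int, exacerbation=False, hospitalization=False, base: date = ENROLL):
    return SelfMonitoringRecord(
        pid,
        datetime.combine(base + timedelta(days=day), datetime.min.time()).replace(hour=11),
        RecordKind.discomfort,
        {"acute_exacerbation": exacerbation, "hospitalization": hospitalization},
    )
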