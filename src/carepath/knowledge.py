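"""Declarative pathway knowledge and a forward-chaining fixpoint evaluator.

Pathway knowledge is expressed as condition -> action rules in a small YAML
dialect with the semantics of a monotonic production-rule system: conditions
are positive conjunctions of predicates over a patient fact base, actions
emit pathway task instances, and evaluation iterates to fixpoint so that a
task fired by one rule can satisfy the condition of another.  Negation-as-
failure is deliberately excluded; absence tests are expressed as
pre-computed boolean facts (e.g. ``no_bp_record_7d``).

A (rule_id, dedup_key) pair fires at most once, which both guarantees
termination and gives periodic tasks once-per-period semantics: the default
dedup key of a task fired by a periodic rule includes the index of the
current scheduling period.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Any, Iterable, Optional, Union

import yaml

from .models import DiseaseScope, RecordKind, TaskKind, ValidationError

COMPARATORS = ("==", "!=", "<", "<=", ">", ">=", "in", "exists")

#: fact paths referring to derived tasks; only `exists` may test them so
#: that conditions stay monotone in the growing task set
_TASK_PREFIX = "tasks."


def _builtin(name: str) -> Path:
    return Path(str(importlib.resources.files("carepath").joinpath("rulesets", name)))


def load_fact_schema(path: Optional[Union[str, Path]] = None) -> dict[str, dict]:
    """Load the published fact schema: fact_path -> {type, unit, description}."""
    p = Path(path) if path else _builtin("fact_schema.yaml")
    with open(p) as fh:
        schema = yaml.safe_load(fh) or {}
    return schema


@dataclass(frozen=True)
class Predicate:
    fact_path: str
    comparator: str
    value: Any = None

    def holds(self, facts: "FactBase") -> bool:
        if self.fact_path.startswith(_TASK_PREFIX):
            kind = self.fact_path[len(_TASK_PREFIX):]
            return any(t.task_kind.value == kind for t in facts.derived_tasks)
        present = self.fact_path in facts.patient_facts
        if self.comparator == "exists":
            return present
        if not present:
            return False
        actual = facts.patient_facts[self.fact_path]
        expect = self.value
        if self.comparator == "==":
            return actual == expect
        if self.comparator == "!=":
            return actual != expect
        if self.comparator == "in":
            return actual in expect
        if self.comparator == "<":
            return actual < expect
        if self.comparator == "<=":
            return actual <= expect
        if self.comparator == ">":
            return actual > expect
        if self.comparator == ">=":
            return actual >= expect
        raise ValidationError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class Trigger:
    mode: str  # "periodic" | "event"
    frequency_days: Optional[int] = None
    record_kinds: frozenset[RecordKind] = frozenset()

    def is_due(self, now: date, anchor: date) -> bool:
        """Whether a periodic trigger falls due on ``now`` given the anchor
        date (normally the patient's enrollment date)."""
        if self.mode != "periodic":
            return False
        return (now - anchor).days % self.frequency_days == 0

    def period_index(self, now: date, anchor: date) -> int:
        return (now - anchor).days // self.frequency_days


@dataclass(frozen=True)
class Rule:
    rule_id: str
    disease_scope: DiseaseScope
    trigger: Trigger
    condition: tuple[Predicate, ...]
    task_kind: TaskKind
    parameters: dict[str, Any] = field(default_factory=dict)
    valid_duration_days: Optional[int] = None
    priority: int = 0

    def matches_event(self, kind: RecordKind) -> bool:
        return self.trigger.mode == "event" and kind in self.trigger.record_kinds


@dataclass
class TaskInstance:
    task_kind: TaskKind
    generated_at: date
    dedup_key: str
    provenance: str  # rule_id
    valid_until: Optional[date] = None
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid_until is not None and self.valid_until < self.generated_at:
            raise ValidationError(
                f"task {self.dedup_key}: valid_until precedes generated_at"
            )


@dataclass
class FactBase:
    """Patient facts plus the tasks derived from them, with firing history."""

    patient_facts: dict[str, Any] = field(default_factory=dict)
    derived_tasks: list[TaskInstance] = field(default_factory=list)
    fired: set[tuple[str, str]] = field(default_factory=set)  # (rule_id, dedup_key)

    def task_keys(self) -> set[str]:
        return {t.dedup_key for t in self.derived_tasks}

    def anchor_date(self, fallback: date) -> date:
        raw = self.patient_facts.get("profile.enrollment_date")
        if raw is None:
            return fallback
        return raw if isinstance(raw, date) else date.fromisoformat(str(raw))


def _parse_rule(entry: dict, schema: dict[str, dict]) -> Rule:
    rid = entry.get("rule_id")
    if not rid:
        raise ValidationError("rule without rule_id")

    def err(msg: str) -> ValidationError:
        return ValidationError(f"rule {rid!r}: {msg}")

    try:
        scope = DiseaseScope(entry["disease_scope"])
    except (KeyError, ValueError):
        raise err(f"unknown disease_scope {entry.get('disease_scope')!r}") from None

    trig = entry.get("trigger") or {}
    if "periodic" in trig:
        freq = trig["periodic"].get("frequency_days")
        if not isinstance(freq, int) or freq < 1:
            raise err(f"periodic frequency_days must be a positive int, got {freq!r}")
        trigger = Trigger("periodic", frequency_days=freq)
    elif "event" in trig:
        try:
            kinds = frozenset(RecordKind(k) for k in trig["event"].get("record_kinds", []))
        except ValueError as e:
            raise err(str(e)) from None
        trigger = Trigger("event", record_kinds=kinds)
    else:
        raise err("trigger must be 'periodic' or 'event'")

    preds = []
    for c in entry.get("condition", []) or []:
        path, op = c.get("fact"), c.get("op")
        if op not in COMPARATORS:
            raise err(f"unknown comparator {op!r}")
        if path.startswith(_TASK_PREFIX):
            kind_name = path[len(_TASK_PREFIX):]
            if kind_name not in TaskKind.__members__:
                raise err(f"unknown fact_path {path!r}")
            if op != "exists":
                raise err(f"task facts admit only 'exists', got {op!r} on {path!r}")
        elif path not in schema:
            raise err(f"unknown fact_path {path!r}")
        preds.append(Predicate(path, op, c.get("value")))

    action = entry.get("action") or {}
    try:
        task_kind = TaskKind(action["task_kind"])
    except (KeyError, ValueError):
        raise err(f"unknown task_kind {action.get('task_kind')!r}") from None

    vdur = entry.get("valid_duration_days")
    if vdur is not None and (not isinstance(vdur, int) or vdur < 1):
        raise err(f"valid_duration_days must be a positive int, got {vdur!r}")

    return Rule(
        rule_id=rid,
        disease_scope=scope,
        trigger=trigger,
        condition=tuple(preds),
        task_kind=task_kind,
        parameters=dict(action.get("parameters") or {}),
        valid_duration_days=vdur,
        priority=int(entry.get("priority", 0)),
    )


def load_ruleset(
    path: Union[str, Path], schema: Optional[dict[str, dict]] = None
) -> list[Rule]:
    """Parse and validate a YAML rule file, returning rules sorted by
    (priority, rule_id)."""
    schema = schema if schema is not None else load_fact_schema()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: rule file must be a YAML list of rules")
    rules = [_parse_rule(entry, schema) for entry in doc]
    seen: set[str] = set()
    for r in rules:
        if r.rule_id in seen:
            raise ValidationError(f"duplicate rule_id {r.rule_id!r} in {path}")
        seen.add(r.rule_id)
    return sorted(rules, key=lambda r: (r.priority, r.rule_id))


def builtin_ruleset(scope: Union[str, DiseaseScope]) -> list[Rule]:
    """Load one of the bundled rulesets (HTN, T2DM, COPD, HM)."""
    scope = DiseaseScope(scope)
    return load_ruleset(_builtin(f"{scope.value.lower()}.yaml"))


def default_dedup_key(rule: Rule, now: date, anchor: date) -> str:
    """Task kind plus scheduling-period index, so a periodic task fires once
    per period; event-triggered tasks dedup on the firing date."""
    if rule.trigger.mode == "periodic":
        return f"{rule.task_kind.value}#{rule.trigger.period_index(now, anchor)}"
    return f"{rule.task_kind.value}@{now.isoformat()}"


def evaluate_to_fixpoint(
    facts: FactBase, ruleset: Iterable[Rule], now: date
) -> list[TaskInstance]:
    """Fire all rules whose conditions hold, repeatedly, until quiescence.

    Fired tasks are inserted into ``facts`` before the next pass, so a task
    generated by one rule can trigger another.  Returns the newly fired
    instances in a deterministic order (priority, then rule_id).
    """
    rules = sorted(ruleset, key=lambda r: (r.priority, r.rule_id))
    anchor_fallback = date(1970, 1, 1)
    fired_now: list[TaskInstance] = []
    max_passes = max(1, len(rules)) * 10
    passes = 0
    while True:
        passes += 1
        if passes > max_passes:
            cycle = sorted({t.provenance for t in fired_now})
            raise ValidationError(
                f"fixpoint did not converge within {max_passes} passes; "
                f"rules involved: {cycle}"
            )
        delta = 0
        for rule in rules:
            anchor = facts.anchor_date(anchor_fallback)
            key = str(rule.parameters.get("dedup_key") or default_dedup_key(rule, now, anchor))
            if (rule.rule_id, key) in facts.fired:
                continue
            if not all(p.holds(facts) for p in rule.condition):
                continue
            facts.fired.add((rule.rule_id, key))
            if key in facts.task_keys():
                continue  # same task already derived by another rule
            task = TaskInstance(
                task_kind=rule.task_kind,
                generated_at=now,
                dedup_key=key,
                provenance=rule.rule_id,
                valid_until=(
                    now + timedelta(days=rule.valid_duration_days)
                    if rule.valid_duration_days
                    else None
                ),
                payload=dict(rule.parameters),
            )
            facts.derived_tasks.append(task)
            fired_now.append(task)
            delta += 1
        if delta == 0:
            return fired_now


def expire_tasks(facts: FactBase, now: date) -> FactBase:
    """Drop tasks whose validity window has closed; idempotent."""
    facts.derived_tasks = [
        t for t in facts.derived_tasks if t.valid_until is None or t.valid_until >= now
    ]
    return facts
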