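"""Declarative grade tables and the highest-grade-fulfilled evaluator.

Every scale in this package (the ESMO-MCBS forms and the Neuro-MCBS) is a
*data* object: a :class:`GradeTable` of criterion rows, each an interval
band on one head metric plus optional companion intervals that must hold
jointly.  A single generic evaluator grades any record against any table,
so transcriptions of the published threshold tables live in a versioned
registry file (``data/grade_tables.yaml``) with a source citation per
table, where they can be audited and replaced without touching code.

Interval semantics follow the printed scale text exactly: ">= a to < b"
is the half-open interval [a, b); a single-sided ">= a" is [a, inf).
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from typing import Any, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Metric",
    "Interval",
    "GradeCriterion",
    "GradeTable",
    "CriterionEvaluation",
    "PreliminaryResult",
    "evaluate_criterion",
    "preliminary_grade",
    "Registry",
    "default_registry",
]

_INF = math.inf


class Metric(str, Enum):
    pfs_months = "pfs_months"
    orr_pct = "orr_pct"
    dcr_pct = "dcr_pct"
    dor_months = "dor_months"
    docb_months = "docb_months"
    gain_months = "gain_months"
    hr_lower95 = "hr_lower95"
    landmark_gain_pct = "landmark_gain_pct"


class Interval(BaseModel):
    """One interval condition on a metric; bounds default to (-inf, inf)."""

    model_config = ConfigDict(frozen=True)

    metric: Metric
    lower: float = -_INF
    lower_closed: bool = True
    upper: float = _INF
    upper_closed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Interval":
        if self.lower > self.upper:
            raise ValueError("interval requires lower <= upper")
        if self.lower == self.upper and not (self.lower_closed and self.upper_closed):
            raise ValueError("a degenerate interval needs both bounds closed")
        return self

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_closed and value == self.lower)
        below = value < self.upper or (self.upper_closed and value == self.upper)
        return above and below

    def describe(self) -> str:
        parts = []
        if self.lower != -_INF:
            parts.append(f">{'=' if self.lower_closed else ''} {self.lower:g}")
        if self.upper != _INF:
            parts.append(f"<{'=' if self.upper_closed else ''} {self.upper:g}")
        cond = " and ".join(parts) if parts else "any value"
        return f"{self.metric.value} {cond}"


class GradeCriterion(BaseModel):
    """One scale row: a head interval plus companions that must all hold."""

    model_config = ConfigDict(frozen=True)

    grade: int
    head: Interval
    companions: tuple[Interval, ...] = ()
    label: str = ""

    @model_validator(mode="after")
    def _check(self) -> "GradeCriterion":
        if self.grade < 1:
            raise ValueError("grade must be >= 1")
        if any(c.metric == self.head.metric for c in self.companions):
            raise ValueError("companion metrics must differ from the head metric")
        return self

    @property
    def intervals(self) -> tuple[Interval, ...]:
        return (self.head, *self.companions)

    def describe(self) -> str:
        if self.label:
            return self.label
        return " and ".join(iv.describe() for iv in self.intervals)


class CriterionEvaluation(BaseModel):
    """Audit entry: one criterion checked against one value map.

    ``satisfied`` is ``None`` (indeterminate) when no interval is
    determinately violated but at least one required metric is missing.
    """

    criterion: GradeCriterion
    satisfied: Optional[bool]
    inputs_used: tuple[tuple[Metric, Optional[float], bool], ...]  # (metric, value, proxy?)

    @property
    def indeterminate(self) -> bool:
        return self.satisfied is None

    @property
    def missing_metrics(self) -> tuple[Metric, ...]:
        return tuple(m for m, v, _ in self.inputs_used if v is None)


class PreliminaryResult(BaseModel):
    """Outcome of grading a value map against a table."""

    grade: Optional[int]  # None: every criterion indeterminate (not assessable)
    evaluations: tuple[CriterionEvaluation, ...]

    @property
    def max_indeterminate_grade(self) -> int:
        return max((e.criterion.grade for e in self.evaluations if e.indeterminate), default=0)

    @property
    def certain(self) -> bool:
        """True when no indeterminate criterion could raise the grade."""
        return self.grade is not None and self.max_indeterminate_grade <= self.grade


class GradeTable(BaseModel):
    """A complete scale transcription: criteria covering grades 1..max."""

    model_config = ConfigDict(frozen=True)

    table_id: str
    max_preliminary: int
    criteria: tuple[GradeCriterion, ...]
    source: str = ""

    @model_validator(mode="after")
    def _check(self) -> "GradeTable":
        grades = {c.grade for c in self.criteria}
        for g in range(1, self.max_preliminary + 1):
            if g not in grades:
                raise ValueError(f"table {self.table_id!r} has no criterion for grade {g}")
        if grades and max(grades) > self.max_preliminary:
            raise ValueError("criterion grade exceeds max_preliminary")
        return self


def evaluate_criterion(
    criterion: GradeCriterion,
    values: Mapping[Metric, float],
    proxied: frozenset[Metric] | set[Metric] = frozenset(),
) -> CriterionEvaluation:
    """Check one criterion against a (possibly partial) value map.

    Short-circuit semantics: a single determinately-violated interval makes
    the criterion *not satisfied* even if another required metric is
    missing; indeterminate is reserved for "could still go either way".
    """
    inputs = []
    any_missing = False
    any_failed = False
    for iv in criterion.intervals:
        v = values.get(iv.metric)
        inputs.append((iv.metric, v, iv.metric in proxied))
        if v is None:
            any_missing = True
        elif not iv.contains(v):
            any_failed = True
    if any_failed:
        satisfied: Optional[bool] = False
    elif any_missing:
        satisfied = None
    else:
        satisfied = True
    return CriterionEvaluation(
        criterion=criterion, satisfied=satisfied, inputs_used=tuple(inputs)
    )


def preliminary_grade(
    table: GradeTable,
    values: Mapping[Metric, float],
    proxied: frozenset[Metric] | set[Metric] = frozenset(),
) -> PreliminaryResult:
    """Grade = highest grade among satisfied criteria.

    Returns grade 0 when no criterion is satisfied but at least one was
    determinate, and grade ``None`` (not assessable) when every criterion
    came back indeterminate.  The full evaluation list is returned for the
    audit trail; the result is invariant to criteria order.
    """
    evaluations = tuple(evaluate_criterion(c, values, proxied) for c in table.criteria)
    satisfied = [e.criterion.grade for e in evaluations if e.satisfied]
    if satisfied:
        grade: Optional[int] = max(satisfied)
    elif all(e.indeterminate for e in evaluations):
        grade = None
    else:
        grade = 0
    return PreliminaryResult(grade=grade, evaluations=evaluations)


# ---------------------------------------------------------------------------
# registry


def _interval_from_doc(doc: Mapping[str, Any]) -> Interval:
    return Interval(
        metric=Metric(doc["metric"]),
        lower=float(doc.get("lower", -_INF)),
        lower_closed=bool(doc.get("lower_closed", True)),
        upper=float(doc.get("upper", _INF)),
        upper_closed=bool(doc.get("upper_closed", False)),
    )


def _criterion_from_doc(doc: Mapping[str, Any]) -> GradeCriterion:
    return GradeCriterion(
        grade=int(doc["grade"]),
        head=_interval_from_doc(doc),
        companions=tuple(_interval_from_doc(c) for c in doc.get("companions", [])),
        label=str(doc.get("label", "")),
    )


class Registry:
    """Container of grade tables keyed by table_id."""

    def __init__(self, tables: Sequence[GradeTable]):
        self._tables = {t.table_id: t for t in tables}
        if len(self._tables) != len(tables):
            raise ValueError("duplicate table_id in registry")

    def __getitem__(self, table_id: str) -> GradeTable:
        return self._tables[table_id]

    def __contains__(self, table_id: str) -> bool:
        return table_id in self._tables

    def ids(self) -> list[str]:
        return sorted(self._tables)

    def tables(self) -> list[GradeTable]:
        return [self._tables[k] for k in self.ids()]

    @classmethod
    def from_yaml(cls, text: str) -> "Registry":
        doc = yaml.safe_load(text)
        tables = []
        for t in doc["tables"]:
            tables.append(
                GradeTable(
                    table_id=t["table_id"],
                    max_preliminary=int(t["max_preliminary"]),
                    criteria=tuple(_criterion_from_doc(c) for c in t["criteria"]),
                    source=str(t.get("source", "")),
                )
            )
        return cls(tables)


_DEFAULT: Optional[Registry] = None


def default_registry() -> Registry:
    """The registry shipped with the package (loaded once, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("neuromcbs.data").joinpath("grade_tables.yaml").read_text("utf-8")
        _DEFAULT = Registry.from_yaml(text)
    return _DEFAULT
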