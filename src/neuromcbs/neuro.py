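"""The Neuro-Oncology Magnitude of Clinical Benefit Scale (single-arm form).

The scale refines the ESMO single-arm form for CNS tumours: objective
response is replaced by *disease control* (DCR = CR+PR+MR+SD, recognising
minor responses and durable stable disease under RANO 2.0), and duration
of response by duration of clinical benefit (DoCB).

Step 1 renders a preliminary grade on a 3-point scale from PFS, ORR, and
DCR-with-DoCB bands; Step 2 downgrades one level for >=30% grade 3-4
toxicities impacting daily well-being and upgrades one level for
objectively improved QoL or confirmatory phase-4 experience; Step 3 sums
and caps the final score at 4.  A final score below the grade-1 bands is
reported as 0 ("no demonstrable benefit"), which is distinct from *not
assessable* (the available data cannot exclude a higher grade).

Proxy policy
------------
Published single-arm reports often print ORR and DoR but not DCR/DoCB.
Because CR+PR+MR is a subset of CR+PR+MR+SD, ORR is a certified lower
bound of DCR and may stand in for it; DoR likewise substitutes for DoCB.
Both substitutions are controlled by :class:`ProxyPolicy` and every use
is recorded in the audit trail.

The printed DCR bands carry upper limits (">= 20 to < 60%"), which read
literally makes the scale non-monotone in DCR above 60% when ORR offers
no higher-grade path.  The default ``as_printed`` mode implements the
literal bands and emits :class:`NonMonotoneBandWarning` when a value
falls above every band; ``monotone`` mode drops the DCR upper bounds.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .esmo import (
    Adjustment,
    AdjustmentKind,
    FormId,
    ScoreResult,
    finalize,
    resolve_uncertain_preliminary,
    _na,
    NotAssessableReason,
)
from .grading import (
    GradeCriterion,
    GradeTable,
    Interval,
    Metric,
    Registry,
    default_registry,
    preliminary_grade,
)
from .records import BestResponse, Design, ResponseSummary, StudyRecord, Ternary

__all__ = ["ProxyPolicy", "NonMonotoneBandWarning", "score_neuro_mcbs", "score_patient"]

SCALE_ID = "neuro_mcbs_v1"


class NonMonotoneBandWarning(UserWarning):
    """A value fell above every printed band without a higher-grade path."""


class ProxyPolicy(BaseModel):
    model_config = ConfigDict(frozen=True)

    allow_orr_as_dcr_floor: bool = True
    allow_dor_as_docb: bool = True
    dcr_band_mode: Literal["as_printed", "monotone"] = "as_printed"


def _monotone_table(table: GradeTable) -> GradeTable:
    """Drop DCR upper bounds so the scale is non-decreasing in DCR."""
    criteria = []
    for c in table.criteria:
        if c.head.metric == Metric.dcr_pct and c.head.upper != float("inf"):
            head = Interval(
                metric=c.head.metric,
                lower=c.head.lower,
                lower_closed=c.head.lower_closed,
            )
            c = GradeCriterion(
                grade=c.grade,
                head=head,
                companions=c.companions,
                label=(c.label + " [monotone: DCR upper bound dropped]").strip(),
            )
        criteria.append(c)
    return GradeTable(
        table_id=table.table_id + "_monotone",
        max_preliminary=table.max_preliminary,
        criteria=tuple(criteria),
        source=table.source,
    )


def score_neuro_mcbs(
    record: StudyRecord,
    policy: ProxyPolicy = ProxyPolicy(),
    registry: Optional[Registry] = None,
) -> ScoreResult:
    """Score a single-arm study (or n-of-1 patient) on the Neuro-MCBS."""
    registry = registry or default_registry()
    if record.design.is_comparative:
        raise ValueError(
            f"record {record.record_id!r}: the Neuro-MCBS applies to single-arm records"
        )
    values: dict[Metric, float] = {}
    proxied: set[Metric] = set()
    notes = [f"proxy policy: {policy.dcr_band_mode}"]
    if record.single_arm_pfs_months is not None:
        values[Metric.pfs_months] = record.single_arm_pfs_months
    resp = record.response
    if resp is not None:
        if resp.orr_pct is not None:
            values[Metric.orr_pct] = resp.orr_pct
        if resp.dcr_pct is not None:
            values[Metric.dcr_pct] = resp.dcr_pct
        elif policy.allow_orr_as_dcr_floor and resp.orr_pct is not None:
            values[Metric.dcr_pct] = resp.orr_pct
            proxied.add(Metric.dcr_pct)
            notes.append("DCR missing: ORR used as its certified lower bound")
        if resp.docb_months is not None:
            values[Metric.docb_months] = resp.docb_months
        elif policy.allow_dor_as_docb and resp.dor_months is not None:
            values[Metric.docb_months] = resp.dor_months
            proxied.add(Metric.docb_months)
            notes.append(f"DoCB missing: DoR ({resp.dor_statistic}) substituted")
    table = registry[SCALE_ID]
    if policy.dcr_band_mode == "monotone":
        table = _monotone_table(table)
    prelim = preliminary_grade(table, values, frozenset(proxied))
    na = resolve_uncertain_preliminary(
        record, FormId.neuro_mcbs, SCALE_ID, prelim, (Metric.docb_months,), notes
    )
    if na is not None:
        return na
    grade = prelim.grade or 0
    if (
        policy.dcr_band_mode == "as_printed"
        and values.get(Metric.dcr_pct) is not None
        and values[Metric.dcr_pct] >= 60
        and grade < 3
    ):
        warnings.warn(
            f"record {record.record_id!r}: DCR {values[Metric.dcr_pct]:g}% exceeds the "
            "printed band upper limits without a higher-grade path (as-printed mode)",
            NonMonotoneBandWarning,
            stacklevel=2,
        )
    adjustments: list[Adjustment] = []
    if record.flags.toxicity_ge30pct_grade34 == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.toxicity_downgrade, delta=-1))
    # a single +1 even when both upgrade conditions hold ("upgrade 1 level if ... or ...")
    if record.flags.qol_improved == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.qol_upgrade, delta=+1))
    elif record.flags.phase4_confirmation == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.phase4_upgrade, delta=+1))
    if grade == 1 and any(a.delta < 0 for a in adjustments) and not any(
        a.delta > 0 for a in adjustments
    ):
        notes.append("toxicity downgrade took a preliminary 1 to 0 (floored at 0)")
    return finalize(
        record, FormId.neuro_mcbs, SCALE_ID, grade, adjustments, prelim.evaluations, notes
    )


_RESPONDERS = {BestResponse.CR, BestResponse.PR, BestResponse.MR}
_CONTROLLED = _RESPONDERS | {BestResponse.SD}


def score_patient(
    patient: StudyRecord,
    policy: ProxyPolicy = ProxyPolicy(),
    registry: Optional[Registry] = None,
) -> ScoreResult:
    """Score one patient as an n-of-1 single arm.

    The best response category becomes a degenerate rate: ORR is 100% if
    the best response was CR/PR/MR else 0%, DCR is 100% if it was at
    least SD else 0%.  DoCB must be recorded explicitly; it is never
    inferred from PFS.
    """
    if patient.design != Design.patient_n_of_1:
        raise ValueError(f"record {patient.record_id!r} is not an n-of-1 patient record")
    if patient.best_response is None and patient.single_arm_pfs_months is None:
        return _na(
            patient,
            FormId.neuro_mcbs,
            SCALE_ID,
            NotAssessableReason.all_criteria_indeterminate,
            notes=["neither best response nor PFS recorded"],
        )
    update: dict = {}
    if patient.best_response is not None:
        base = patient.response or ResponseSummary()
        update["response"] = base.model_copy(
            update={
                "orr_pct": 100.0 if patient.best_response in _RESPONDERS else 0.0,
                "dcr_pct": 100.0 if patient.best_response in _CONTROLLED else 0.0,
            }
        )
    derived = patient.model_copy(update=update)
    result = score_neuro_mcbs(derived, policy, registry)
    result.notes.insert(0, "n-of-1 scoring: best response mapped to 0/100% rates")
    return result
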