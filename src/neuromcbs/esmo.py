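"""ESMO-MCBS v1.1 scoring: form router, Forms 2a/2b/2c/3, assessability.

Routing follows the published form instructions: OS-primary comparative
trials go to Form 2a; PFS-primary trials go to Form 2b unless an OS
benefit was demonstrated (95% CI of the OS hazard ratio excludes 1), in
which case Form 2a is used; non-inferiority designs and other primary
endpoints go to Form 2c; single-arm studies (and n-of-1 patients) to
Form 3.

Forms 2a/2b grade on the *lower limit* of the hazard ratio's 95%
confidence interval jointly with the median survival gain.  The Form 2a
thresholds depend on the control-arm median survival ("band"); when no
control median is available the engine scores both bands and accepts the
result only if the grade is band-invariant — otherwise the record is
reported not assessable rather than guessed.

Every result carries a full audit trail: each criterion evaluated, the
inputs (and proxies) used, each adjustment applied, and the band used.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel

from .grading import (
    CriterionEvaluation,
    GradeTable,
    Metric,
    PreliminaryResult,
    Registry,
    default_registry,
    preliminary_grade,
)
from .records import Design, Endpoint, StudyRecord, Ternary

__all__ = [
    "FormId",
    "Status",
    "NotAssessableReason",
    "AdjustmentKind",
    "Adjustment",
    "BandUsed",
    "ScoreResult",
    "SCALE_MAXIMUM",
    "select_form",
    "score_form2a",
    "score_form2b",
    "score_form2c",
    "score_form3",
    "score_esmo",
]


class FormId(str, Enum):
    form2a = "form2a"
    form2b = "form2b"
    form2c = "form2c"
    form3 = "form3"
    neuro_mcbs = "neuro_mcbs"
    asco_advanced = "asco_advanced"
    asco_adjuvant = "asco_adjuvant"


class Status(str, Enum):
    scored = "scored"
    not_assessable = "not_assessable"


class NotAssessableReason(str, Enum):
    insufficient_toxicity_data = "insufficient_toxicity_data"
    noninferiority_design_unsupported = "noninferiority_design_unsupported"
    no_statistical_significance = "no_statistical_significance"
    duration_of_response_missing = "duration_of_response_missing"
    control_median_required = "control_median_required"
    all_criteria_indeterminate = "all_criteria_indeterminate"


class AdjustmentKind(str, Enum):
    qol_upgrade = "qol_upgrade"
    toxicity_upgrade = "toxicity_upgrade"
    toxicity_downgrade = "toxicity_downgrade"
    phase4_upgrade = "phase4_upgrade"
    crossover_downgrade = "crossover_downgrade"


class Adjustment(BaseModel):
    kind: AdjustmentKind
    delta: int  # exactly +1 or -1


class BandUsed(str, Enum):
    le_threshold = "le_threshold"
    gt_threshold = "gt_threshold"
    band_invariant = "band_invariant"


#: maximum final score per form
SCALE_MAXIMUM = {
    FormId.form2a: 5,
    FormId.form2b: 4,
    FormId.form2c: 4,
    FormId.form3: 4,
    FormId.neuro_mcbs: 4,
    FormId.asco_advanced: 130,
    FormId.asco_adjuvant: 100,
}


class ScoreResult(BaseModel):
    """One scored (or not-assessable) record with its audit trail."""

    record_id: str
    scale_id: str
    form_id: FormId
    status: Status
    not_assessable_reason: Optional[NotAssessableReason] = None
    preliminary: Optional[int] = None
    adjustments: list[Adjustment] = []
    final: Optional[float] = None
    band_used: Optional[BandUsed] = None
    audit: list[CriterionEvaluation] = []
    notes: list[str] = []
    components: Optional[dict[str, float]] = None  # ASCO decomposition

    @property
    def scored(self) -> bool:
        return self.status == Status.scored

    def model_post_init(self, __context) -> None:
        if (self.status == Status.scored) != (self.final is not None):
            raise ValueError("status = scored iff final present")


def _na(
    record: StudyRecord,
    form: FormId,
    scale_id: str,
    reason: NotAssessableReason,
    audit: Sequence[CriterionEvaluation] = (),
    notes: Sequence[str] = (),
    preliminary: Optional[int] = None,
) -> ScoreResult:
    return ScoreResult(
        record_id=record.record_id,
        scale_id=scale_id,
        form_id=form,
        status=Status.not_assessable,
        not_assessable_reason=reason,
        preliminary=preliminary,
        audit=list(audit),
        notes=list(notes),
    )


def finalize(
    record: StudyRecord,
    form: FormId,
    scale_id: str,
    preliminary: int,
    adjustments: Sequence[Adjustment],
    audit: Sequence[CriterionEvaluation],
    notes: Sequence[str] = (),
    band_used: Optional[BandUsed] = None,
) -> ScoreResult:
    """Apply adjustments and clamp to [0, form maximum]."""
    maximum = SCALE_MAXIMUM[form]
    final = preliminary + sum(a.delta for a in adjustments)
    final = max(0, min(maximum, final))
    return ScoreResult(
        record_id=record.record_id,
        scale_id=scale_id,
        form_id=form,
        status=Status.scored,
        preliminary=preliminary,
        adjustments=list(adjustments),
        final=final,
        band_used=band_used,
        audit=list(audit),
        notes=list(notes),
    )


# ---------------------------------------------------------------------------
# router


def select_form(record: StudyRecord) -> FormId:
    """Choose the ESMO form a record is graded under (total, deterministic)."""
    if record.design in (Design.single_arm, Design.patient_n_of_1):
        return FormId.form3
    if record.design == Design.comparative_noninferiority:
        return FormId.form2c
    if record.primary_endpoint == Endpoint.OS:
        return FormId.form2a
    if record.primary_endpoint == Endpoint.PFS:
        # Form 2b instructions: use Form 2a if an OS benefit is demonstrated
        if record.os is not None and record.os.hr is not None and record.os.hr.significant_benefit:
            return FormId.form2a
        return FormId.form2b
    return FormId.form2c


# ---------------------------------------------------------------------------
# shared helpers


def _survival_values(ep, landmark_years_for_band: int) -> dict[Metric, float]:
    values: dict[Metric, float] = {}
    if ep.hr is not None:
        values[Metric.hr_lower95] = ep.hr.lower95
    if ep.gain_months is not None:
        values[Metric.gain_months] = ep.gain_months
    elif ep.landmark_gain_pct is not None and ep.landmark_years == landmark_years_for_band:
        # landmark-survival criteria only substitute when no median gain
        values[Metric.landmark_gain_pct] = ep.landmark_gain_pct
    return values


def _banded_preliminary(
    ep,
    band_threshold_months: float,
    table_le: GradeTable,
    table_gt: GradeTable,
    landmark_years: tuple[int, int],
) -> tuple[Optional[PreliminaryResult], Optional[BandUsed], list[str]]:
    """Grade under the control-median band, or under both when unknown.

    Returns (preliminary, band_used, notes); preliminary is None when the
    two bands disagree (the caller reports control_median_required).
    """
    notes: list[str] = []
    cm = ep.control_median_months
    if cm is not None:
        if cm <= band_threshold_months:
            table, band, years = table_le, BandUsed.le_threshold, landmark_years[0]
        else:
            table, band, years = table_gt, BandUsed.gt_threshold, landmark_years[1]
        notes.append(f"band chosen by control median {cm:g} months ({table.table_id})")
        return preliminary_grade(table, _survival_values(ep, years)), band, notes
    p_le = preliminary_grade(table_le, _survival_values(ep, landmark_years[0]))
    p_gt = preliminary_grade(table_gt, _survival_values(ep, landmark_years[1]))
    if p_le.grade == p_gt.grade:
        notes.append("control median unknown; grade identical under both bands")
        return p_le, BandUsed.band_invariant, notes
    notes.append(
        f"control median unknown and bands disagree "
        f"({table_le.table_id}: {p_le.grade}, {table_gt.table_id}: {p_gt.grade})"
    )
    return None, None, notes


def upgrade_credit(record: StudyRecord) -> list[Adjustment]:
    """Single +1 for improved QoL or reduced toxicity vs control (2a/2b)."""
    if record.flags.qol_improved == Ternary.yes:
        return [Adjustment(kind=AdjustmentKind.qol_upgrade, delta=+1)]
    if record.flags.toxicity_reduced_vs_control == Ternary.yes:
        return [Adjustment(kind=AdjustmentKind.toxicity_upgrade, delta=+1)]
    return []


def _require_comparative(record: StudyRecord) -> None:
    if not record.design.is_comparative:
        raise ValueError(f"record {record.record_id!r} is not a comparative trial")


# ---------------------------------------------------------------------------
# forms


def score_form2a(record: StudyRecord, registry: Optional[Registry] = None) -> ScoreResult:
    """Form 2a: comparative trial, OS benefit, preliminary 1-4, final cap 5."""
    registry = registry or default_registry()
    _require_comparative(record)
    scale = "esmo_form2a_v1_1"
    if record.superiority_met != Ternary.yes:
        return _na(record, FormId.form2a, scale, NotAssessableReason.no_statistical_significance)
    ep = record.os
    if ep is None or ep.hr is None:
        raise ValueError(f"record {record.record_id!r}: Form 2a requires an OS hazard ratio")
    prelim, band, notes = _banded_preliminary(
        ep,
        12.0,
        registry["esmo_form2a_le12_v1_1"],
        registry["esmo_form2a_gt12_v1_1"],
        landmark_years=(2, 3),
    )
    if prelim is None:
        return _na(
            record, FormId.form2a, scale, NotAssessableReason.control_median_required, notes=notes
        )
    if prelim.grade is None:
        return _na(
            record,
            FormId.form2a,
            scale,
            NotAssessableReason.all_criteria_indeterminate,
            audit=prelim.evaluations,
            notes=notes,
        )
    return finalize(
        record,
        FormId.form2a,
        scale,
        prelim.grade,
        upgrade_credit(record),
        prelim.evaluations,
        notes,
        band,
    )


def score_form2b(record: StudyRecord, registry: Optional[Registry] = None) -> ScoreResult:
    """Form 2b: comparative trial, PFS primary, preliminary 1-3, final cap 4."""
    registry = registry or default_registry()
    _require_comparative(record)
    scale = "esmo_form2b_v1_1"
    if record.superiority_met != Ternary.yes:
        return _na(record, FormId.form2b, scale, NotAssessableReason.no_statistical_significance)
    ep = record.pfs
    if ep is None or ep.hr is None:
        raise ValueError(f"record {record.record_id!r}: Form 2b requires a PFS hazard ratio")
    prelim, band, notes = _banded_preliminary(
        ep,
        6.0,
        registry["esmo_form2b_le6_v1_1"],
        registry["esmo_form2b_gt6_v1_1"],
        landmark_years=(2, 3),
    )
    if prelim is None:
        return _na(
            record, FormId.form2b, scale, NotAssessableReason.control_median_required, notes=notes
        )
    if prelim.grade is None:
        return _na(
            record,
            FormId.form2b,
            scale,
            NotAssessableReason.all_criteria_indeterminate,
            audit=prelim.evaluations,
            notes=notes,
        )
    adjustments = upgrade_credit(record)
    if record.flags.early_stopping_or_crossover == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.crossover_downgrade, delta=-1))
    return finalize(
        record, FormId.form2b, scale, prelim.grade, adjustments, prelim.evaluations, notes, band
    )


def score_form2c(record: StudyRecord, registry: Optional[Registry] = None) -> ScoreResult:
    """Form 2c: non-inferiority designs or non-OS/PFS primary endpoints.

    A non-inferiority trial scores (final 4) only when non-inferiority was
    met AND there is positive toxicity or QoL evidence; with the evidence
    unknown the record is not assessable (insufficient toxicity data), and
    with it explicitly negative the trial scores 1 (non-inferior without a
    demonstrated tolerability advantage).
    """
    _require_comparative(record)
    scale = "esmo_form2c_v1_1"
    flags = record.flags
    if record.design == Design.comparative_noninferiority:
        if record.noninferiority_met != Ternary.yes:
            return _na(
                record, FormId.form2c, scale, NotAssessableReason.no_statistical_significance
            )
        benefit = (
            flags.toxicity_reduced_vs_control == Ternary.yes
            or flags.qol_improved == Ternary.yes
        )
        if benefit:
            kind = (
                AdjustmentKind.qol_upgrade
                if flags.qol_improved == Ternary.yes
                else AdjustmentKind.toxicity_upgrade
            )
            notes = ["non-inferiority met with reduced toxicity and/or improved QoL"]
            return finalize(
                record, FormId.form2c, scale, 3, [Adjustment(kind=kind, delta=+1)], [], notes
            )
        if (
            flags.toxicity_reduced_vs_control == Ternary.unknown
            or flags.qol_improved == Ternary.unknown
        ):
            return _na(
                record, FormId.form2c, scale, NotAssessableReason.insufficient_toxicity_data
            )
        notes = ["non-inferiority met but no toxicity or QoL advantage demonstrated"]
        return finalize(record, FormId.form2c, scale, 1, [], [], notes)
    # superiority trial with a non-OS/PFS primary endpoint: response-based
    if record.superiority_met != Ternary.yes:
        return _na(record, FormId.form2c, scale, NotAssessableReason.no_statistical_significance)
    if flags.toxicity_reduced_vs_control == Ternary.yes or flags.qol_improved == Ternary.yes:
        return finalize(record, FormId.form2c, scale, 2, upgrade_credit(record), [],
                        ["superior non-OS/PFS endpoint with tolerability advantage"])
    if (
        flags.toxicity_reduced_vs_control == Ternary.unknown
        and flags.qol_improved == Ternary.unknown
    ):
        return _na(record, FormId.form2c, scale, NotAssessableReason.insufficient_toxicity_data)
    return finalize(record, FormId.form2c, scale, 2, [], [],
                    ["superior non-OS/PFS endpoint; no tolerability advantage"])


def resolve_uncertain_preliminary(
    record: StudyRecord,
    form: FormId,
    scale: str,
    prelim: PreliminaryResult,
    duration_metrics: tuple[Metric, ...],
    notes: Sequence[str] = (),
) -> Optional[ScoreResult]:
    """Not-assessable handling shared by Form 3 and the Neuro-MCBS.

    When *no* criterion is satisfied and at least one is indeterminate the
    grade cannot be ruled a true 0, so the record is not assessable; the
    reason names the missing duration when that caused the indeterminacy.
    """
    if prelim.grade is not None and prelim.grade > 0:
        return None
    indeterminate = [e for e in prelim.evaluations if e.indeterminate]
    if not indeterminate:
        return None  # honest grade 0: everything determinate, nothing satisfied
    missing = {m for e in indeterminate for m in e.missing_metrics}
    if missing & set(duration_metrics):
        reason = NotAssessableReason.duration_of_response_missing
    else:
        reason = NotAssessableReason.all_criteria_indeterminate
    return _na(record, form, scale, reason, audit=prelim.evaluations, notes=notes)


def score_form3(record: StudyRecord, registry: Optional[Registry] = None) -> ScoreResult:
    """Form 3: single-arm studies; preliminary 1-3 on PFS/ORR/DoR, cap 4."""
    registry = registry or default_registry()
    if record.design.is_comparative:
        raise ValueError(f"record {record.record_id!r}: Form 3 applies to single-arm records")
    scale = "esmo_form3_v1_1"
    values: dict[Metric, float] = {}
    if record.single_arm_pfs_months is not None:
        values[Metric.pfs_months] = record.single_arm_pfs_months
    if record.response is not None:
        if record.response.orr_pct is not None:
            values[Metric.orr_pct] = record.response.orr_pct
        if record.response.dor_months is not None:
            values[Metric.dor_months] = record.response.dor_months
    prelim = preliminary_grade(registry[scale], values)
    na = resolve_uncertain_preliminary(
        record, FormId.form3, scale, prelim, (Metric.dor_months,)
    )
    if na is not None:
        return na
    adjustments: list[Adjustment] = []
    if record.flags.toxicity_ge30pct_grade34 == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.toxicity_downgrade, delta=-1))
    if record.flags.qol_improved == Ternary.yes:
        adjustments.append(Adjustment(kind=AdjustmentKind.qol_upgrade, delta=+1))
    return finalize(
        record, FormId.form3, scale, prelim.grade or 0, adjustments, prelim.evaluations
    )


def score_esmo(record: StudyRecord, registry: Optional[Registry] = None) -> ScoreResult:
    """Route a record to its ESMO form and score it."""
    form = select_form(record)
    scorer = {
        FormId.form2a: score_form2a,
        FormId.form2b: score_form2b,
        FormId.form2c: score_form2c,
        FormId.form3: score_form3,
    }[form]
    return scorer(record, registry)
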