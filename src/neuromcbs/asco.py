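"""ASCO value framework v2: net health benefit (NHB) scoring.

The NHB combines a clinical-benefit component (scaled treatment effect),
a toxicity component (relative difference in grade 3-4 toxicity between
arms), and - in the advanced-disease setting only - bonus points for
tail-of-the-curve survival, palliation, QoL improvement and
treatment-free interval.  The advanced setting caps at 130 points, the
adjuvant setting (no bonuses) at 100.

Unlike the ESMO forms, which grade on the most optimistic limit of the
hazard ratio's confidence interval, the ASCO framework uses the *point
estimate*; the engine enforces the distinction.  The framework applies
to randomized trials only: non-inferiority designs are reported not
assessable, mirroring its published scope.

Point magnitudes live in ``data/asco_nhb_v2.yaml`` so the transcription
is auditable; component decomposition always sums exactly to the score.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .esmo import (
    FormId,
    NotAssessableReason,
    ScoreResult,
    Status,
    _na,
)
from .records import Design, HazardRatioEstimate, StudyRecord, Ternary

__all__ = [
    "BenefitBasis",
    "ToxicitySummary",
    "BonusFlags",
    "AscoInputs",
    "asco_parameters",
    "asco_inputs_from_record",
    "score_asco",
]

SCALE_ID = "asco_nhb_v2"


class BenefitBasis(str, Enum):
    os_hr = "os_hr"
    pfs_hr = "pfs_hr"
    rr = "rr"


class ToxicitySummary(BaseModel):
    """Grade 3-4 toxicity burden per arm, as percentages of patients."""

    model_config = ConfigDict(frozen=True)

    treatment_g34_pct: float
    control_g34_pct: float

    @model_validator(mode="after")
    def _check(self) -> "ToxicitySummary":
        for v in (self.treatment_g34_pct, self.control_g34_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("toxicity percentages must lie in [0, 100]")
        return self


class BonusFlags(BaseModel):
    model_config = ConfigDict(frozen=True)

    tail_of_curve: bool = False
    palliation: bool = False
    qol_improved: bool = False
    treatment_free_interval: bool = False


class AscoInputs(BaseModel):
    model_config = ConfigDict(frozen=True)

    clinical_benefit_basis: BenefitBasis
    hr: Optional[HazardRatioEstimate] = None
    rr_diff_pct: Optional[float] = None
    toxicity: Optional[ToxicitySummary] = None
    bonus: BonusFlags = BonusFlags()

    @model_validator(mode="after")
    def _check(self) -> "AscoInputs":
        if self.clinical_benefit_basis in (BenefitBasis.os_hr, BenefitBasis.pfs_hr):
            if self.hr is None:
                raise ValueError("hazard-ratio basis requires hr")
        elif self.rr_diff_pct is None:
            raise ValueError("response-rate basis requires rr_diff_pct")
        return self


_PARAMS: Optional[dict] = None


def asco_parameters() -> dict:
    global _PARAMS
    if _PARAMS is None:
        text = resources.files("neuromcbs.data").joinpath("asco_nhb_v2.yaml").read_text("utf-8")
        _PARAMS = yaml.safe_load(text)
    return _PARAMS


def asco_inputs_from_record(record: StudyRecord) -> AscoInputs:
    """Derive framework inputs from a comparative study record.

    The benefit basis follows the endpoint hierarchy (OS hazard ratio if
    available, else PFS); toxicity stays unknown unless supplied
    separately, which yields a partial score.
    """
    if record.os is not None and record.os.hr is not None:
        basis, hr = BenefitBasis.os_hr, record.os.hr
    elif record.pfs is not None and record.pfs.hr is not None:
        basis, hr = BenefitBasis.pfs_hr, record.pfs.hr
    else:
        raise ValueError(f"record {record.record_id!r} carries no hazard ratio")
    return AscoInputs(
        clinical_benefit_basis=basis,
        hr=hr,
        bonus=BonusFlags(qol_improved=record.flags.qol_improved == Ternary.yes),
    )


def score_asco(
    record: StudyRecord, inputs: AscoInputs, setting: str = "advanced"
) -> ScoreResult:
    """Compute the NHB score; components are reported and sum to the total."""
    if setting not in ("advanced", "adjuvant"):
        raise ValueError("setting must be 'advanced' or 'adjuvant'")
    form = FormId.asco_advanced if setting == "advanced" else FormId.asco_adjuvant
    if not record.design.is_comparative:
        raise ValueError(
            f"record {record.record_id!r}: the ASCO framework applies to randomized trials"
        )
    if record.design == Design.comparative_noninferiority:
        return _na(record, form, SCALE_ID, NotAssessableReason.noninferiority_design_unsupported)
    if record.superiority_met == Ternary.no:
        return _na(record, form, SCALE_ID, NotAssessableReason.no_statistical_significance)
    p = asco_parameters()
    cbp = p["clinical_benefit"]
    notes = []
    if inputs.clinical_benefit_basis == BenefitBasis.os_hr:
        effect = (1.0 - inputs.hr.point) * cbp["os_hr_weight"]
    elif inputs.clinical_benefit_basis == BenefitBasis.pfs_hr:
        effect = (1.0 - inputs.hr.point) * cbp["pfs_hr_weight"]
    else:
        effect = inputs.rr_diff_pct * cbp["rr_weight"]
    clinical_benefit = min(max(effect, 0.0), float(cbp["cap"]))
    components = {"clinical_benefit": clinical_benefit}
    if inputs.toxicity is not None:
        tmax = float(p["toxicity"]["max_points"])
        control = inputs.toxicity.control_g34_pct
        treatment = inputs.toxicity.treatment_g34_pct
        if control > 0:
            rel = (control - treatment) / control
        else:
            rel = 0.0 if treatment == 0 else -1.0
        components["toxicity"] = tmax * min(max(rel, -1.0), 1.0)
    else:
        notes.append("toxicity profile missing: component excluded, score is partial")
    if p["settings"][setting]["bonus_allowed"]:
        b = p["bonus"]
        raw = sum(
            float(b[name])
            for name in ("tail_of_curve", "palliation", "qol_improved", "treatment_free_interval")
            if getattr(inputs.bonus, name)
        )
        components["bonus"] = min(raw, float(b["cap"]))
    total = sum(components.values())
    return ScoreResult(
        record_id=record.record_id,
        scale_id=SCALE_ID,
        form_id=form,
        status=Status.scored,
        final=total,
        components=components,
        notes=notes + [f"NHB = {' + '.join(f'{k} {v:g}' for k, v in components.items())}"],
    )
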