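"""Domain types and I/O for structured study-outcome records.

A :class:`StudyRecord` holds everything a benefit scale needs to grade one
study (or one patient treated as an n-of-1 single arm): the trial design,
the primary endpoint, survival endpoints with hazard-ratio confidence
intervals, response summaries (ORR/DCR with durations), and the ternary
toxicity/quality-of-life flags that drive score adjustments.

Conventions
-----------
* All durations are stored in **months**; readers normalise units so that
  nothing downstream ever converts.
* Percentages are stored on the 0-100 scale exactly as reported.
* A duration reported as "not reached" is stored as ``math.inf``: it
  satisfies every ">= x" criterion and fails every "< x" one, and it
  round-trips through CSV/JSON as the literal token ``"not reached"``.
* Flags are ternary (yes / no / unknown) because published tables
  distinguish "no" from "not reported": an unknown flag blocks upgrades
  but never triggers a downgrade.
"""

from __future__ import annotations

import json
import math
import re
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Ternary",
    "Design",
    "Endpoint",
    "BestResponse",
    "HazardRatioEstimate",
    "SurvivalEndpoint",
    "ResponseSummary",
    "AdjustmentFlags",
    "StudyRecord",
    "RecordError",
    "RecordValidationError",
    "parse_hr_ci",
    "format_hr_ci",
    "normalize_duration",
    "load_records",
    "save_records",
    "records_to_frame",
    "NOT_REACHED_TOKEN",
    "MISSING_TOKENS",
    "CSV_COLUMNS",
]

NOT_REACHED_TOKEN = "not reached"
#: cell values that denote a missing entry in the CSV dialect
MISSING_TOKENS = {"", "(-)", "(−)", "n/a", "na", "NA"}


class Ternary(str, Enum):
    yes = "yes"
    no = "no"
    unknown = "unknown"


class Design(str, Enum):
    comparative_superiority = "comparative_superiority"
    comparative_noninferiority = "comparative_noninferiority"
    single_arm = "single_arm"
    patient_n_of_1 = "patient_n_of_1"

    @property
    def is_comparative(self) -> bool:
        return self in (Design.comparative_superiority, Design.comparative_noninferiority)


class Endpoint(str, Enum):
    OS = "OS"
    PFS = "PFS"
    ORR = "ORR"
    other = "other"
    safety = "safety"


class BestResponse(str, Enum):
    CR = "CR"
    PR = "PR"
    MR = "MR"
    SD = "SD"
    PD = "PD"


class RecordError(ValueError):
    """A single structured validation problem, locatable by record and field."""

    def __init__(self, record_id: str, field: str, message: str):
        self.record_id = record_id
        self.field = field
        self.message = message
        super().__init__(f"record {record_id!r}, field {field!r}: {message}")


class RecordValidationError(ValueError):
    """Raised when loading a file that contains invalid records."""

    def __init__(self, errors: Sequence[RecordError]):
        self.errors = list(errors)
        lines = "\n".join(f"  - {e.args[0]}" for e in self.errors)
        super().__init__(f"{len(self.errors)} invalid record(s):\n{lines}")


# ---------------------------------------------------------------------------
# value parsing helpers


_HR_RE = re.compile(
    r"^\s*(?P<point>\d+(?:\.\d+)?)\s*"
    r"\(\s*(?P<lower>\d+(?:\.\d+)?)\s*[–—−-]\s*(?P<upper>\d+(?:\.\d+)?)\s*\)\s*$"
)


def parse_hr_ci(text: Optional[str]) -> Optional["HazardRatioEstimate"]:
    """Parse a hazard-ratio cell like ``"0.63 (0.53-0.75)"``.

    Middle-dot decimals (``0·63``) are normalised to periods and the range
    dash may be a hyphen, en-dash, em-dash or minus sign.  The explicit
    missing tokens (empty cell, ``"(-)"``) return ``None``.  Malformed
    numeric content raises :class:`ValueError` naming the offending cell.
    """
    if text is None:
        return None
    cell = text.strip().replace("·", ".")
    if cell in MISSING_TOKENS or cell.replace("−", "-") in MISSING_TOKENS:
        return None
    m = _HR_RE.match(cell)
    if not m:
        raise ValueError(f"malformed hazard-ratio cell: {text!r}")
    return HazardRatioEstimate(
        point=float(m["point"]), lower95=float(m["lower"]), upper95=float(m["upper"])
    )


def format_hr_ci(hr: Optional["HazardRatioEstimate"]) -> str:
    if hr is None:
        return ""
    return f"{hr.point!r} ({hr.lower95!r}-{hr.upper95!r})"


def normalize_duration(value: float, unit: str = "months") -> float:
    """Convert a duration to months (``years`` are multiplied by 12).

    Negative values are accepted: survival *gains* may be negative
    (an inferior arm) and are stored as negative reals.
    """
    if unit == "months":
        return value
    if unit == "years":
        return value * 12.0
    raise ValueError(f"unknown duration unit: {unit!r}")


def _duration_before(v: Any) -> Any:
    if isinstance(v, str):
        s = v.strip().lower()
        if s == NOT_REACHED_TOKEN:
            return math.inf
        if s in MISSING_TOKENS:
            return None
    return v


def _duration_json(v: Optional[float]) -> Any:
    if v is None:
        return None
    if math.isinf(v):
        return NOT_REACHED_TOKEN
    return v


# ---------------------------------------------------------------------------
# domain types


class HazardRatioEstimate(BaseModel):
    """Hazard-ratio point estimate with its 95% confidence limits.

    The lower limit is the quantity ESMO-MCBS grading compares to its
    thresholds; ASCO-NHB uses the point estimate.
    """

    model_config = ConfigDict(frozen=True)

    point: float
    lower95: float
    upper95: float

    @model_validator(mode="after")
    def _check(self) -> "HazardRatioEstimate":
        if not (self.lower95 > 0 and self.point > 0 and self.upper95 > 0):
            raise ValueError("hazard ratio and CI limits must be strictly positive")
        if not (self.lower95 <= self.point <= self.upper95):
            raise ValueError("require lower95 <= point <= upper95")
        return self

    @property
    def significant_benefit(self) -> bool:
        """Whether the 95% CI excludes 1 in favour of the intervention."""
        return self.upper95 < 1.0


class SurvivalEndpoint(BaseModel):
    """One survival endpoint (OS or PFS) of a comparative trial."""

    endpoint_kind: Endpoint
    gain_months: Optional[float] = None
    control_median_months: Optional[float] = None
    hr: Optional[HazardRatioEstimate] = None
    landmark_gain_pct: Optional[float] = None
    landmark_years: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "SurvivalEndpoint":
        if self.endpoint_kind not in (Endpoint.OS, Endpoint.PFS):
            raise ValueError("survival endpoint must be OS or PFS")
        if self.landmark_gain_pct is not None and self.landmark_years is None:
            raise ValueError("landmark_gain_pct requires landmark_years")
        if self.control_median_months is not None and self.control_median_months <= 0:
            raise ValueError("control_median_months must be > 0")
        return self


class ResponseSummary(BaseModel):
    """Response-based outcomes of a single-arm study or patient.

    ORR counts CR+PR+MR; DCR additionally counts SD.  DoR/DoCB are the
    durations over which response / disease control was maintained.
    """

    orr_pct: Optional[float] = None
    dcr_pct: Optional[float] = None
    dor_months: Optional[float] = None
    dor_statistic: str = "unspecified"  # mean | median | unspecified
    docb_months: Optional[float] = None
    response_criteria: Optional[str] = None

    @field_validator("dor_months", "docb_months", mode="before")
    @classmethod
    def _parse_duration(cls, v: Any) -> Any:
        return _duration_before(v)

    @field_validator("dor_statistic")
    @classmethod
    def _stat(cls, v: str) -> str:
        if v not in ("mean", "median", "unspecified"):
            raise ValueError("dor_statistic must be mean, median or unspecified")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ResponseSummary":
        for name in ("orr_pct", "dcr_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.orr_pct is not None and self.dcr_pct is not None:
            if self.dcr_pct < self.orr_pct:
                raise ValueError("dcr_pct must be >= orr_pct (SD can only add)")
        for name in ("dor_months", "docb_months"):
            v = getattr(self, name)
            if v is not None and not math.isinf(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


class AdjustmentFlags(BaseModel):
    """Ternary flags feeding score upgrades and downgrades.

    ``unknown`` never triggers a downgrade and never earns an upgrade.
    ``early_stopping_or_crossover`` carries the Form 2b downgrade penalty.
    """

    toxicity_ge30pct_grade34: Ternary = Ternary.unknown
    toxicity_reduced_vs_control: Ternary = Ternary.unknown
    qol_assessed: Ternary = Ternary.unknown
    qol_improved: Ternary = Ternary.unknown
    phase4_confirmation: Ternary = Ternary.unknown
    early_stopping_or_crossover: Ternary = Ternary.unknown

    @model_validator(mode="after")
    def _check(self) -> "AdjustmentFlags":
        if self.qol_improved == Ternary.yes and self.qol_assessed != Ternary.yes:
            raise ValueError("qol_improved = yes requires qol_assessed = yes")
        return self


class StudyRecord(BaseModel):
    """One scorable unit: a trial, a trial arm/cohort, or an n-of-1 patient."""

    record_id: str
    design: Design
    primary_endpoint: Endpoint
    n_subjects: Optional[int] = None
    superiority_met: Ternary = Ternary.unknown
    noninferiority_met: Ternary = Ternary.unknown
    os: Optional[SurvivalEndpoint] = None
    pfs: Optional[SurvivalEndpoint] = None
    single_arm_pfs_months: Optional[float] = None
    response: Optional[ResponseSummary] = None
    best_response: Optional[BestResponse] = None
    flags: AdjustmentFlags = AdjustmentFlags()
    subgroup_label: Optional[str] = None
    entity: Optional[str] = None
    therapy_class: Optional[str] = None
    note: Optional[str] = None

    @field_validator("single_arm_pfs_months", mode="before")
    @classmethod
    def _parse_pfs(cls, v: Any) -> Any:
        return _duration_before(v)

    @model_validator(mode="after")
    def _check(self) -> "StudyRecord":
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.design.is_comparative:
            ok = any(
                ep is not None and (ep.hr is not None or ep.gain_months is not None)
                for ep in (self.os, self.pfs)
            )
            if not ok:
                raise ValueError(
                    "comparative design requires an OS or PFS endpoint with hr or gain"
                )
        else:
            for ep in (self.os, self.pfs):
                if ep is not None and ep.hr is not None:
                    raise ValueError("single-arm / n-of-1 records cannot carry hazard ratios")
        return self


# ---------------------------------------------------------------------------
# CSV / JSON readers and writers

CSV_COLUMNS = [
    "record_id",
    "design",
    "primary_endpoint",
    "n_subjects",
    "superiority_met",
    "noninferiority_met",
    "os_gain",
    "os_gain_unit",
    "os_control_median_months",
    "os_hr",
    "os_landmark_gain_pct",
    "os_landmark_years",
    "pfs_gain",
    "pfs_gain_unit",
    "pfs_control_median_months",
    "pfs_hr",
    "single_arm_pfs_months",
    "orr_pct",
    "dcr_pct",
    "dor_months",
    "dor_statistic",
    "docb_months",
    "response_criteria",
    "best_response",
    "toxicity_ge30pct_grade34",
    "toxicity_reduced_vs_control",
    "qol_assessed",
    "qol_improved",
    "phase4_confirmation",
    "early_stopping_or_crossover",
    "subgroup_label",
    "entity",
    "therapy_class",
    "note",
]

_TERNARY_FIELDS = [
    "toxicity_ge30pct_grade34",
    "toxicity_reduced_vs_control",
    "qol_assessed",
    "qol_improved",
    "phase4_confirmation",
    "early_stopping_or_crossover",
]


def _cell(row: dict, key: str) -> Optional[str]:
    v = row.get(key)
    if v is None:
        return None
    s = str(v).strip()
    if s in MISSING_TOKENS or s.replace("−", "-") in MISSING_TOKENS:
        return None
    return s


def _num(row: dict, key: str) -> Optional[float]:
    s = _cell(row, key)
    if s is None:
        return None
    if s.lower() == NOT_REACHED_TOKEN:
        return math.inf
    return float(s.replace("·", ".").replace("−", "-"))


def _ternary(row: dict, key: str) -> Ternary:
    s = _cell(row, key)
    if s is None:
        return Ternary.unknown
    s = s.lower()
    if s in ("yes", "y", "true"):
        return Ternary.yes
    if s in ("no", "n", "false"):
        return Ternary.no
    if s == "unknown":
        return Ternary.unknown
    raise ValueError(f"cannot interpret {s!r} as yes/no/unknown")


def _survival_from_row(row: dict, prefix: str, kind: Endpoint) -> Optional[SurvivalEndpoint]:
    gain = _num(row, f"{prefix}_gain")
    unit = _cell(row, f"{prefix}_gain_unit") or "months"
    hr = parse_hr_ci(_cell(row, f"{prefix}_hr"))
    cm = _num(row, f"{prefix}_control_median_months")
    lm = _num(row, f"{prefix}_landmark_gain_pct")
    ly = _num(row, f"{prefix}_landmark_years")
    if gain is None and hr is None and cm is None and lm is None:
        return None
    return SurvivalEndpoint(
        endpoint_kind=kind,
        gain_months=None if gain is None else normalize_duration(gain, unit),
        control_median_months=cm,
        hr=hr,
        landmark_gain_pct=lm,
        landmark_years=None if ly is None else int(ly),
    )


def _record_from_row(row: dict) -> StudyRecord:
    resp_fields = ("orr_pct", "dcr_pct", "dor_months", "docb_months", "response_criteria")
    response = None
    if any(_cell(row, k) is not None for k in resp_fields):
        response = ResponseSummary(
            orr_pct=_num(row, "orr_pct"),
            dcr_pct=_num(row, "dcr_pct"),
            dor_months=_num(row, "dor_months"),
            dor_statistic=_cell(row, "dor_statistic") or "unspecified",
            docb_months=_num(row, "docb_months"),
            response_criteria=_cell(row, "response_criteria"),
        )
    n = _num(row, "n_subjects")
    return StudyRecord(
        record_id=_cell(row, "record_id") or "",
        design=Design(_cell(row, "design")),
        primary_endpoint=Endpoint(_cell(row, "primary_endpoint")),
        n_subjects=None if n is None else int(n),
        superiority_met=_ternary(row, "superiority_met"),
        noninferiority_met=_ternary(row, "noninferiority_met"),
        os=_survival_from_row(row, "os", Endpoint.OS),
        pfs=_survival_from_row(row, "pfs", Endpoint.PFS),
        single_arm_pfs_months=_num(row, "single_arm_pfs_months"),
        response=response,
        best_response=(lambda s: None if s is None else BestResponse(s))(
            _cell(row, "best_response")
        ),
        flags=AdjustmentFlags(**{k: _ternary(row, k) for k in _TERNARY_FIELDS}),
        subgroup_label=_cell(row, "subgroup_label"),
        entity=_cell(row, "entity"),
        therapy_class=_cell(row, "therapy_class"),
        note=_cell(row, "note"),
    )


def _fmt(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isinf(v):
            return NOT_REACHED_TOKEN
        return repr(v)
    if isinstance(v, Enum):
        return v.value
    return str(v)


def _row_from_record(r: StudyRecord) -> dict:
    row = {c: "" for c in CSV_COLUMNS}
    row["record_id"] = r.record_id
    row["design"] = r.design.value
    row["primary_endpoint"] = r.primary_endpoint.value
    row["n_subjects"] = _fmt(r.n_subjects)
    row["superiority_met"] = r.superiority_met.value
    row["noninferiority_met"] = r.noninferiority_met.value
    for prefix, ep in (("os", r.os), ("pfs", r.pfs)):
        if ep is None:
            continue
        row[f"{prefix}_gain"] = _fmt(ep.gain_months)
        row[f"{prefix}_gain_unit"] = "months" if ep.gain_months is not None else ""
        row[f"{prefix}_control_median_months"] = _fmt(ep.control_median_months)
        row[f"{prefix}_hr"] = format_hr_ci(ep.hr)
        row[f"{prefix}_landmark_gain_pct"] = _fmt(ep.landmark_gain_pct)
        row[f"{prefix}_landmark_years"] = _fmt(ep.landmark_years)
    row["single_arm_pfs_months"] = _fmt(r.single_arm_pfs_months)
    if r.response is not None:
        row["orr_pct"] = _fmt(r.response.orr_pct)
        row["dcr_pct"] = _fmt(r.response.dcr_pct)
        row["dor_months"] = _fmt(r.response.dor_months)
        row["dor_statistic"] = r.response.dor_statistic
        row["docb_months"] = _fmt(r.response.docb_months)
        row["response_criteria"] = _fmt(r.response.response_criteria)
    row["best_response"] = _fmt(r.best_response)
    for k in _TERNARY_FIELDS:
        row[k] = getattr(r.flags, k).value
    row["subgroup_label"] = _fmt(r.subgroup_label)
    row["entity"] = _fmt(r.entity)
    row["therapy_class"] = _fmt(r.therapy_class)
    row["note"] = _fmt(r.note)
    return row


def _record_to_json_obj(r: StudyRecord) -> dict:
    obj = r.model_dump(mode="json", exclude_none=True)

    def fix(d: Any) -> Any:
        if isinstance(d, dict):
            return {k: fix(v) for k, v in d.items()}
        if isinstance(d, list):
            return [fix(v) for v in d]
        if isinstance(d, float) and math.isinf(d):
            return NOT_REACHED_TOKEN
        return d

    return fix(obj)


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "json" if str(path).lower().endswith(".json") else "csv"


def load_records(path: Union[str, Path], format: Optional[str] = None) -> list[StudyRecord]:
    """Load study records from a CSV or JSON file.

    Rows that fail validation are collected and reported together in a
    :class:`RecordValidationError` carrying the record id and field for
    each problem.  An empty file yields an empty list.  Extra columns
    (e.g. fixture metadata) are ignored.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        text = path.read_text(encoding="utf-8").strip()
        raw = json.loads(text) if text else []
        records, errors = [], []
        for i, obj in enumerate(raw):
            try:
                records.append(StudyRecord.model_validate(obj))
            except Exception as exc:  # pydantic error: locate it
                rid = obj.get("record_id", f"<row {i}>") if isinstance(obj, dict) else f"<row {i}>"
                errors.append(RecordError(str(rid), _first_field(exc), str(exc)))
        if errors:
            raise RecordValidationError(errors)
        return records
    if fmt != "csv":
        raise ValueError(f"unknown format: {fmt!r}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return []
    records, errors = [], []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row))
        except Exception as exc:
            rid = str(row.get("record_id", "")) or f"<row {i}>"
            errors.append(RecordError(rid, _first_field(exc), str(exc)))
    if errors:
        raise RecordValidationError(errors)
    return records


def _first_field(exc: Exception) -> str:
    try:
        errs = exc.errors()  # type: ignore[attr-defined]
        if errs:
            return ".".join(str(p) for p in errs[0].get("loc", ())) or "<record>"
    except Exception:
        pass
    return "<record>"


def save_records(
    records: Iterable[StudyRecord], path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write records to CSV or JSON; ``load_records`` round-trips the result."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = list(records)
    if fmt == "json":
        path.write_text(
            json.dumps([_record_to_json_obj(r) for r in records], indent=1), encoding="utf-8"
        )
        return
    if fmt != "csv":
        raise ValueError(f"unknown format: {fmt!r}")
    df = pd.DataFrame([_row_from_record(r) for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Flat DataFrame view of a record list (the CSV schema, in memory)."""
    return pd.DataFrame([_row_from_record(r) for r in records], columns=CSV_COLUMNS)
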