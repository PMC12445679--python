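"""Packaged fixtures: published trial tables and a demo synthetic cohort.

``table1_comparative`` holds the ten randomized phase-3 neuro-oncology
trials (with molecular subgroups expanded to their printed rows) and
``table2_single_arm`` the seven single-arm scoring units (the basket
trial contributes two cohorts).  Both contain only published values,
with one exception: two band-dependent rows carry a control-arm median
OS sourced outside the published table, kept in the clearly separated
CSV column ``external_os_control_median_months``.

The printed scores ride along as ``expected_*`` columns - test metadata,
ignored by the generic record reader - retrievable via
:func:`expected_scores`.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from typing import Optional

import pandas as pd

from .records import StudyRecord, _record_from_row
from .simulate import default_config, generate_cohort

__all__ = ["FIXTURE_NAMES", "load_fixture", "expected_scores"]

FIXTURE_NAMES = ("table1_comparative", "table2_single_arm", "mtbzpm_demo")

#: seed for the packaged demo cohort (fixed so the fixture is stable)
_DEMO_SEED = 1234


def _fixture_frame(name: str) -> pd.DataFrame:
    text = resources.files("neuromcbs.data").joinpath(f"{name}.csv").read_text("utf-8")
    return pd.read_csv(StringIO(text), dtype=str, keep_default_na=False)


def load_fixture(name: str) -> list[StudyRecord]:
    """Return the validated records of a packaged fixture.

    Band-dependent comparative rows have their external control-arm
    median OS applied (see module docstring); all other values are as
    printed.  ``mtbzpm_demo`` is a deterministic 70-patient synthetic
    cohort generated on the fly.
    """
    if name == "mtbzpm_demo":
        return generate_cohort(default_config(seed=_DEMO_SEED, n_patients=70))
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    records = []
    for row in _fixture_frame(name).to_dict(orient="records"):
        record = _record_from_row(row)
        external_cm = str(row.get("external_os_control_median_months", "")).strip()
        if external_cm:
            assert record.os is not None
            record = record.model_copy(
                update={
                    "os": record.os.model_copy(
                        update={"control_median_months": float(external_cm)}
                    )
                }
            )
        records.append(record)
    return records


def expected_scores(name: str) -> dict[str, dict[str, Optional[str]]]:
    """Printed-score metadata per record_id (test oracle annotations)."""
    if name == "mtbzpm_demo":
        return {}
    df = _fixture_frame(name)
    out: dict[str, dict[str, Optional[str]]] = {}
    for row in df.to_dict(orient="records"):
        meta = {
            k: (str(v).strip() or None)
            for k, v in row.items()
            if k.startswith("expected_")
        }
        out[str(row["record_id"])] = meta
    return out
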