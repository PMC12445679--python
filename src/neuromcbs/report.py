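"""Human-readable and machine-readable score reports.

Audit-first rendering: every reported score is accompanied by the exact
criterion text that fired, the inputs (and proxies) it consumed, each
adjustment applied, and the band used - bare numbers are never emitted
without provenance.
"""

from __future__ import annotations

import json
from typing import Any, Iterable, Sequence

from .cohort import CohortSummary
from .esmo import ScoreResult

__all__ = [
    "score_result_to_dict",
    "results_to_json",
    "render_result",
    "render_report",
    "render_summary_markdown",
    "summaries_to_csv",
]


def score_result_to_dict(result: ScoreResult) -> dict[str, Any]:
    """JSON-safe dict with the audit trail flattened to readable strings."""
    d: dict[str, Any] = {
        "record_id": result.record_id,
        "scale_id": result.scale_id,
        "form_id": result.form_id.value,
        "status": result.status.value,
        "not_assessable_reason": (
            result.not_assessable_reason.value if result.not_assessable_reason else None
        ),
        "preliminary": result.preliminary,
        "adjustments": [{"kind": a.kind.value, "delta": a.delta} for a in result.adjustments],
        "final": result.final,
        "band_used": result.band_used.value if result.band_used else None,
        "criteria": [
            {
                "grade": e.criterion.grade,
                "criterion": e.criterion.describe(),
                "satisfied": e.satisfied,
                "inputs": [
                    {"metric": m.value, "value": _json_value(v), "proxy": p}
                    for m, v, p in e.inputs_used
                ],
            }
            for e in result.audit
        ],
        "notes": list(result.notes),
    }
    if result.components is not None:
        d["components"] = dict(result.components)
    return d


def _json_value(v: Any) -> Any:
    if isinstance(v, float) and v == float("inf"):
        return "not reached"
    return v


def results_to_json(results: Iterable[ScoreResult]) -> str:
    return json.dumps([score_result_to_dict(r) for r in results], indent=1)


def render_result(result: ScoreResult) -> str:
    lines = [f"== {result.record_id} [{result.scale_id} / {result.form_id.value}] =="]
    if not result.scored:
        reason = result.not_assessable_reason.value if result.not_assessable_reason else "?"
        lines.append(f"   not assessable ({reason})")
    else:
        lines.append(f"   preliminary {result.preliminary}" if result.preliminary is not None
                     else "   (no preliminary grade)")
        for a in result.adjustments:
            lines.append(f"   {'+' if a.delta > 0 else ''}{a.delta} {a.kind.value}")
        band = f"  [band: {result.band_used.value}]" if result.band_used else ""
        lines.append(f"   final {result.final:g}{band}")
    for e in result.audit:
        if e.satisfied:
            lines.append(f"   fired grade {e.criterion.grade}: {e.criterion.describe()}")
            for m, v, proxy in e.inputs_used:
                tag = " (proxy)" if proxy else ""
                lines.append(f"       {m.value} = {_json_value(v)}{tag}")
    if result.components:
        lines.append("   components: " + ", ".join(f"{k}={v:g}" for k, v in result.components.items()))
    for n in result.notes:
        lines.append(f"   note: {n}")
    return "\n".join(lines)


def render_report(results: Sequence[ScoreResult]) -> str:
    """Per-record sections followed by a compact summary table."""
    parts = [render_result(r) for r in results]
    rows = ["", "record_id\tform\tstatus\tfinal"]
    for r in results:
        final = "n/a" if r.final is None else f"{r.final:g}"
        rows.append(f"{r.record_id}\t{r.form_id.value}\t{r.status.value}\t{final}")
    return "\n\n".join(parts) + "\n" + "\n".join(rows) + "\n"


def render_summary_markdown(summaries: Sequence[CohortSummary]) -> str:
    lines = [
        "| entity | n | benefit (score >= {thr}) | % |".format(
            thr=summaries[0].threshold if summaries else 3
        ),
        "|---|---|---|---|",
    ]
    for s in summaries:
        lines.append(f"| {s.entity} | {s.n_total} | {s.n_benefit} | {s.render_pct()} |")
    return "\n".join(lines) + "\n"


def summaries_to_csv(summaries: Sequence[CohortSummary]) -> str:
    lines = ["entity,n_total,n_benefit,pct_benefit,threshold"]
    for s in summaries:
        pct = "" if s.pct_benefit is None else s.pct_benefit
        lines.append(f"{s.entity},{s.n_total},{s.n_benefit},{pct},{s.threshold}")
    return "\n".join(lines) + "\n"
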