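"""Route and score the packaged randomized phase-3 trials.

Each comparative record is routed to its ESMO form (OS-primary to 2a,
PFS-primary to 2b unless an OS benefit promotes it, non-inferiority to
2c) and graded on the lower limit of the hazard ratio's 95% CI together
with the median survival gain.  "band" shows how the control-median
band was resolved: band_invariant means both bands agree, so no
control-arm median was needed.  Not-assessable rows print the reason.
"""

from neuromcbs import load_fixture, score_esmo

for record in load_fixture("table1_comparative"):
    result = score_esmo(record)
    label = record.record_id + (f" [{record.subgroup_label}]" if record.subgroup_label else "")
    if result.scored:
        band = result.band_used.value if result.band_used else "-"
        print(f"{label:45s} {result.form_id.value:7s} final {result.final:g}  band={band}")
    else:
        print(f"{label:45s} {result.form_id.value:7s} n/a ({result.not_assessable_reason.value})")
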