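"""Score the packaged single-arm neuro-oncology studies on both scales.

Loads the seven single-arm scoring units shipped with the package (a
basket trial contributes two cohorts), grades each with the ESMO
single-arm form and with the Neuro-MCBS, and prints the two final
scores side by side.  A final score of 4 indicates a high level of
clinical benefit; "n/a" means the available data cannot exclude a
higher grade (here: a response-duration band with the duration
unreported), which is different from a score of 0.
"""

from neuromcbs import load_fixture, score_form3, score_neuro_mcbs

records = load_fixture("table2_single_arm")
print(f"{'study unit':18s} {'ORR':>5s} {'mPFS':>5s}  {'form3':>6s} {'neuro':>6s}")
for record in records:
    form3 = score_form3(record)
    neuro = score_neuro_mcbs(record)
    orr = record.response.orr_pct if record.response else None
    print(
        f"{record.record_id:18s} "
        f"{'' if orr is None else f'{orr:g}%':>5s} "
        f"{'' if record.single_arm_pfs_months is None else f'{record.single_arm_pfs_months:g}':>5s}  "
        f"{f'{form3.final:g}' if form3.scored else 'n/a':>6s} "
        f"{f'{neuro.final:g}' if neuro.scored else 'n/a':>6s}"
    )

print("\naudit trail for the top-scoring study:")
best = max((score_neuro_mcbs(r) for r in records if score_neuro_mcbs(r).scored),
           key=lambda s: s.final)
for evaluation in best.audit:
    if evaluation.satisfied:
        print(f"  grade {evaluation.criterion.grade}: {evaluation.criterion.describe()}")
for adjustment in best.adjustments:
    print(f"  adjustment {adjustment.kind.value}: {adjustment.delta:+d}")
print(f"  final: {best.final:g}")
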