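# neuromcbs

Magnitude-of-clinical-benefit scoring for neuro-oncology therapies.

When a patient with a CNS malignancy is offered a new systemic therapy —
a trial drug, or a molecularly matched therapy recommended by a tumour
board — the question that matters is not only *does it work* but *how
much benefit does it deliver, weighed against its toxicity*. Oncology
has two established rubrics for answering that question from published
trial results: the **ESMO Magnitude of Clinical Benefit Scale
(ESMO-MCBS v1.1)** and the **ASCO value framework net health benefit
score (ASCO-NHB v2)**. Neither credits durable disease stabilisation,
which for brain tumours is often the clinically meaningful outcome.
The **Neuro-MCBS** refines the ESMO single-arm form for that setting:
it grades on disease control rate (DCR = CR + PR + MR + SD, recognising
RANO 2.0 minor responses) and duration of clinical benefit (DoCB)
alongside PFS and ORR, and it applies equally to single-arm studies and
to individual patients treated as n-of-1 single arms.

This package is a scoring engine for all three scales over structured
study-outcome records, for trialists, tumour boards and
health-services researchers. It is built audit-first: every score is
returned with the exact criterion rows that fired, the inputs and
proxies they consumed, and each upgrade/downgrade applied.

## The scales, briefly

* **ESMO Form 2a** (comparative, OS primary): preliminary grade 1–4
  from the *lower limit of the 95% CI of the hazard ratio* (LL95%CI)
  jointly with the median OS gain; thresholds depend on whether the
  control-arm median OS is ≤ 12 months (e.g. grade 4: LL95%CI ≤ 0.65
  and gain ≥ 3 months) or > 12 months (LL95%CI ≤ 0.70 and gain ≥ 5
  months). A QoL/toxicity credit can raise the final score to 5.
  When no control median is available the engine scores both bands and
  accepts the grade only if it is **band-invariant**; otherwise the
  record is honestly *not assessable* rather than guessed.
* **Form 2b** (comparative, PFS primary; promoted to 2a when an OS
  benefit is demonstrated) and **Form 2c** (non-inferiority or other
  endpoints: scoreable only with positive toxicity/QoL evidence).
* **Form 3** (single-arm): preliminary 1–3 from PFS / ORR / DoR bands,
  ±1 adjustments, cap 4.
* **Neuro-MCBS** (single-arm, this scale): Step 1 grades 1–3, e.g.
  grade 3 for `PFS ≥ 6 months` or `ORR ≥ 60%` or
  `DCR ≥ 20 to < 60% and DoCB ≥ 9 months`; Step 2 downgrades one level
  for ≥ 30% grade 3–4 toxicities impacting daily well-being and
  upgrades one level for objectively improved QoL or confirmatory
  phase-4 experience; Step 3 sums, capped at 4. Missing DCR/DoCB may
  be proxied by ORR/DoR (ORR is a certified lower bound of DCR); every
  proxy is audit-flagged.
* **ASCO-NHB v2**: points-based, `clinical benefit + toxicity + bonus`,
  capped at 130 (advanced disease) or 100 (adjuvant, no bonuses); uses
  the hazard-ratio *point estimate*, not the CI limit.

All scales are shipped as declarative grade tables
(`src/neuromcbs/data/grade_tables.yaml`) with source citations, graded
by one generic highest-grade-fulfilled evaluator — the transcriptions
are data you can audit, not code you have to trust.

## Worked example

```python
from neuromcbs import load_fixture, score_neuro_mcbs

for record in load_fixture("table2_single_arm"):
    result = score_neuro_mcbs(record)
    print(record.record_id, result.final if result.scored else
          result.not_assessable_reason.value)
```

Running `python examples/score_single_arm_studies.py` prints:

```
study unit           ORR  mPFS   form3  neuro
roar_hgg             31%   4.5       2      2
roar_lgg             69%    14       3      3
alliance_071601      94%             2      2
everolimus_sega      75%             3      3
selumetinib_nf1      68%             4      4
pbtc_029             24%           n/a    n/a
onc201_dmg           20%             3      3

audit trail for the top-scoring study:
  grade 3: ORR (CR+PR+MR) >= 60%
  adjustment qol_upgrade: +1
  final: 4
```

Reading the rows: the high-grade glioma basket cohort (ORR 31%, mean
DoR 13.6 months standing in for DoCB) earns preliminary grade 3 through
the disease-control band but loses one level to grade 3–4 toxicity,
final 2. The selumetinib study (ORR 68%, response duration not
reached, QoL objectively improved) reaches the maximum of 4 — a high
level of clinical benefit. `pbtc_029` is *not assessable*: its ORR of
24% sits in a duration-dependent band and the duration was never
reported, so a grade cannot be excluded either way.

`examples/score_comparative_trials.py` does the same for the packaged
randomized phase-3 trials (form routing, band handling, not-assessable
reasons), and `examples/simulate_cohort.py` generates a seeded
synthetic n-of-1 cohort, scores every patient, and summarises the
fraction per tumour entity reaching the benefit threshold (score ≥ 3).

A thin CLI wraps the same functions:

```sh
neuromcbs score my_records.csv --scale neuro --format json
neuromcbs summarize cohort.csv --threshold 3
neuromcbs simulate --seed 7 --n 70 --out cohort.csv
neuromcbs tables          # print the grade-table registry with sources
```

Input formats (CSV and JSON) are documented by the shipped JSON-Schema
(`src/neuromcbs/data/study_record.schema.json`); missing values are
empty cells or `(-)`, durations reported as "not reached" keep that
token and satisfy any `≥ x` criterion.

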