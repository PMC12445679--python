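# Methods

This note documents the scoring semantics the package implements, the
choices made where the published scales are silent, and what the
synthetic-data generator does and does not emulate.

## Records and units

A `StudyRecord` is one scorable unit: a comparative trial, one arm or
molecular subgroup of a trial scored separately, one cohort of a basket
trial treated as its own single-arm study, or one patient treated as an
n-of-1 single arm. All durations are normalised to months at load time
(years × 12); nothing downstream converts units. Percentages stay on
the 0–100 scale as reported. A duration "not reached" is stored as
`inf`: it satisfies every `≥ x` criterion and fails every `< x` one,
and it round-trips through CSV/JSON as the literal token. Survival
*gains* may be negative (an inferior arm); a negative gain satisfies no
gain criterion.

Flags are ternary (`yes`/`no`/`unknown`) because published tables
distinguish "no" from "not reported", and scoring treats them
differently: `unknown` never triggers a downgrade and never earns an
upgrade. `qol_improved = yes` requires `qol_assessed = yes`.

## Grade tables and the evaluator

Every scale is a `GradeTable`: criterion rows, each an interval band on
a head metric plus companion intervals that must hold jointly. Interval
bounds follow the printed text exactly: "≥ a to < b" is `[a, b)`;
single-sided "≥ a" is `[a, ∞)`; hazard-ratio thresholds are closed
upper bounds on the lower 95% CI limit (`LL95%CI ≤ 0.65`). The
evaluator returns, per criterion, satisfied / not satisfied /
indeterminate, with short-circuit semantics: one determinately violated
interval makes the criterion *not satisfied* even if another metric is
missing; indeterminate is reserved for "could still go either way".

The preliminary grade is the highest grade among satisfied criteria.
Grade 0 ("no demonstrable benefit") is returned when every unsatisfied
criterion is determinate — the scales label themselves 1–4 but define
no behaviour below their grade-1 bands, and 0 is the truthful answer
there. When *no* criterion is satisfied and at least one is
indeterminate, the unit is **not assessable**: the available data
cannot exclude a higher grade. This distinction is what makes a study
with a mid-band response rate but unreported response duration
unassessable while a study with uniformly sub-band values scores 0.
The not-assessable reason names the missing duration metric when the
indeterminacy runs through DoR/DoCB companions.

## ESMO forms

**Routing.** Single-arm and n-of-1 → Form 3; non-inferiority → Form 2c;
OS primary → 2a; PFS primary → 2b, promoted to 2a when the OS
hazard-ratio CI excludes 1; anything else → 2c. The router is total
and deterministic on valid records.

**Form 2a** grades on LL95%CI and median OS gain in two bands split at
a control-arm median OS of 12 months (≤ 12: grade 4 at LL ≤ 0.65 and
gain ≥ 3 months, grade 3 at gain 2.5–3, grade 2 at 1.5–2.5; > 12:
LL ≤ 0.70 with cuts 5 / 3–5 / 1.5–3 months). Landmark-survival rows
(absolute 2-/3-year survival gain alone) are used only when no median
gain is reported. A statistically superior trial below all higher
bands grades 1. One +1 credit (improved QoL or reduced toxicity)
can raise the final score to 5. When the control median is unknown
the engine grades under both bands: identical grades are accepted as
`band_invariant`; differing grades yield
`not_assessable(control_median_required)` rather than a guess. This
band-invariance device is what makes most published comparative rows
reproducible without external control-arm medians; the two
band-dependent fixture rows carry an external control median in a
clearly separated field.

**Form 2b** is the PFS analogue (bands split at control median PFS of
6 months, preliminary max 3, cap 4 after adjustments) with an
early-stopping/crossover downgrade flag. Only its top band is
exercised by the shipped fixtures; the mid-band rows are flagged as
best-effort transcription in the registry.

**Form 2c** is gate logic, not interval bands (hence not a registry
table): a non-inferiority trial scores (final 4) only when
non-inferiority was met *and* there is positive toxicity or QoL
evidence; unknown evidence yields
`not_assessable(insufficient_toxicity_data)`; explicitly negative
evidence scores 1. Superiority trials with other endpoints score 2,
plus the usual credit, and are unassessable when tolerability evidence
is wholly unreported.

**Form 3** grades 1–3 on PFS / ORR / DoR bands (grade 3: PFS ≥ 6
months, or ORR ≥ 60%, or ORR 20–60% with DoR ≥ 9 months, and so on),
downgrades one level for ≥ 30% grade 3–4 toxicity, upgrades one for
improved QoL, cap 4.

The exact v1.1 threshold numbers are not restated in neuro-oncology
applications of the scale; they are transcribed into
`data/grade_tables.yaml` from the ESMO-MCBS v1.1 publication (Cherny
et al., Ann Oncol 2017), each table carrying its citation. The
transcription is validated end-to-end: the test suite and acceptance
script reproduce every published score of the fixture trials.

## Neuro-MCBS

Step 1 grades 1–3 on PFS, ORR (CR+PR+MR) and DCR (CR+PR+MR+SD) with
DoCB companions, as printed. Step 2: −1 for ≥ 30% grade 3–4 toxicity
impacting daily well-being; +1 (a single level, even if both conditions
hold) for objectively improved QoL *or* confirmatory phase-4
experience. Step 3 sums and caps at 4. A downgrade may take a
preliminary 1 to 0; the case is flagged in the audit notes.

**Proxy policy.** Reports often print ORR/DoR but not DCR/DoCB. Since
CR+PR+MR ⊆ CR+PR+MR+SD, ORR is a certified lower bound of DCR and may
substitute for it; DoR substitutes for DoCB (mean or median — the
statistic used is recorded). Substitution can only under-grade, never
over-grade, and every use is audit-flagged. Both proxies default on.

**DCR band ceilings.** Read literally, the printed band "DCR ≥ 20 to
< 60%" gives no grade-3 path to a study with DCR 70% unless ORR ≥ 60 —
a non-monotonicity. The default `as_printed` mode implements the
literal bands and emits `NonMonotoneBandWarning` when a value falls
above every band without a higher-grade path; `monotone` mode drops the
DCR upper bounds. Fidelity first: the anomaly is surfaced, not
silently repaired.

**n-of-1 scoring** maps a patient's best response to degenerate rates
(ORR 100/0, DCR 100/0) and uses their own PFS and DoCB. DoCB is never
inferred from PFS — a durable-SD patient without an explicit DoCB earns
no disease-control credit (this is deliberate: inferring it would
manufacture evidence the record does not contain).

## ASCO-NHB v2

Clinical benefit scales the treatment effect by endpoint importance:
`(1 − HR) × 100` on an OS basis, `× 80` on a PFS basis, `0.6 ×` the
percentage-point ORR difference on a response basis, floored at 0 and
capped at 80 — the framework uses the hazard-ratio *point estimate*,
and the engine enforces that distinction from ESMO grading. Toxicity
contributes ±20 points scaled by the relative difference in grade 3–4
toxicity between arms; a missing toxicity profile excludes the
component and flags the score as partial. Advanced-disease bonus
points (tail-of-curve 20, palliation 10, QoL 10, treatment-free
interval 10) are capped at 30, so the decomposition sums exactly to the
total and the setting maxima (130 advanced, 80 + 20 = 100 adjuvant)
hold by construction. Published NHB values for specific trials depend
on original-trial toxicity tables that structured outcome rows do not
carry, so this module's guarantees are the framework *properties*
(caps, monotonicity in HR, exact decomposition, design gates), not
per-trial numbers. Non-inferiority designs are rejected as
`noninferiority_design_unsupported`.

## Cohort summaries

Per-entity benefit fractions count scored n-of-1 results with final
score ≥ threshold (default 3, the level read as "net clinical
benefit"); not-assessable patients are excluded and counted separately
by the caller. Percentages round half *up* to integers (5/8 → 63%,
1/8 → 13%), which matches standard clinical reporting; banker's
rounding would print 62/12. Therapy-class tabulations are plain counts,
descending.

## Synthetic cohorts

The generator emulates the *structure* of a molecular-tumour-board
cohort, not its clinical truth: entity drawn from a configurable mix
(default: meningioma 8/70, brain metastases 10/70, glioblastoma 36/70,
IDH-mutant astrocytoma 8/70, other 8/70), therapy class drawn with
probabilities proportional to published usage counts, PFS exponential
with an entity-specific median (defaults 6.5 / 7 / 2.5 / 4 / 3.5
months — chosen once as entity-typical orders of magnitude, with the
qualitative ordering that metastases and meningiomas fare better under
targeted therapy than gliomas), best response categorical per entity,
DoCB lognormal (median 6 months, σ = 0.6) for non-progressors, and
Bernoulli toxicity (0.15) and QoL-improvement (0.20) flags.
Generation is deterministic for a fixed seed.

What passing tests on synthetic cohorts shows: the engine's algebra
(determinism, score bounds, monotone response of mean score to the PFS
model, agreement with a straight-line re-implementation of the scale).
What it does not show: anything about real patients — exponential PFS
has no cure fraction or censoring, responses are independent of PFS,
and flags are independent of everything. Test sizes: property suites
run on hundreds of records; the monotone-mean check uses two
10 000-patient cohorts at PFS medians 2 vs 12 months under one seed.

## Numerical and degenerate-input conventions

Boundary values sit exactly on printed thresholds (closed lower bounds,
open upper bounds; closed HR upper bounds), so e.g. LL95%CI = 0.65
still earns the band. Empty files load as empty record lists. An
empty cohort renders its percentage as "—" rather than dividing by
zero. Proportions in simulation configs must sum to 1 within 1e-9.
Record identifiers are caller-supplied and never auto-generated, to
keep audit trails stable across runs.

## Known limitations

* Form 2b mid-band rows and Form 2a landmark rows below grade 4 follow
  the cited publication but are not exercised by any shipped fixture.
* Form 2c's response-rate path for superiority trials with exotic
  endpoints is deliberately coarse (grade 2 + credit); no fixture
  exists to pin it more finely.
* The ASCO module reproduces framework properties, not published
  per-trial scores (see above).
* RANO response categories are inputs; the package performs no imaging
  assessment.
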