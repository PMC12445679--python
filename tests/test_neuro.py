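"""Neuro-MCBS scoring: Table-style step semantics, proxies, and n-of-1 use."""

import math
import warnings

import pytest

from neuromcbs.esmo import NotAssessableReason, Status
from neuromcbs.neuro import NonMonotoneBandWarning, ProxyPolicy, score_neuro_mcbs, score_patient
from neuromcbs.records import (
    AdjustmentFlags,
    BestResponse,
    Design,
    Endpoint,
    ResponseSummary,
    StudyRecord,
    Ternary,
)
from neuromcbs.simulate import default_config, generate_cohort

MONOTONE = ProxyPolicy(dcr_band_mode="monotone")


def single_arm(record_id="s", pfs=None, orr=None, dcr=None, dor=None, docb=None,
               tox=Ternary.unknown, qol=Ternary.unknown, phase4=Ternary.unknown):
    response = None
    if any(v is not None for v in (orr, dcr, dor, docb)):
        response = ResponseSummary(orr_pct=orr, dcr_pct=dcr, dor_months=dor, docb_months=docb)
    return StudyRecord(
        record_id=record_id, design=Design.single_arm, primary_endpoint=Endpoint.ORR,
        single_arm_pfs_months=pfs, response=response,
        flags=AdjustmentFlags(
            toxicity_ge30pct_grade34=tox,
            qol_assessed=Ternary.yes if qol == Ternary.yes else Ternary.unknown,
            qol_improved=qol, phase4_confirmation=phase4,
        ),
    )


def patient(record_id="p", pfs=None, response=None, docb=None,
            tox=Ternary.unknown, qol=Ternary.unknown):
    return StudyRecord(
        record_id=record_id, design=Design.patient_n_of_1, primary_endpoint=Endpoint.PFS,
        single_arm_pfs_months=pfs, best_response=response,
        response=None if docb is None else ResponseSummary(docb_months=docb),
        flags=AdjustmentFlags(
            toxicity_ge30pct_grade34=tox,
            qol_assessed=Ternary.yes if qol == Ternary.yes else Ternary.unknown,
            qol_improved=qol,
        ),
    )


# ---------------------------------------------------------------------------
# independent straight-line oracle of the published three-step scale


def oracle_step1(pfs, orr, dcr, docb):
    """Literal transcription of the preliminary grade bands (as printed)."""
    grades = []
    if pfs is not None:
        if pfs >= 6:
            grades.append(3)
        elif 3 <= pfs < 6:
            grades.append(2)
        elif 2 <= pfs < 3:
            grades.append(1)
    if orr is not None:
        if orr >= 60:
            grades.append(3)
        elif 40 <= orr < 60:
            grades.append(2)
        elif 20 <= orr < 40 and docb is not None and docb < 6:
            grades.append(1)
    if dcr is not None and docb is not None:
        if 20 <= dcr < 60 and docb >= 9:
            grades.append(3)
        elif 20 <= dcr < 40 and 6 <= docb < 9:
            grades.append(2)
        elif 10 <= dcr < 20 and docb >= 6:
            grades.append(1)
    return max(grades) if grades else 0


def oracle_final(pfs, orr, dcr, docb, tox_yes, upgrade_yes):
    grade = oracle_step1(pfs, orr, dcr, docb)
    if tox_yes:
        grade -= 1
    if upgrade_yes:
        grade += 1
    return min(max(grade, 0), 4)


class TestPublishedSingleArmScores:
    def test_reproduces_every_printed_score(self, table2, table2_expected, registry):
        for record in table2:
            exp = table2_expected[record.record_id]
            result = score_neuro_mcbs(record, registry=registry)
            if exp["expected_status"] == "scored":
                assert result.scored, record.record_id
                assert result.final == float(exp["expected_neuro_score"]), record.record_id
            else:
                assert result.status == Status.not_assessable
                assert result.not_assessable_reason.value == exp["expected_reason"]

    def test_proxies_are_audit_flagged(self, table2):
        record = next(r for r in table2 if r.record_id == "onc201_dmg")
        result = score_neuro_mcbs(record)
        flagged = {
            m.value
            for e in result.audit if e.satisfied
            for m, _, proxy in e.inputs_used if proxy
        }
        assert {"dcr_pct", "docb_months"} <= flagged
        assert any("policy" in n for n in result.notes)


class TestStepSemantics:
    def test_below_every_band_scores_zero_not_na(self):
        result = score_neuro_mcbs(single_arm(pfs=1.0, orr=5, dcr=8))
        assert result.scored and result.final == 0

    def test_downgrade_can_take_one_to_zero(self):
        result = score_neuro_mcbs(single_arm(pfs=2.4, orr=0, dcr=0, tox=Ternary.yes))
        assert result.preliminary == 1 and result.final == 0
        assert any("floored" in n for n in result.notes)

    def test_upgrade_and_downgrade_cancel_exactly(self):
        base = score_neuro_mcbs(single_arm(pfs=7.0, orr=10, dcr=15))
        both = score_neuro_mcbs(
            single_arm(pfs=7.0, orr=10, dcr=15, tox=Ternary.yes, qol=Ternary.yes)
        )
        assert both.final == base.final
        assert sum(a.delta for a in both.adjustments) == 0

    def test_single_upgrade_even_when_both_conditions_hold(self):
        result = score_neuro_mcbs(
            single_arm(pfs=4.0, orr=0, dcr=0, qol=Ternary.yes, phase4=Ternary.yes)
        )
        assert sum(a.delta for a in result.adjustments) == 1

    def test_phase4_alone_earns_the_upgrade(self):
        result = score_neuro_mcbs(single_arm(pfs=4.0, orr=0, dcr=0, phase4=Ternary.yes))
        assert result.final == 3

    def test_final_capped_at_4(self):
        result = score_neuro_mcbs(single_arm(pfs=20.0, orr=90, dcr=95, docb=30, qol=Ternary.yes))
        assert result.final == 4

    def test_unknown_flags_change_nothing(self):
        assert score_neuro_mcbs(single_arm(pfs=7.0, orr=10, dcr=15)).adjustments == []

    def test_comparative_record_rejected(self, table1):
        with pytest.raises(ValueError, match="single-arm"):
            score_neuro_mcbs(table1[0])


class TestProxyPolicy:
    def test_orr_proxy_never_lowers_score(self):
        for orr, docb in [(25, 10), (25, 3), (45, 10), (70, 2), (15, 7), (5, 20)]:
            with_proxy = score_neuro_mcbs(single_arm(orr=orr, docb=docb))
            without = score_neuro_mcbs(
                single_arm(orr=orr, docb=docb),
                ProxyPolicy(allow_orr_as_dcr_floor=False),
            )
            if with_proxy.scored and without.scored:
                assert with_proxy.final >= without.final

    def test_as_printed_warns_above_band_ceiling(self):
        # DCR above every printed band with no higher-grade path via ORR/PFS
        with pytest.warns(NonMonotoneBandWarning):
            result = score_neuro_mcbs(single_arm(pfs=1.0, orr=10, dcr=70, docb=12))
        assert result.final < 3

    def test_monotone_mode_is_non_decreasing_in_dcr(self):
        finals = []
        for dcr in [5, 10, 15, 20, 30, 40, 55, 60, 70, 90, 100]:
            result = score_neuro_mcbs(single_arm(pfs=1.0, orr=5, dcr=dcr, docb=12), MONOTONE)
            finals.append(result.final)
        assert finals == sorted(finals)

    def test_as_printed_monotone_on_fixture_inputs(self, table2, registry):
        # within the printed band range the literal scale is already monotone
        for record in table2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonMonotoneBandWarning)
                as_printed = score_neuro_mcbs(record, registry=registry)
                monotone = score_neuro_mcbs(record, MONOTONE, registry)
            assert as_printed.status == monotone.status
            if as_printed.scored:
                assert monotone.final >= as_printed.final


class TestPatientScoring:
    def test_pfs_alone_reaches_grade_3(self):
        result = score_patient(patient(pfs=7.2, response=BestResponse.SD, docb=8.0))
        assert result.preliminary == 3

    def test_progressive_disease_short_pfs_grade_1(self):
        result = score_patient(patient(pfs=2.4, response=BestResponse.PD))
        assert result.preliminary == 1

    def test_missing_response_and_pfs_not_assessable(self):
        result = score_patient(patient())
        assert result.status == Status.not_assessable

    def test_docb_never_inferred_from_pfs(self):
        # durable SD without an explicit DoCB earns no disease-control credit
        result = score_patient(patient(pfs=4.0, response=BestResponse.SD))
        assert result.preliminary == 2  # PFS band only

    def test_non_patient_record_rejected(self, table2):
        with pytest.raises(ValueError, match="n-of-1"):
            score_patient(table2[0])

    def test_engine_matches_straight_line_oracle_on_simulated_patients(self):
        cohort = generate_cohort(default_config(seed=424, n_patients=400))
        responders = {BestResponse.CR, BestResponse.PR, BestResponse.MR}
        controlled = responders | {BestResponse.SD}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonMonotoneBandWarning)
            for p in cohort:
                result = score_patient(p)
                assert result.scored
                orr = 100.0 if p.best_response in responders else 0.0
                dcr = 100.0 if p.best_response in controlled else 0.0
                docb = p.response.docb_months if p.response else None
                expected = oracle_final(
                    p.single_arm_pfs_months, orr, dcr, docb,
                    tox_yes=p.flags.toxicity_ge30pct_grade34 == Ternary.yes,
                    upgrade_yes=p.flags.qol_improved == Ternary.yes,
                )
                assert result.final == expected, p.record_id
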