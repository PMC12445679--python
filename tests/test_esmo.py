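"""ESMO form routing, Forms 2a/2b/2c/3 scoring, and assessability rules."""

import itertools

import pytest

from neuromcbs.esmo import (
    FormId,
    NotAssessableReason,
    Status,
    score_esmo,
    score_form2a,
    score_form2b,
    score_form2c,
    score_form3,
    select_form,
)
from neuromcbs.records import (
    AdjustmentFlags,
    Design,
    Endpoint,
    HazardRatioEstimate,
    ResponseSummary,
    StudyRecord,
    SurvivalEndpoint,
    Ternary,
)


def comparative(
    record_id="trial",
    design=Design.comparative_superiority,
    primary=Endpoint.OS,
    os_gain=None,
    os_hr=None,
    os_cm=None,
    pfs_gain=None,
    pfs_hr=None,
    pfs_cm=None,
    superiority=Ternary.yes,
    noninferiority=Ternary.unknown,
    flags=None,
):
    os_ep = pfs_ep = None
    if os_gain is not None or os_hr is not None:
        os_ep = SurvivalEndpoint(
            endpoint_kind=Endpoint.OS, gain_months=os_gain,
            hr=None if os_hr is None else HazardRatioEstimate(
                point=os_hr[1], lower95=os_hr[0], upper95=os_hr[2]),
            control_median_months=os_cm,
        )
    if pfs_gain is not None or pfs_hr is not None:
        pfs_ep = SurvivalEndpoint(
            endpoint_kind=Endpoint.PFS, gain_months=pfs_gain,
            hr=None if pfs_hr is None else HazardRatioEstimate(
                point=pfs_hr[1], lower95=pfs_hr[0], upper95=pfs_hr[2]),
            control_median_months=pfs_cm,
        )
    return StudyRecord(
        record_id=record_id, design=design, primary_endpoint=primary,
        superiority_met=superiority, noninferiority_met=noninferiority,
        os=os_ep, pfs=pfs_ep, flags=flags or AdjustmentFlags(),
    )


def single_arm(record_id="study", pfs=None, orr=None, dor=None, flags=None,
               primary=Endpoint.ORR):
    return StudyRecord(
        record_id=record_id, design=Design.single_arm, primary_endpoint=primary,
        single_arm_pfs_months=pfs,
        response=None if orr is None and dor is None else ResponseSummary(
            orr_pct=orr, dor_months=dor),
        flags=flags or AdjustmentFlags(),
    )


class TestRouter:
    def test_os_primary_goes_to_2a(self):
        r = comparative(os_gain=2.5, os_hr=(0.53, 0.63, 0.75))
        assert select_form(r) == FormId.form2a

    def test_pfs_primary_with_os_benefit_promoted_to_2a(self):
        # a PFS-primary trial whose OS hazard-ratio CI excludes 1
        r = comparative(primary=Endpoint.PFS, pfs_gain=2.7, pfs_hr=(0.52, 0.63, 0.76),
                        os_gain=4.9, os_hr=(0.53, 0.63, 0.76))
        assert select_form(r) == FormId.form2a

    def test_pfs_primary_without_os_benefit_stays_2b(self):
        r = comparative(primary=Endpoint.PFS, pfs_gain=16.6, pfs_hr=(0.27, 0.39, 0.56))
        assert select_form(r) == FormId.form2b

    def test_noninferiority_goes_to_2c(self):
        r = comparative(design=Design.comparative_noninferiority,
                        os_gain=-1.0, os_hr=(0.84, 1.09, 1.42),
                        superiority=Ternary.no, noninferiority=Ternary.yes)
        assert select_form(r) == FormId.form2c

    def test_other_primary_goes_to_2c(self):
        r = comparative(primary=Endpoint.ORR, os_hr=(0.5, 0.6, 0.7))
        assert select_form(r) == FormId.form2c

    def test_single_arm_goes_to_form3(self):
        assert select_form(single_arm(orr=20)) == FormId.form3

    def test_router_is_deterministic_and_total_on_fixture(self, table1, table1_expected):
        for record in table1:
            form = select_form(record)
            assert form.value == table1_expected[record.record_id]["expected_form"]
            assert select_form(record) == form


class TestForm2a:
    def test_fixture_scores_match_printed_column(self, table1, table1_expected, registry):
        for record in table1:
            exp = table1_expected[record.record_id]
            if exp["expected_form"] != "form2a":
                continue
            result = score_form2a(record, registry)
            if exp["expected_status"] == "scored":
                assert result.scored, record.record_id
                assert result.final == float(exp["expected_esmo_score"]), record.record_id
            else:
                assert result.status == Status.not_assessable
                assert result.not_assessable_reason.value == exp["expected_reason"]

    def test_band_dependent_record_without_control_median(self):
        # OS gain 2.5 months grades differently under the two bands
        r = comparative(os_gain=2.5, os_hr=(0.53, 0.63, 0.75))
        result = score_form2a(r)
        assert result.status == Status.not_assessable
        assert result.not_assessable_reason == NotAssessableReason.control_median_required

    def test_upgrade_credit_capped_at_5(self):
        flags = AdjustmentFlags(qol_assessed=Ternary.yes, qol_improved=Ternary.yes)
        r = comparative(os_gain=16.5, os_hr=(0.35, 0.6, 1.03), flags=flags)
        result = score_form2a(r)
        assert result.preliminary == 4 and result.final == 5

    def test_monotone_in_gain_and_hr_lower_limit(self, registry):
        gains = [0.5, 1.5, 2.0, 2.5, 3.0, 6.0, 20.0]
        lls = [0.9, 0.75, 0.70, 0.65, 0.5, 0.3]
        for cm in (10.0, 20.0):
            for ll in lls:
                prelims = []
                for gain in gains:
                    r = comparative(os_gain=gain, os_hr=(ll, max(ll, 0.95), 1.5), os_cm=cm)
                    prelims.append(score_form2a(r, registry).preliminary)
                assert prelims == sorted(prelims)
            for gain in gains:
                prelims = []
                for ll in lls:  # decreasing lower limit
                    r = comparative(os_gain=gain, os_hr=(ll, max(ll, 0.95), 1.5), os_cm=cm)
                    prelims.append(score_form2a(r, registry).preliminary)
                assert prelims == sorted(prelims)


class TestForm2b:
    def test_indigo_style_record_scores_4_with_upgrade(self, table1, table1_expected):
        record = next(r for r in table1 if r.record_id == "indigo")
        result = score_esmo(record)
        assert result.form_id == FormId.form2b
        assert result.preliminary == 3
        assert [a.delta for a in result.adjustments] == [1]
        assert result.final == 4

    def test_hr_lower_limit_boundary_is_closed(self):
        r = comparative(primary=Endpoint.PFS, pfs_gain=4.0,
                        pfs_hr=(0.65, 0.8, 1.0), pfs_cm=8.0)
        assert score_form2b(r).preliminary == 3

    def test_final_never_exceeds_4_over_all_flag_combinations(self):
        ternaries = [Ternary.yes, Ternary.no, Ternary.unknown]
        for qol, tox_red, cross in itertools.product(ternaries, repeat=3):
            flags = AdjustmentFlags(
                qol_assessed=Ternary.yes if qol == Ternary.yes else Ternary.unknown,
                qol_improved=qol, toxicity_reduced_vs_control=tox_red,
                early_stopping_or_crossover=cross,
            )
            for gain, ll in [(16.6, 0.27), (2.0, 0.6), (0.5, 0.9)]:
                r = comparative(primary=Endpoint.PFS, pfs_gain=gain,
                                pfs_hr=(ll, max(ll, 0.95), 1.2), pfs_cm=5.0, flags=flags)
                result = score_form2b(r)
                assert 0 <= result.final <= 4
                for a in result.adjustments:
                    assert a.delta in (-1, 1)


class TestForm2c:
    def _ni(self, tox=Ternary.unknown, qol=Ternary.unknown, met=Ternary.yes):
        flags = AdjustmentFlags(
            toxicity_reduced_vs_control=tox,
            qol_assessed=Ternary.yes if qol == Ternary.yes else Ternary.unknown,
            qol_improved=qol,
        )
        return comparative(design=Design.comparative_noninferiority,
                           os_gain=-1.0, os_hr=(0.84, 1.09, 1.42),
                           superiority=Ternary.no, noninferiority=met, flags=flags)

    def test_unknown_toxicity_blocks_scoring(self):
        result = score_form2c(self._ni())
        assert result.not_assessable_reason == NotAssessableReason.insufficient_toxicity_data

    def test_reduced_toxicity_unlocks_score(self):
        result = score_form2c(self._ni(tox=Ternary.yes))
        assert result.scored and result.final == 4

    def test_noninferiority_not_met(self):
        result = score_form2c(self._ni(met=Ternary.no))
        assert result.not_assessable_reason == NotAssessableReason.no_statistical_significance


class TestForm3:
    def test_fixture_scores_match_printed_column(self, table2, table2_expected, registry):
        for record in table2:
            exp = table2_expected[record.record_id]
            result = score_form3(record, registry)
            if exp["expected_status"] == "scored":
                assert result.scored, record.record_id
                assert result.final == float(exp["expected_esmo_score"]), record.record_id
            else:
                assert result.status == Status.not_assessable
                assert result.not_assessable_reason.value == exp["expected_reason"]

    def test_missing_duration_blocks_mid_band_orr(self):
        # ORR in the duration-dependent band with DoR unreported: not assessable
        result = score_form3(single_arm(orr=24))
        assert result.not_assessable_reason == NotAssessableReason.duration_of_response_missing

    def test_high_orr_needs_no_duration(self):
        assert score_form3(single_arm(orr=94)).preliminary == 3

    def test_empty_record_not_assessable(self):
        result = score_form3(single_arm())
        assert result.status == Status.not_assessable

    def test_comparative_record_rejected(self):
        with pytest.raises(ValueError, match="single-arm"):
            score_form3(comparative(os_gain=2.0, os_hr=(0.5, 0.6, 0.7)))


def test_adjustments_are_individually_logged_unit_steps(table1, table2):
    for record in table1 + table2:
        result = score_esmo(record)
        for a in result.adjustments:
            assert a.delta in (-1, 1)
        if result.scored and result.preliminary is not None:
            expected = result.preliminary + sum(a.delta for a in result.adjustments)
            maximum = 5 if result.form_id == FormId.form2a else 4
            assert result.final == min(max(expected, 0), maximum)
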