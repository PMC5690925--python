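import datetime

import pytest

from cobaltqa import (
    ERROR_KIND_CATEGORIES,
    ErrorSpec,
    GridSpec,
    NoiseSpec,
    ToleranceConfig,
    default_reference_sources,
    generate_plan,
    inject_error,
    reference_error_catalogue,
    simulate_delivery,
    verify_delivery,
)
from cobaltqa.checks import check_beam, check_prescription, check_source

from conftest import TREATMENT_DATE


def _fail_items(verification):
    return [r for r in verification.results if r.status == "fail"]


class TestCleanDelivery:
    def test_error_free_simulation_passes(self, plan, record, tol):
        v = verify_delivery(plan, record, tol)
        assert v.overall == "pass"
        assert v.n_fail == 0 and v.n_warn == 0
        assert all(s.pass_rate == 100.0 for s in v.per_beam_fluence.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_error_completeness_over_seeds(self, sources, tol, seed):
        """Error-free deliveries with machine noise at 10% of each tolerance
        never trip a check."""
        plan = generate_plan(seed, n_groups=1, beams_per_group=2, segments_per_beam=2)
        noise = NoiseSpec(gantry_deg_sd=0.05, leaf_cm_sd=0.02, time_s_sd=0.02)
        record = simulate_delivery(plan, sources, TREATMENT_DATE, noise=noise, seed=seed)
        v = verify_delivery(plan, record, tol)
        assert v.overall == "pass" and v.n_fail == 0 and v.n_warn == 0


class TestIdentityAndPrescription:
    def test_wrong_patient_id_fails_on_patient_id(self, plan, record, tol):
        bad = inject_error(record, ErrorSpec(kind="wrong_patient"))
        v = verify_delivery(plan, bad, tol)
        assert v.overall == "fail"
        assert any(r.item == "Patient ID" for r in _fail_items(v))

    def test_plan_version_suffix_fails_on_plan_name(self, plan, record, tol):
        bad = inject_error(record, ErrorSpec(kind="wrong_plan_version"))
        v = verify_delivery(plan, bad, tol)
        assert any(r.item == "Plan name" for r in _fail_items(v))

    def test_changed_prescription_dose_fails(self, plan, record, tol):
        # daily dose changed from 2 Gy to 1.8 Gy in the delivered plan
        bad = record.model_copy(deep=True)
        bad.prescription = bad.prescription.model_copy(update={"dose_per_fraction": 1.8})
        results = check_prescription(plan, bad, tol)
        dose = next(r for r in results if "dose" in r.item.lower())
        assert dose.status == "fail"

    def test_fraction_overrun_warns_not_fails(self, plan, sources, tol):
        record = simulate_delivery(
            plan, sources, TREATMENT_DATE,
            fraction_number=plan.prescription.n_fractions + 1,
        )
        results = check_prescription(plan, record, tol)
        overrun = next(r for r in results if "Fraction number" in r.item)
        assert overrun.status == "warn"


class TestSourceChecks:
    def test_correctly_decayed_rate_passes(self, record, tol):
        results = check_source(record.sources, tol, TREATMENT_DATE)
        assert all(r.status == "pass" for r in results)

    def test_undecayed_rate_on_later_date_fails(self, record, tol):
        bad = inject_error(record, ErrorSpec(kind="source_decay_wrong", head_id=1))
        results = check_source(bad.sources, tol, TREATMENT_DATE)
        failed = [r for r in results if r.status == "fail"]
        assert failed and all("Head 1 decayed" in r.item for r in failed)

    def test_serial_mismatch_fails(self, record, tol):
        bad = record.model_copy(deep=True)
        bad.sources[0] = bad.sources[0].model_copy(update={"serial": "SN-9999"})
        results = check_source(bad.sources, tol, TREATMENT_DATE)
        assert any(r.status == "fail" and "serial" in r.item for r in results)


class TestBeamTolerances:
    @pytest.mark.parametrize(
        "offset, expected",
        [(0.4, "pass"), (0.5, "pass"), (0.6, "fail"), (-0.6, "fail"), (-0.4, "pass")],
    )
    def test_gantry_boundary_and_symmetry(self, plan, record, tol, offset, expected):
        bid = plan.beams[0].beam_id
        bad = inject_error(record, ErrorSpec(kind="gantry_offset", magnitude=offset, beam_id=bid))
        results = check_beam(
            plan.beams[0], bad.delivered_beams[0],
            record.source_for_head(plan.beams[0].head_id).decayed_dose_rate, tol,
        )
        gantry = next(r for r in results if "Gantry" in r.item)
        assert gantry.status == expected

    def test_missing_segment_fails_on_count(self, plan, record, tol):
        bid = plan.beams[0].beam_id
        bad = inject_error(record, ErrorSpec(kind="skip_segment", beam_id=bid))
        v = verify_delivery(plan, bad, tol)
        assert any("Number of segments" in r.item for r in _fail_items(v))


class TestSegmentTolerances:
    @pytest.mark.parametrize("offset_cm, expected", [(1.0, "fail"), (0.1, "pass"), (-1.0, "fail")])
    def test_single_leaf_error(self, plan, record, tol, offset_cm, expected):
        bid = plan.beams[0].beam_id
        leaf = next(
            2 * p.pair_index - 1
            for p in plan.beams[0].segments[0].leaf_pairs if not p.is_closed
        )
        bad = inject_error(
            record,
            ErrorSpec(kind="leaf_offset", magnitude=offset_cm, beam_id=bid,
                      segment_index=1, leaf_index=leaf),
        )
        v = verify_delivery(plan, bad, tol)
        mlc = [r for r in v.results if "MLC leaf positions" in r.item and f"segment 1" in r.item
               and bid in r.item]
        assert mlc[0].status == expected
        if expected == "fail":
            assert f"pair {(leaf + 1) // 2}" in mlc[0].item

    def test_junction_walk_beyond_tolerance_fails(self, plan, record, tol):
        bid = plan.beams[0].beam_id
        bad = inject_error(
            record, ErrorSpec(kind="junction_walk", magnitude=1.0, beam_id=bid, segment_index=1)
        )
        v = verify_delivery(plan, bad, tol)
        assert any(r.category == "segment" and "MLC" in r.item for r in _fail_items(v))


class TestFluenceCheck:
    def test_beam_weighting_one_percent_reflected_in_time_and_fluence(self, plan, record, tol):
        """Scaling a beam's segment times by 1% must surface as a beam-on
        time discrepancy and a nonzero fluence difference."""
        bid = plan.beams[0].beam_id
        bad = inject_error(record, ErrorSpec(kind="beam_time_scale", magnitude=1.01, beam_id=bid))
        v = verify_delivery(plan, bad, tol)
        assert any("Total beam-on time" in r.item and bid in r.item for r in _fail_items(v))
        assert v.per_beam_fluence[bid].max_diff > 0.0

    def test_missing_final_segment_drops_pass_rate(self, sources, tol):
        # one beam, two segments with disjoint-enough apertures: dropping the
        # last removes >2% of max from a large share of evaluated pixels
        plan = generate_plan(17, n_groups=1, beams_per_group=1, segments_per_beam=2)
        record = simulate_delivery(plan, sources, TREATMENT_DATE)
        bid = plan.beams[0].beam_id
        bad = inject_error(record, ErrorSpec(kind="skip_segment", beam_id=bid, segment_index=2))
        v = verify_delivery(plan, bad, tol)
        stats = v.per_beam_fluence[bid]
        assert stats.pass_rate is not None and stats.pass_rate < 90.0


class TestVerifyDelivery:
    def test_skipped_beam_reported_as_incomplete_delivery(self, plan, record, tol):
        bid = plan.beams[1].beam_id
        bad = inject_error(record, ErrorSpec(kind="skip_beam", beam_id=bid))
        v = verify_delivery(plan, bad, tol)
        assert v.overall == "fail"
        assert any(f"Beam {bid} delivered" == r.item for r in _fail_items(v))
        assert any(r.item == "Total number of beams" for r in _fail_items(v))

    def test_interrupted_then_resumed_segment_passes(self, plan, record, tol):
        resumed = inject_error(
            record,
            ErrorSpec(kind="interruption_split", magnitude=1.0,
                      beam_id=plan.beams[0].beam_id, segment_index=1),
        )
        v = verify_delivery(plan, resumed, tol)
        assert v.overall == "pass" and v.n_fail == 0

    def test_aborted_interruption_fails(self, plan, record, tol):
        aborted = inject_error(
            record,
            ErrorSpec(kind="interruption_split", magnitude=0.5,
                      beam_id=plan.beams[0].beam_id, segment_index=1),
        )
        assert verify_delivery(plan, aborted, tol).overall == "fail"

    def test_every_catalogue_error_detected_with_correct_category(self, plan, record, tol):
        for spec in reference_error_catalogue(plan):
            bad = inject_error(record, spec)
            v = verify_delivery(plan, bad, tol)
            assert v.overall == "fail", spec.kind
            fail_cats = {r.category for r in _fail_items(v)}
            assert fail_cats & ERROR_KIND_CATEGORIES[spec.kind], (
                f"{spec.kind}: failing categories {fail_cats} miss "
                f"{ERROR_KIND_CATEGORIES[spec.kind]}"
            )

    def test_decay_uncorrected_log_times_detected(self, plan, sources, tol):
        """A log reporting times before the decay correction, with a decayed
        day rate, must fail both the beam-on-time and the fluence checks."""
        record = simulate_delivery(plan, sources, TREATMENT_DATE)
        bad = inject_error(
            record, ErrorSpec(kind="decay_uncorrected_times", magnitude=plan.nominal_dose_rate)
        )
        v = verify_delivery(plan, bad, tol)
        cats = {r.category for r in _fail_items(v)}
        assert {"fluence"} <= cats and ({"beam", "segment"} & cats)
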