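"""The comparison engine: plan vs delivery-log verification.

Runs in the order a reviewer reads the report: patient identity, then
prescription, then the day's cobalt-60 source data against the configured
reference, then plan-level structure, then every beam (gantry, segment
count, total beam-on time), every segment (leaf positions, time) and every
beam's integrated fluence map.

Tolerance semantics: a comparison *fails* when the deviation is strictly
greater than its tolerance — a deviation exactly at tolerance passes,
matching the "error greater than tolerance" reading of the detection rules.
Gantry differences are taken on the circle; beam-on times are compared on
the nominal-dose-rate scale (logged times normalized by the head's
day rate), so a log reporting decay-uncorrected times surfaces as an
over-tolerance time discrepancy.  Warn (never fail) is reserved for
non-safety findings: fraction overrun and a degenerate all-closed fluence
denominator.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .datamodel import (
    Beam,
    CheckResult,
    DeliveryRecord,
    FluenceMap,
    GridSpec,
    Plan,
    Segment,
    SourceInfo,
    ToleranceConfig,
    circular_difference_deg,
    total_beam_on_time,
)
from .decay import decay_factor, normalize_delivered_time
from .fluence import FluenceStats, compose_fluence, fluence_compare

__all__ = [
    "VerificationReportData",
    "check_identity",
    "check_prescription",
    "check_source",
    "check_beam",
    "check_segments",
    "check_beam_fluence",
    "verify_delivery",
]


@dataclass
class VerificationReportData:
    """Aggregate outcome of one delivery verification."""

    results: list[CheckResult]
    per_beam_fluence: dict[str, FluenceStats]
    per_beam_maps: dict[str, tuple[FluenceMap, FluenceMap]]
    overall: str
    counts: tuple[int, int, int]  # (n_pass, n_fail, n_warn)

    @property
    def n_pass(self) -> int:
        return self.counts[0]

    @property
    def n_fail(self) -> int:
        return self.counts[1]

    @property
    def n_warn(self) -> int:
        return self.counts[2]


def _exact(category: str, item: str, planned, delivered) -> CheckResult:
    status = "pass" if planned == delivered else "fail"
    return CheckResult(category, item, planned, delivered, "exact match", status)


def _within(category: str, item: str, planned: float, delivered: float,
            deviation: float, tolerance: float) -> CheckResult:
    status = "pass" if deviation <= tolerance else "fail"
    return CheckResult(category, item, planned, delivered, tolerance, status)


def check_identity(plan: Plan, record: DeliveryRecord) -> list[CheckResult]:
    """Patient name, patient ID and plan name must match exactly."""
    return [
        _exact("patient", "Patient name", plan.patient.name, record.patient.name),
        _exact("patient", "Patient ID", plan.patient.patient_id, record.patient.patient_id),
        _exact("plan", "Plan name", plan.plan_name, record.plan_name),
    ]


def check_prescription(
    plan: Plan, record: DeliveryRecord, config: ToleranceConfig
) -> list[CheckResult]:
    """Prescription dose, fraction count and PTV name; fraction overrun warns."""
    rx_p, rx_d = plan.prescription, record.prescription
    results = [
        _exact("prescription", "Prescription name", rx_p.prescription_name, rx_d.prescription_name),
        _exact(
            "prescription", "Prescription dose per fraction (Gy)",
            rx_p.dose_per_fraction, rx_d.dose_per_fraction,
        ),
        _exact("prescription", "Number of fractions", rx_p.n_fractions, rx_d.n_fractions),
        _exact("prescription", "PTV target", rx_p.ptv_name, rx_d.ptv_name),
    ]
    overrun = record.fraction_number > rx_p.n_fractions
    results.append(
        CheckResult(
            "prescription", "Fraction number within prescribed course",
            f"<= {rx_p.n_fractions}", record.fraction_number,
            rx_p.n_fractions, "warn" if overrun else "pass",
        )
    )
    return results


def check_source(
    record_sources: Sequence[SourceInfo],
    config: ToleranceConfig,
    treatment_date: datetime.date,
) -> list[CheckResult]:
    """Day-of-treatment source data vs the configured reference.

    Serial and calibration data must match the reference exactly; the
    decayed strength and dose rate are recomputed from the reference
    calibration via the half-life and must agree within
    ``config.source_rate_rel_tol`` (relative).
    """
    results: list[CheckResult] = []
    for src in sorted(record_sources, key=lambda s: s.head_id):
        h = src.head_id
        try:
            ref = config.reference_for_head(h)
        except KeyError:
            results.append(
                CheckResult("source", f"Head {h} reference data configured",
                            "present", "absent", "exact match", "fail")
            )
            continue
        results.append(_exact("source", f"Head {h} source serial", ref.serial, src.serial))
        results.append(
            _exact("source", f"Head {h} calibration date",
                   ref.calibration_date, src.calibration_date)
        )
        results.append(
            _exact("source", f"Head {h} calibration strength (Ci)",
                   ref.calibration_strength, src.calibration_strength)
        )
        results.append(
            _exact("source", f"Head {h} calibration dose rate (Gy/min)",
                   ref.calibration_dose_rate, src.calibration_dose_rate)
        )
        results.append(
            _exact("source", f"Head {h} source data date", treatment_date, src.as_of_date)
        )
        f = decay_factor(ref.calibration_date, treatment_date, config.half_life_years)
        for item, expected, logged in (
            (f"Head {h} decayed strength (Ci)", ref.calibration_strength * f, src.decayed_strength),
            (f"Head {h} decayed dose rate (Gy/min)", ref.calibration_dose_rate * f, src.decayed_dose_rate),
        ):
            ok = math.isclose(expected, logged, rel_tol=config.source_rate_rel_tol)
            results.append(
                CheckResult(
                    "source", item, expected, logged,
                    f"rel {config.source_rate_rel_tol:g}", "pass" if ok else "fail",
                )
            )
    return results


def check_beam(
    plan_beam: Beam,
    delivered_beam: Beam,
    day_rate: float,
    config: ToleranceConfig,
) -> list[CheckResult]:
    """Per-beam checks: gantry angle, head, segment count, total beam-on time.

    The delivered total time is normalized to the nominal-rate scale before
    comparison against the planned total.
    """
    bid = plan_beam.beam_id
    results = [
        _within(
            "beam", f"Gantry angle (beam {bid})",
            plan_beam.gantry_angle, delivered_beam.gantry_angle,
            circular_difference_deg(plan_beam.gantry_angle, delivered_beam.gantry_angle),
            config.gantry_deg,
        ),
        _exact("beam", f"Treatment head (beam {bid})", plan_beam.head_id, delivered_beam.head_id),
        _exact(
            "beam", f"Number of segments (beam {bid})",
            len(plan_beam.segments), len(delivered_beam.segments),
        ),
    ]
    planned_total = total_beam_on_time(plan_beam)
    delivered_total = normalize_delivered_time(
        total_beam_on_time(delivered_beam), config.nominal_dose_rate, day_rate
    )
    results.append(
        _within(
            "beam", f"Total beam-on time (beam {bid}, s at nominal rate)",
            round(planned_total, 3), round(delivered_total, 3),
            abs(delivered_total - planned_total), config.time_s,
        )
    )
    return results


def check_segments(
    plan_beam: Beam,
    delivered_beam: Beam,
    day_rate: float,
    config: ToleranceConfig,
) -> list[CheckResult]:
    """Per-segment checks: MLC leaf positions and beam-on time.

    Leaf positions are compared leaf by leaf against ``config.mlc_mm``; each
    segment yields one MLC result carrying the worst deviation, naming the
    offending leaf when over tolerance.  Segment times are compared on the
    nominal scale against ``config.time_s``.  Segments beyond the common
    count are flagged by :func:`check_beam`'s segment-count comparison.
    """
    bid = plan_beam.beam_id
    results: list[CheckResult] = []
    for plan_seg, del_seg in zip(plan_beam.segments, delivered_beam.segments):
        k = plan_seg.segment_index
        worst_mm = 0.0
        worst_leaf = ""
        for p_pair, d_pair in zip(plan_seg.leaf_pairs, del_seg.leaf_pairs):
            for side, p_x, d_x in (
                ("left", p_pair.left_x, d_pair.left_x),
                ("right", p_pair.right_x, d_pair.right_x),
            ):
                dev_mm = abs(d_x - p_x) * 10.0
                if dev_mm > worst_mm:
                    worst_mm = dev_mm
                    worst_leaf = f"pair {p_pair.pair_index} {side}"
        over = worst_mm > config.mlc_mm
        item = f"MLC leaf positions (beam {bid}, segment {k})"
        if over:
            item += f" — worst leaf {worst_leaf}"
        results.append(
            CheckResult(
                "segment", item,
                "0 mm deviation", f"{worst_mm:.1f} mm max deviation",
                config.mlc_mm, "fail" if over else "pass",
            )
        )
        normalized = normalize_delivered_time(
            del_seg.beam_on_time, config.nominal_dose_rate, day_rate
        )
        results.append(
            _within(
                "segment", f"Beam-on time (beam {bid}, segment {k}, s at nominal rate)",
                round(plan_seg.beam_on_time, 3), round(normalized, 3),
                abs(normalized - plan_seg.beam_on_time), config.time_s,
            )
        )
    return results


def check_beam_fluence(
    plan_beam: Beam,
    delivered_beam: Beam,
    day_rate: float,
    grid: GridSpec,
    config: ToleranceConfig,
) -> tuple[FluenceStats, CheckResult, FluenceMap, FluenceMap]:
    """Compose planned and delivered fluence maps and apply the pass-rate
    criterion; the beam fails when its pass rate drops below the accept rate.

    The delivered map is composed from decay-normalized segment times so a
    correct delivery at a decayed dose rate matches the planned map.
    """
    bid = plan_beam.beam_id
    plan_map = compose_fluence(plan_beam.segments, grid)
    normalized_segments = [
        seg.model_copy(
            update={
                "beam_on_time": normalize_delivered_time(
                    seg.beam_on_time, config.nominal_dose_rate, day_rate
                )
            }
        )
        for seg in delivered_beam.segments
    ]
    delivered_map = compose_fluence(normalized_segments, grid)
    stats = fluence_compare(
        plan_map, delivered_map, config.fluence_low_cut, config.fluence_pass_frac
    )
    if stats.pass_rate is None:
        result = CheckResult(
            "fluence", f"Fluence pass rate (beam {bid})",
            f">= {config.fluence_accept_rate:g}%", "no evaluable pixels",
            config.fluence_accept_rate, "warn",
        )
    else:
        ok = stats.pass_rate >= config.fluence_accept_rate
        result = CheckResult(
            "fluence", f"Fluence pass rate (beam {bid})",
            f">= {config.fluence_accept_rate:g}%", round(stats.pass_rate, 1),
            config.fluence_accept_rate, "pass" if ok else "fail",
        )
    return stats, result, plan_map, delivered_map


def _match_beams(
    plan: Plan, record: DeliveryRecord, config: ToleranceConfig
) -> tuple[list[tuple[Beam, Beam]], list[Beam], list[Beam]]:
    """Pair plan and delivered beams by beam_id, falling back to
    (head, gantry-within-tolerance); returns (matched, unmatched_plan,
    unmatched_delivered)."""
    delivered = list(record.delivered_beams)
    matched: list[tuple[Beam, Beam]] = []
    unmatched_plan: list[Beam] = []
    for pb in plan.beams:
        hit = next((db for db in delivered if db.beam_id == pb.beam_id), None)
        if hit is None:
            hit = next(
                (
                    db
                    for db in delivered
                    if db.head_id == pb.head_id
                    and circular_difference_deg(db.gantry_angle, pb.gantry_angle)
                    <= config.gantry_deg
                ),
                None,
            )
        if hit is None:
            unmatched_plan.append(pb)
        else:
            delivered.remove(hit)
            matched.append((pb, hit))
    return matched, unmatched_plan, delivered


def verify_delivery(
    plan: Plan,
    record: DeliveryRecord,
    config: ToleranceConfig,
    grid: Optional[GridSpec] = None,
) -> VerificationReportData:
    """Run the full verification: identity, prescription, source, plan
    structure, then per-beam, per-segment and fluence checks.

    A plan beam absent from the record (treatment interruption or incomplete
    delivery) fails, as does a delivered beam not in the plan.  The overall
    verdict is *fail* iff any individual result failed — which includes any
    beam whose fluence pass rate fell below the accept rate.
    """
    grid = grid or GridSpec()
    results: list[CheckResult] = []
    results += check_identity(plan, record)
    results += check_prescription(plan, record, config)
    treatment_date = max(s.as_of_date for s in record.sources)
    results += check_source(record.sources, config, treatment_date)
    results.append(
        _exact(
            "plan", "Total number of beams",
            len(plan.beams), len(record.delivered_beams),
        )
    )

    matched, missing, extra = _match_beams(plan, record, config)
    for pb in missing:
        results.append(
            CheckResult(
                "beam", f"Beam {pb.beam_id} delivered",
                "delivered", "absent from log (interrupted or incomplete delivery)",
                "exact match", "fail",
            )
        )
    for db in extra:
        results.append(
            CheckResult(
                "beam", f"Beam {db.beam_id} planned",
                "absent from plan", "delivered",
                "exact match", "fail",
            )
        )

    per_beam_fluence: dict[str, FluenceStats] = {}
    per_beam_maps: dict[str, tuple[FluenceMap, FluenceMap]] = {}
    for pb, db in matched:
        day_rate = record.source_for_head(db.head_id).decayed_dose_rate
        results += check_beam(pb, db, day_rate, config)
        results += check_segments(pb, db, day_rate, config)
        stats, fluence_result, plan_map, delivered_map = check_beam_fluence(
            pb, db, day_rate, grid, config
        )
        results.append(fluence_result)
        per_beam_fluence[pb.beam_id] = stats
        per_beam_maps[pb.beam_id] = (plan_map, delivered_map)

    n_pass = sum(r.status == "pass" for r in results)
    n_fail = sum(r.status == "fail" for r in results)
    n_warn = sum(r.status == "warn" for r in results)
    return VerificationReportData(
        results=results,
        per_beam_fluence=per_beam_fluence,
        per_beam_maps=per_beam_maps,
        overall="fail" if n_fail else "pass",
        counts=(n_pass, n_fail, n_warn),
    )
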