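"""Synthetic fixtures: random valid plans, simulated error-free deliveries,
and an injectable catalogue of delivery-error scenarios.

This module is the package's test and demo data source.  ``generate_plan``
emits reproducible step-and-shoot plans (rectangular or staircase apertures,
beam groups 120 degrees apart); ``simulate_delivery`` turns a plan into the
delivery log a well-behaved machine would write on a given treatment day,
with beam-on times stretched by the source decay of each head and optional
machine noise; ``inject_error`` applies exactly one delivery error from the
catalogue, leaving every other field identical.

Serialized quantities are quantized to the file dialect's resolution
(times 3 decimals, positions and gantry angles 2), so a generated object
survives a write/parse round-trip bit-identically.
"""

from __future__ import annotations

import copy
import datetime
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .datamodel import (
    N_LEAF_PAIRS,
    Beam,
    BeamGroup,
    DeliveryRecord,
    Interruption,
    LeafPair,
    PatientInfo,
    Plan,
    Prescription,
    Segment,
    SourceInfo,
)
from .decay import COBALT60_HALF_LIFE_YEARS, decayed_source, expected_delivered_time

__all__ = [
    "NoiseSpec",
    "ErrorSpec",
    "ERROR_KINDS",
    "ERROR_KIND_CATEGORIES",
    "generate_plan",
    "default_reference_sources",
    "simulate_delivery",
    "inject_error",
    "reference_error_catalogue",
]

_NAMES = ["ALPHA^TEST", "BRAVO^QA", "CHARLIE^PHANTOM", "DELTA^COMMISSION"]

DEFAULT_TREATMENT_DATE = datetime.date(2016, 4, 1)
_DEFAULT_CAL_DATE = datetime.date(2015, 6, 1)


def _q2(x: float) -> float:
    return round(float(x), 2)


def _q3(x: float) -> float:
    return round(float(x), 3)


class NoiseSpec(BaseModel):
    """Per-quantity machine-noise standard deviations for simulated logs.

    Defaults are zero (an exact delivery).  Realistic machine jitter sits
    well below the comparison tolerances, e.g. 10% of each.
    """

    model_config = ConfigDict(extra="forbid")
    gantry_deg_sd: float = 0.0
    leaf_cm_sd: float = 0.0
    time_s_sd: float = 0.0


def generate_plan(
    seed: int,
    n_groups: int = 2,
    beams_per_group: int = 2,
    segments_per_beam: int = 3,
    min_time_s: float = 1.0,
    max_time_s: float = 60.0,
    min_width_cm: float = 2.0,
    max_width_cm: float = 10.0,
) -> Plan:
    """Generate a random valid treatment plan, reproducible per seed.

    Apertures are rectangles or staircases 2-10 cm wide over a contiguous
    run of leaf pairs, with the remaining pairs closed at a common junction;
    segment beam-on times are uniform in [1, 60] s at the nominal dose rate.
    Beams within a group sit 120 degrees apart and are assigned to heads
    1..3 in order.
    """
    if not 1 <= beams_per_group <= 3:
        raise ValueError("beams_per_group must be in 1..3")
    rng = np.random.default_rng(seed)
    patient = PatientInfo(
        name=str(rng.choice(_NAMES)),
        patient_id=f"PT{int(rng.integers(1000, 10000))}",
    )
    prescription = Prescription(
        prescription_name="Rx daily",
        dose_per_fraction=2.0,
        n_fractions=25,
        ptv_name="PTV",
    )
    groups = []
    for g in range(1, n_groups + 1):
        base = _q2(rng.uniform(0.0, 360.0))
        beams = []
        for j in range(beams_per_group):
            segments = [
                _random_segment(rng, k, min_time_s, max_time_s, min_width_cm, max_width_cm)
                for k in range(1, segments_per_beam + 1)
            ]
            beams.append(
                Beam(
                    beam_id=f"G{g}B{j + 1}",
                    head_id=j + 1,
                    gantry_angle=_q2((base + 120.0 * j) % 360.0),
                    segments=segments,
                )
            )
        groups.append(BeamGroup(group_index=g, beams=beams))
    return Plan(
        patient=patient,
        prescription=prescription,
        plan_name=f"plan{seed:05d}",
        plan_date=datetime.date(2016, 3, 1),
        beam_groups=groups,
        nominal_dose_rate=1.85,
    )


def _random_segment(
    rng: np.random.Generator,
    index: int,
    min_time_s: float,
    max_time_s: float,
    min_width_cm: float,
    max_width_cm: float,
) -> Segment:
    n_open = int(rng.integers(4, 13))
    start = int(rng.integers(1, N_LEAF_PAIRS - n_open + 2))
    center = rng.uniform(-4.0, 4.0)
    width = rng.uniform(min_width_cm, max_width_cm)
    staircase = bool(rng.random() < 0.5)
    junction = _q2(center)
    pairs = []
    for i in range(1, N_LEAF_PAIRS + 1):
        if start <= i < start + n_open:
            jl = rng.uniform(-1.0, 1.0) if staircase else 0.0
            jr = rng.uniform(-1.0, 1.0) if staircase else 0.0
            left = _q2(center - width / 2.0 + jl)
            right = _q2(center + width / 2.0 + jr)
            if left >= right:  # staircase jitter may pinch the row shut
                left = right = junction
            pairs.append(LeafPair(pair_index=i, left_x=left, right_x=right))
        else:
            pairs.append(LeafPair(pair_index=i, left_x=junction, right_x=junction))
    return Segment(
        segment_index=index,
        beam_on_time=_q3(rng.uniform(min_time_s, max_time_s)),
        leaf_pairs=pairs,
    )


def default_reference_sources(
    calibration_date: datetime.date = _DEFAULT_CAL_DATE,
    calibration_dose_rate: float = 1.85,
) -> list[SourceInfo]:
    """Reference calibration data for the three heads, as a configuration
    would record it (decayed state equals calibration state on that date)."""
    return [
        SourceInfo(
            head_id=h,
            serial=f"SN-100{h}",
            calibration_date=calibration_date,
            calibration_strength=15000.0 + 10.0 * h,
            calibration_dose_rate=calibration_dose_rate,
            decayed_strength=15000.0 + 10.0 * h,
            decayed_dose_rate=calibration_dose_rate,
            as_of_date=calibration_date,
        )
        for h in (1, 2, 3)
    ]


def simulate_delivery(
    plan: Plan,
    sources: Sequence[SourceInfo],
    treatment_date: datetime.date = DEFAULT_TREATMENT_DATE,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
    fraction_number: int = 1,
    half_life_years: float = COBALT60_HALF_LIFE_YEARS,
) -> DeliveryRecord:
    """Simulate an error-free delivery of ``plan`` on ``treatment_date``.

    Each head's source is decayed from its calibration to the treatment day
    and every segment's beam-on time is stretched by ``nominal / day_rate``
    for its head, exactly as the machine compensates for source decay.
    Optional Gaussian noise (``NoiseSpec``) perturbs gantry, leaves and
    times; with zero noise and an undecayed source the record equals the
    plan's delivered view bit-for-bit.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    day_sources = [decayed_source(s, treatment_date, half_life_years) for s in sources]
    rate_by_head = {s.head_id: s.decayed_dose_rate for s in day_sources}

    delivered = []
    for beam in plan.beams:
        day_rate = rate_by_head[beam.head_id]
        segments = []
        for seg in beam.segments:
            t = expected_delivered_time(seg.beam_on_time, plan.nominal_dose_rate, day_rate)
            if noise.time_s_sd > 0:
                t += rng.normal(0.0, noise.time_s_sd)
            pairs = []
            for pair in seg.leaf_pairs:
                left, right = pair.left_x, pair.right_x
                if noise.leaf_cm_sd > 0:
                    left = _q2(left + rng.normal(0.0, noise.leaf_cm_sd))
                    right = _q2(right + rng.normal(0.0, noise.leaf_cm_sd))
                    if left > right:
                        left = right = _q2((left + right) / 2.0)
                pairs.append(LeafPair(pair_index=pair.pair_index, left_x=left, right_x=right))
            segments.append(
                Segment(
                    segment_index=seg.segment_index,
                    beam_on_time=max(_q3(t), 0.0),
                    leaf_pairs=pairs,
                )
            )
        gantry = beam.gantry_angle
        if noise.gantry_deg_sd > 0:
            gantry = _q2((gantry + rng.normal(0.0, noise.gantry_deg_sd)) % 360.0)
        delivered.append(
            Beam(
                beam_id=beam.beam_id,
                head_id=beam.head_id,
                gantry_angle=gantry,
                segments=segments,
            )
        )
    return DeliveryRecord(
        patient=plan.patient,
        plan_name=plan.plan_name,
        prescription=plan.prescription,
        fraction_number=fraction_number,
        delivered_beams=delivered,
        sources=day_sources,
        interruptions=[],
    )


# --------------------------------------------------------------------------
# error injection

ERROR_KINDS = (
    "gantry_offset",
    "leaf_offset",
    "segment_time_offset",
    "beam_time_scale",
    "skip_beam",
    "skip_segment",
    "wrong_patient",
    "wrong_plan_version",
    "decay_uncorrected_times",
    "interruption_split",
    "source_decay_wrong",
    "junction_walk",
)

#: Check categories in which each injected error kind must surface.
ERROR_KIND_CATEGORIES: dict[str, frozenset[str]] = {
    "gantry_offset": frozenset({"beam"}),
    "leaf_offset": frozenset({"segment"}),
    "segment_time_offset": frozenset({"segment", "beam"}),
    "beam_time_scale": frozenset({"beam", "segment", "fluence"}),
    "skip_beam": frozenset({"beam", "plan"}),
    "skip_segment": frozenset({"beam"}),
    "wrong_patient": frozenset({"patient"}),
    "wrong_plan_version": frozenset({"plan"}),
    "decay_uncorrected_times": frozenset({"segment", "beam", "fluence"}),
    "interruption_split": frozenset({"segment", "beam"}),
    "source_decay_wrong": frozenset({"source"}),
    "junction_walk": frozenset({"segment"}),
}


class ErrorSpec(BaseModel):
    """One delivery error to inject into a simulated record.

    ``magnitude`` units depend on the kind: degrees for ``gantry_offset``,
    cm for ``leaf_offset`` and ``junction_walk``, seconds (delivered scale)
    for ``segment_time_offset``, a dimensionless factor for
    ``beam_time_scale``, the nominal planning dose rate (Gy/min) for
    ``decay_uncorrected_times``, and the delivered fraction of the segment
    for ``interruption_split`` (1.0 = interrupted then fully resumed, < 1 =
    aborted mid-segment).  ``leaf_index`` is 1..60: odd values address the
    left leaf of pair (i+1)//2, even values the right leaf.
    """

    model_config = ConfigDict(extra="forbid")
    kind: Literal[
        "gantry_offset",
        "leaf_offset",
        "segment_time_offset",
        "beam_time_scale",
        "skip_beam",
        "skip_segment",
        "wrong_patient",
        "wrong_plan_version",
        "decay_uncorrected_times",
        "interruption_split",
        "source_decay_wrong",
        "junction_walk",
    ]
    magnitude: float = 0.0
    beam_id: Optional[str] = None
    segment_index: Optional[int] = None
    leaf_index: Optional[int] = None
    head_id: Optional[int] = None


def _find_beam(record: DeliveryRecord, beam_id: Optional[str]) -> Beam:
    if beam_id is None:
        return record.delivered_beams[0]
    for beam in record.delivered_beams:
        if beam.beam_id == beam_id:
            return beam
    raise ValueError(f"error target beam {beam_id!r} not in record")


def _find_segment(beam: Beam, segment_index: Optional[int]) -> Segment:
    if segment_index is None:
        return beam.segments[0]
    if not 1 <= segment_index <= len(beam.segments):
        raise ValueError(
            f"error target segment {segment_index} not in beam {beam.beam_id!r}"
        )
    return beam.segments[segment_index - 1]


def inject_error(record: DeliveryRecord, spec: ErrorSpec) -> DeliveryRecord:
    """Return a copy of ``record`` with exactly one error applied.

    All fields other than the targeted one are identical to the input.  For
    ``leaf_offset``, if the offset would push a leaf past its partner the
    partner is pushed along (a single pair cannot physically interdigitate).
    """
    rec = record.model_copy(deep=True)
    kind = spec.kind

    if kind == "gantry_offset":
        beam = _find_beam(rec, spec.beam_id)
        beam.gantry_angle = (beam.gantry_angle + spec.magnitude) % 360.0
    elif kind == "leaf_offset":
        beam = _find_beam(rec, spec.beam_id)
        seg = _find_segment(beam, spec.segment_index)
        if spec.leaf_index is None or not 1 <= spec.leaf_index <= 2 * N_LEAF_PAIRS:
            raise ValueError("leaf_offset requires leaf_index in 1..60")
        pair = seg.leaf_pairs[(spec.leaf_index - 1) // 2]
        if spec.leaf_index % 2 == 1:
            new_left = pair.left_x + spec.magnitude
            new_right = max(pair.right_x, new_left)
            pair.right_x = new_right
            pair.left_x = new_left
        else:
            new_right = pair.right_x + spec.magnitude
            new_left = min(pair.left_x, new_right)
            pair.left_x = new_left
            pair.right_x = new_right
    elif kind == "segment_time_offset":
        beam = _find_beam(rec, spec.beam_id)
        seg = _find_segment(beam, spec.segment_index)
        seg.beam_on_time = max(seg.beam_on_time + spec.magnitude, 0.0)
    elif kind == "beam_time_scale":
        beam = _find_beam(rec, spec.beam_id)
        for seg in beam.segments:
            seg.beam_on_time = seg.beam_on_time * spec.magnitude
    elif kind == "skip_beam":
        beam = _find_beam(rec, spec.beam_id)
        if len(rec.delivered_beams) == 1:
            raise ValueError("cannot skip the only delivered beam")
        # interruptions first: the record validator cross-checks them against beams
        rec.interruptions = [i for i in rec.interruptions if i.beam_id != beam.beam_id]
        rec.delivered_beams = [b for b in rec.delivered_beams if b.beam_id != beam.beam_id]
    elif kind == "skip_segment":
        beam = _find_beam(rec, spec.beam_id)
        idx = spec.segment_index if spec.segment_index is not None else len(beam.segments)
        if not 1 <= idx <= len(beam.segments):
            raise ValueError(f"segment {idx} not in beam {beam.beam_id!r}")
        if len(beam.segments) == 1:
            raise ValueError("cannot skip the only segment; use skip_beam")
        segments = [s for s in beam.segments if s.segment_index != idx]
        for pos, seg in enumerate(segments, start=1):
            seg.segment_index = pos
        beam.segments = segments
    elif kind == "wrong_patient":
        rec.patient.patient_id = rec.patient.patient_id + "X"
    elif kind == "wrong_plan_version":
        rec.plan_name = rec.plan_name + "_v2"
    elif kind == "decay_uncorrected_times":
        nominal = spec.magnitude if spec.magnitude > 0 else 1.85
        rate_by_head = {s.head_id: s.decayed_dose_rate for s in rec.sources}
        for beam in rec.delivered_beams:
            ratio = rate_by_head[beam.head_id] / nominal
            for seg in beam.segments:
                seg.beam_on_time = seg.beam_on_time * ratio
    elif kind == "interruption_split":
        beam = _find_beam(rec, spec.beam_id)
        seg = _find_segment(beam, spec.segment_index)
        frac = spec.magnitude if spec.magnitude > 0 else 1.0
        if frac > 1.0:
            raise ValueError("interruption_split magnitude is a fraction <= 1")
        new_total = _q3(seg.beam_on_time * frac)
        first = _q3(new_total * 0.6)
        seg.beam_on_time = new_total
        rec.interruptions.append(
            Interruption(
                beam_id=beam.beam_id,
                segment_index=seg.segment_index,
                partial_times=[first, _q3(new_total - first)],
            )
        )
    elif kind == "source_decay_wrong":
        heads = [spec.head_id] if spec.head_id is not None else [1, 2, 3]
        for pos, src in enumerate(rec.sources):
            if src.head_id in heads:
                # replace wholesale: strength and rate must change together to
                # keep the SourceInfo same-decay-factor invariant satisfied
                rec.sources[pos] = src.model_copy(
                    update={
                        "decayed_strength": src.calibration_strength,
                        "decayed_dose_rate": src.calibration_dose_rate,
                    }
                )
    elif kind == "junction_walk":
        beam = _find_beam(rec, spec.beam_id)
        seg = _find_segment(beam, spec.segment_index)
        closed = [p for p in seg.leaf_pairs if p.is_closed]
        if not closed:
            raise ValueError("junction_walk target segment has no closed leaf pair")
        pair = closed[0]
        if spec.magnitude >= 0:  # keep left <= right at every assignment
            pair.right_x = pair.right_x + spec.magnitude
            pair.left_x = pair.left_x + spec.magnitude
        else:
            pair.left_x = pair.left_x + spec.magnitude
            pair.right_x = pair.right_x + spec.magnitude
    else:  # pragma: no cover - Literal forbids this
        raise ValueError(f"unknown error kind {kind!r}")
    return rec


def reference_error_catalogue(plan: Plan) -> list[ErrorSpec]:
    """One :class:`ErrorSpec` per kind, at the magnitudes the verification is
    documented to detect: gantry 0.6 deg, a single leaf 1 cm, segment time
    0.3 s, beam weighting 1%, aborted interruption, decay-uncorrected times,
    undecayed source data, and a 1 cm closed-pair junction walk."""
    first = plan.beams[0].beam_id
    second = plan.beams[1].beam_id if len(plan.beams) > 1 else first
    leaf_index = _first_open_leaf_index(plan)
    return [
        ErrorSpec(kind="gantry_offset", magnitude=0.6, beam_id=first),
        ErrorSpec(
            kind="leaf_offset", magnitude=1.0, beam_id=first, segment_index=1,
            leaf_index=leaf_index,
        ),
        ErrorSpec(kind="segment_time_offset", magnitude=0.3, beam_id=first, segment_index=1),
        ErrorSpec(kind="beam_time_scale", magnitude=1.01, beam_id=first),
        ErrorSpec(kind="skip_beam", beam_id=second),
        ErrorSpec(kind="skip_segment", beam_id=first),
        ErrorSpec(kind="wrong_patient"),
        ErrorSpec(kind="wrong_plan_version"),
        ErrorSpec(kind="decay_uncorrected_times", magnitude=plan.nominal_dose_rate),
        ErrorSpec(kind="interruption_split", magnitude=0.5, beam_id=first, segment_index=1),
        ErrorSpec(kind="source_decay_wrong", head_id=1),
        ErrorSpec(kind="junction_walk", magnitude=1.0, beam_id=first, segment_index=1),
    ]


def _first_open_leaf_index(plan: Plan) -> int:
    for pair in plan.beams[0].segments[0].leaf_pairs:
        if not pair.is_closed:
            return 2 * pair.pair_index - 1  # left leaf of the first open pair
    raise ValueError("plan's first segment has no open leaf pair")
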