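"""Domain types for cobalt-60 treatment-delivery verification.

The machine modelled here has three cobalt-60 treatment heads mounted 120
degrees apart, each fitted with a 30-pair (60-leaf) multileaf collimator
(MLC).  A treatment plan is a list of *beam groups*; each group holds one to
three beams at gantry angles 120 degrees apart so the heads can deliver them
simultaneously.  Each beam is delivered step-and-shoot as a sequence of
*segments*, a segment being one static MLC aperture plus a beam-on time.

Planned beam-on times are expressed at the planning system's nominal dose
rate (1.85 Gy/min at new-source installation); as-delivered times in a
machine log are at the day's decayed dose rate.  The :mod:`cobaltqa.decay`
module converts between the two scales.

All geometric quantities are projected to the isocenter plane: ``x`` is the
leaf-travel direction, ``y`` the leaf-stacking direction, units cm, and leaf
pair 1 sits at the most-negative ``y``.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

N_LEAF_PAIRS = 30

__all__ = [
    "N_LEAF_PAIRS",
    "PatientInfo",
    "Prescription",
    "SourceInfo",
    "LeafPair",
    "Segment",
    "Beam",
    "BeamGroup",
    "Plan",
    "Interruption",
    "DeliveryRecord",
    "GridSpec",
    "FluenceMap",
    "CheckResult",
    "ToleranceConfig",
    "total_beam_on_time",
    "circular_difference_deg",
]


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest angular separation between two gantry angles, in degrees.

    Differences are taken on the circle so that 359.8 and 0.1 are 0.3 degrees
    apart, never 359.7.
    """
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


class _Model(BaseModel):
    model_config = ConfigDict(frozen=False, extra="forbid", validate_assignment=True)


class PatientInfo(_Model):
    name: str
    patient_id: str

    @field_validator("patient_id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("patient_id must be non-empty")
        return v


class Prescription(_Model):
    """Prescription summary: dose per fraction (Gy), fraction count, target name."""

    prescription_name: str
    dose_per_fraction: float
    n_fractions: int
    ptv_name: str

    @field_validator("dose_per_fraction")
    @classmethod
    def _dose_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("dose_per_fraction must be > 0")
        return v

    @field_validator("n_fractions")
    @classmethod
    def _fractions_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_fractions must be >= 1")
        return v


class SourceInfo(_Model):
    """Calibration and decayed state of one cobalt-60 source.

    ``decayed_strength`` / ``decayed_dose_rate`` are the source strength and
    dose rate on ``as_of_date``; each head decays independently from its own
    calibration.  The decayed and calibration quantities must share a single
    decay factor.
    """

    head_id: int
    serial: str
    calibration_date: datetime.date
    calibration_strength: float
    calibration_dose_rate: float
    decayed_strength: float
    decayed_dose_rate: float
    as_of_date: datetime.date

    @field_validator("head_id")
    @classmethod
    def _head_in_range(cls, v: int) -> int:
        if v not in (1, 2, 3):
            raise ValueError("head_id must be 1, 2 or 3")
        return v

    @model_validator(mode="after")
    def _decay_consistent(self) -> "SourceInfo":
        if self.as_of_date >= self.calibration_date:
            if self.decayed_strength > self.calibration_strength * (1 + 1e-9):
                raise ValueError(
                    "decayed_strength exceeds calibration_strength after calibration"
                )
        f_strength = self.decayed_strength / self.calibration_strength
        f_rate = self.decayed_dose_rate / self.calibration_dose_rate
        if not math.isclose(f_strength, f_rate, rel_tol=1e-6):
            raise ValueError(
                "strength and dose-rate decay factors disagree: "
                f"{f_strength!r} vs {f_rate!r}"
            )
        return self


class LeafPair(_Model):
    """One MLC leaf pair; positions in cm at the isocenter plane.

    ``left_x <= right_x``; a closed pair has the two leaves at the same
    junction position.
    """

    pair_index: int
    left_x: float
    right_x: float

    @field_validator("pair_index")
    @classmethod
    def _pair_in_range(cls, v: int) -> int:
        if not 1 <= v <= N_LEAF_PAIRS:
            raise ValueError(f"pair_index must be in 1..{N_LEAF_PAIRS}")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "LeafPair":
        if self.left_x > self.right_x + 1e-12:
            raise ValueError(
                f"leaf pair {self.pair_index}: left_x {self.left_x} > right_x {self.right_x}"
            )
        return self

    @property
    def is_closed(self) -> bool:
        return self.left_x == self.right_x

    @property
    def opening_cm(self) -> float:
        return self.right_x - self.left_x


class Segment(_Model):
    """One step-and-shoot segment: a static aperture plus a beam-on time."""

    segment_index: int
    beam_on_time: float
    leaf_pairs: list[LeafPair]

    @field_validator("segment_index")
    @classmethod
    def _index_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("segment_index must be >= 1")
        return v

    @field_validator("beam_on_time")
    @classmethod
    def _time_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("beam_on_time must be >= 0")
        return v

    @field_validator("leaf_pairs")
    @classmethod
    def _thirty_pairs(cls, v: list[LeafPair]) -> list[LeafPair]:
        if len(v) != N_LEAF_PAIRS:
            raise ValueError(f"segment must have exactly {N_LEAF_PAIRS} leaf pairs, got {len(v)}")
        for pos, pair in enumerate(v, start=1):
            if pair.pair_index != pos:
                raise ValueError(
                    f"leaf pairs out of order: position {pos} holds pair_index {pair.pair_index}"
                )
        return v


class Beam(_Model):
    """A treatment beam: one head, one gantry angle, ordered segments.

    Gantry angles are normalized to [0, 360).
    """

    beam_id: str
    head_id: int
    gantry_angle: float
    segments: list[Segment]

    @field_validator("head_id")
    @classmethod
    def _head_in_range(cls, v: int) -> int:
        if v not in (1, 2, 3):
            raise ValueError("head_id must be 1, 2 or 3")
        return v

    @field_validator("gantry_angle")
    @classmethod
    def _normalize_gantry(cls, v: float) -> float:
        v = v % 360.0
        if v == 360.0:  # -0.0 % 360 guard
            v = 0.0
        return v

    @field_validator("segments")
    @classmethod
    def _contiguous(cls, v: list[Segment]) -> list[Segment]:
        if not v:
            raise ValueError("beam must have at least one segment")
        for pos, seg in enumerate(v, start=1):
            if seg.segment_index != pos:
                raise ValueError(
                    f"segment indices must be 1..N without gaps; "
                    f"position {pos} has index {seg.segment_index}"
                )
        return v


class BeamGroup(_Model):
    """1-3 beams whose gantry angles are 120 degrees apart (mod 360), so the
    three heads can deliver them simultaneously."""

    group_index: int
    beams: list[Beam]

    @model_validator(mode="after")
    def _angles_120_apart(self) -> "BeamGroup":
        if not 1 <= len(self.beams) <= 3:
            raise ValueError("beam group must contain 1-3 beams")
        ref = self.beams[0].gantry_angle
        for b in self.beams[1:]:
            sep = (b.gantry_angle - ref) % 360.0
            rem = sep % 120.0
            if min(rem, 120.0 - rem) > 1e-6:
                raise ValueError(
                    f"group {self.group_index}: gantry angles must differ by a "
                    f"multiple of 120 degrees ({ref} vs {b.gantry_angle})"
                )
        return self


class Plan(_Model):
    """The approved treatment plan as parsed from a plan overview file."""

    patient: PatientInfo
    prescription: Prescription
    plan_name: str
    plan_date: datetime.date
    beam_groups: list[BeamGroup]
    nominal_dose_rate: float

    @model_validator(mode="after")
    def _valid(self) -> "Plan":
        if not self.beam_groups:
            raise ValueError("plan must contain at least one beam group")
        if self.nominal_dose_rate <= 0:
            raise ValueError("nominal_dose_rate must be > 0")
        ids = [b.beam_id for g in self.beam_groups for b in g.beams]
        if len(ids) != len(set(ids)):
            raise ValueError("beam_id values must be unique across the plan")
        return self

    @property
    def beams(self) -> list[Beam]:
        return [b for g in self.beam_groups for b in g.beams]


class Interruption(_Model):
    """A segment delivered in several radiation-on intervals (interrupted and
    resumed).  The partial times must sum to the segment's recorded time."""

    beam_id: str
    segment_index: int
    partial_times: list[float]

    @field_validator("partial_times")
    @classmethod
    def _nonempty(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("interruption must record at least one partial time")
        if any(t < 0 for t in v):
            raise ValueError("partial times must be >= 0")
        return v


class DeliveryRecord(_Model):
    """As-delivered treatment parameters from a machine delivery log.

    Per-segment beam-on times are at the day's decayed dose rate of the
    delivering head.  ``sources`` holds the day's state of all three
    cobalt-60 sources.
    """

    patient: PatientInfo
    plan_name: str
    prescription: Prescription
    fraction_number: int
    delivered_beams: list[Beam]
    sources: list[SourceInfo]
    interruptions: list[Interruption] = []

    @field_validator("fraction_number")
    @classmethod
    def _fraction_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("fraction_number must be >= 1")
        return v

    @field_validator("sources")
    @classmethod
    def _three_sources(cls, v: list[SourceInfo]) -> list[SourceInfo]:
        if sorted(s.head_id for s in v) != [1, 2, 3]:
            raise ValueError("delivery record must carry sources for heads 1, 2 and 3")
        return v

    @model_validator(mode="after")
    def _interruptions_consistent(self) -> "DeliveryRecord":
        by_id = {b.beam_id: b for b in self.delivered_beams}
        for itr in self.interruptions:
            beam = by_id.get(itr.beam_id)
            if beam is None:
                raise ValueError(f"interruption refers to unknown beam {itr.beam_id!r}")
            if not 1 <= itr.segment_index <= len(beam.segments):
                raise ValueError(
                    f"interruption refers to missing segment {itr.segment_index} "
                    f"of beam {itr.beam_id!r}"
                )
            seg = beam.segments[itr.segment_index - 1]
            if not math.isclose(sum(itr.partial_times), seg.beam_on_time, abs_tol=1e-6):
                raise ValueError(
                    f"interruption partial times for beam {itr.beam_id!r} segment "
                    f"{itr.segment_index} sum to {sum(itr.partial_times)}, "
                    f"segment records {seg.beam_on_time}"
                )
        return self

    def source_for_head(self, head_id: int) -> SourceInfo:
        for s in self.sources:
            if s.head_id == head_id:
                return s
        raise KeyError(f"no source for head {head_id}")


@dataclass(frozen=True)
class GridSpec:
    """Raster grid on the isocenter plane, centered on the beam axis.

    ``spacing`` is the pixel size (cm/pixel); ``x_extent``/``y_extent`` the
    full field of view (cm).  ``leaf_width`` is the projected width of one
    leaf pair in the stacking direction; the 30-pair stack is centered on the
    axis and must fit inside ``y_extent``.
    """

    spacing: float = 0.1
    x_extent: float = 31.5
    y_extent: float = 31.5
    leaf_width: float = 1.05

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.y_extent < N_LEAF_PAIRS * self.leaf_width - 1e-9:
            raise ValueError(
                f"y_extent {self.y_extent} cm does not cover the "
                f"{N_LEAF_PAIRS * self.leaf_width} cm leaf stack"
            )

    @property
    def nx(self) -> int:
        return int(round(self.x_extent / self.spacing))

    @property
    def ny(self) -> int:
        return int(round(self.y_extent / self.spacing))

    def x_edges(self) -> np.ndarray:
        return -self.x_extent / 2.0 + self.spacing * np.arange(self.nx + 1)

    def y_edges(self) -> np.ndarray:
        return -self.y_extent / 2.0 + self.spacing * np.arange(self.ny + 1)

    @property
    def pixel_area(self) -> float:
        return self.spacing * self.spacing


@dataclass
class FluenceMap:
    """Integrated primary fluence F(x, y) on the isocenter plane, in seconds.

    ``values[i, j]`` is the open time of the pixel at row i (y index, pair 1
    side at row 0) and column j (x index).
    """

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence values must be finite")
        if np.any(self.values < -1e-12):
            raise ValueError("fluence values must be >= 0")


Category = Literal["patient", "prescription", "source", "plan", "beam", "segment", "fluence"]
Status = Literal["pass", "fail", "warn"]


@dataclass(frozen=True)
class CheckResult:
    """Outcome of one compared item: planned vs delivered value, the applied
    tolerance, and pass/fail/warn status."""

    category: Category
    item: str
    planned_value: object
    delivered_value: object
    tolerance: object
    status: Status


class ToleranceConfig(_Model):
    """Program configuration: comparison tolerances, fluence criterion
    parameters, machine constants and the reference source data.

    Defaults follow clinic practice for this machine class: 0.5 degrees on
    gantry, 2 mm on individual MLC leaves, 0.2 s on beam-on times.  The
    fluence criterion evaluates pixels above ``fluence_low_cut`` (fraction of
    the planned map maximum), passes a pixel when the difference is under
    ``fluence_pass_frac`` of that maximum, and accepts a beam at a pass rate
    of ``fluence_accept_rate`` percent or better.
    """

    gantry_deg: float = 0.5
    mlc_mm: float = 2.0
    time_s: float = 0.2
    fluence_low_cut: float = 0.10
    fluence_pass_frac: float = 0.02
    fluence_accept_rate: float = 90.0
    nominal_dose_rate: float = 1.85
    half_life_years: float = 5.2711
    source_rate_rel_tol: float = 1e-3
    reference_sources: list[SourceInfo] = []

    @model_validator(mode="after")
    def _valid(self) -> "ToleranceConfig":
        for name in ("gantry_deg", "mlc_mm", "time_s", "nominal_dose_rate",
                     "half_life_years", "source_rate_rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.fluence_low_cut < 1:
            raise ValueError("fluence_low_cut must be in (0, 1)")
        if not 0 < self.fluence_pass_frac < 1:
            raise ValueError("fluence_pass_frac must be in (0, 1)")
        if not 0 < self.fluence_accept_rate <= 100:
            raise ValueError("fluence_accept_rate must be in (0, 100]")
        if self.reference_sources and sorted(
            s.head_id for s in self.reference_sources
        ) != [1, 2, 3]:
            raise ValueError("reference_sources must cover heads 1, 2 and 3")
        return self

    def reference_for_head(self, head_id: int) -> SourceInfo:
        for s in self.reference_sources:
            if s.head_id == head_id:
                return s
        raise KeyError(f"no reference source for head {head_id}")


def total_beam_on_time(beam: Beam) -> float:
    """Total beam-on time of a beam: the sum of its segment times, seconds."""
    return float(sum(seg.beam_on_time for seg in beam.segments))
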