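"""Cobalt-60 source-decay arithmetic.

Planned beam-on times are defined at the planning system's nominal dose rate
(1.85 Gy/min at new-source installation).  The source activity — and with it
the dose rate — decays with a half-life of about 5.27 years, so the machine
stretches every beam-on time by ``nominal_rate / day_rate`` to deliver the
planned dose.  These helpers convert between the two time scales and
recompute a day's decayed source state from its calibration data.

Plan-vs-log time comparisons are made on the nominal scale: logged times are
normalized back with :func:`normalize_delivered_time` before differencing.
A log that reports times *without* the decay correction then shows an
over-tolerance discrepancy, which is exactly the failure mode this check is
meant to catch.
"""

from __future__ import annotations

import datetime

from .datamodel import SourceInfo

COBALT60_HALF_LIFE_YEARS = 5.2711
DAYS_PER_YEAR = 365.25

__all__ = [
    "COBALT60_HALF_LIFE_YEARS",
    "decay_factor",
    "expected_delivered_time",
    "normalize_delivered_time",
    "decayed_source",
]


def decay_factor(
    calibration_date: datetime.date,
    query_date: datetime.date,
    half_life_years: float = COBALT60_HALF_LIFE_YEARS,
) -> float:
    """Radioactive decay factor 2**(-dt / T1/2) between two dates.

    ``dt`` is measured in Julian years (365.25 days).  The factor is 1.0 when
    the dates coincide and exactly 0.5 after one half-life.

    Raises ``ValueError`` if ``query_date`` precedes ``calibration_date`` or
    the half-life is not positive.
    """
    if half_life_years <= 0:
        raise ValueError("half_life_years must be > 0")
    if query_date < calibration_date:
        raise ValueError(
            f"query date {query_date} precedes calibration date {calibration_date}"
        )
    dt_years = (query_date - calibration_date).days / DAYS_PER_YEAR
    return 2.0 ** (-dt_years / half_life_years)


def expected_delivered_time(
    planned_s: float, nominal_rate: float, day_rate: float
) -> float:
    """Beam-on time the machine should deliver for a planned time.

    A segment planned for ``planned_s`` seconds at ``nominal_rate`` Gy/min
    must run ``planned_s * nominal_rate / day_rate`` seconds at the day's
    decayed rate to deliver the same dose.
    """
    if nominal_rate <= 0 or day_rate <= 0:
        raise ValueError("dose rates must be > 0")
    return planned_s * nominal_rate / day_rate


def normalize_delivered_time(
    delivered_s: float, nominal_rate: float, day_rate: float
) -> float:
    """Map an as-delivered time back onto the plan's nominal-rate scale.

    Inverse of :func:`expected_delivered_time`:
    ``normalize(expected(t)) == t`` to machine precision.
    """
    if nominal_rate <= 0 or day_rate <= 0:
        raise ValueError("dose rates must be > 0")
    return delivered_s * day_rate / nominal_rate


def decayed_source(
    reference: SourceInfo,
    as_of_date: datetime.date,
    half_life_years: float = COBALT60_HALF_LIFE_YEARS,
) -> SourceInfo:
    """Source state on ``as_of_date``, decayed from its calibration data.

    Each of the three heads decays independently from its own calibration;
    strength and dose rate scale by the same factor.
    """
    f = decay_factor(reference.calibration_date, as_of_date, half_life_years)
    return SourceInfo(
        head_id=reference.head_id,
        serial=reference.serial,
        calibration_date=reference.calibration_date,
        calibration_strength=reference.calibration_strength,
        calibration_dose_rate=reference.calibration_dose_rate,
        decayed_strength=reference.calibration_strength * f,
        decayed_dose_rate=reference.calibration_dose_rate * f,
        as_of_date=as_of_date,
    )
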