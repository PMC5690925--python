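"""Readers and writers for the plan overview / delivery log dialects,
the XML configuration, and IGRT screen captures.

The vendor's own plan overview and delivery log formats are proprietary, so
this package defines its own fully specified, human-diffable dialect carrying
the same content: UTF-8 text, line-oriented ``KEY = value`` entries inside
``[SECTION]`` blocks, ``#`` comments, and a mandatory ``FORMAT_VERSION``
header.  MLC apertures are 30 lines ``LEAF i = left right`` (cm at isocenter,
2 decimals); beam-on times carry 3 decimals (ms resolution) — both below the
comparison tolerances, so write/parse round-trips are exact.

A plan overview holds PATIENT, PRESCRIPTION, PLAN, then BEAM/SEGMENT blocks;
a delivery log holds PATIENT, PRESCRIPTION, FRACTION, three SOURCE blocks,
BEAM/SEGMENT blocks and optional INTERRUPT blocks.  Parsers are strict:
missing sections or keys, malformed numbers, wrong leaf counts and unknown
keys all raise :class:`ParseError` naming the line.

Screen captures are loaded only for embedding in the report; their content
is never analyzed.  A missing capture file yields a warning, not an error.
"""

from __future__ import annotations

import datetime
import io
import os
import xml.etree.ElementTree as ET
from typing import Iterable, Optional, Sequence

from PIL import Image

from .datamodel import (
    N_LEAF_PAIRS,
    Beam,
    BeamGroup,
    DeliveryRecord,
    GridSpec,
    Interruption,
    LeafPair,
    PatientInfo,
    Plan,
    Prescription,
    Segment,
    SourceInfo,
    ToleranceConfig,
)

FORMAT_VERSION = 1

__all__ = [
    "FORMAT_VERSION",
    "ParseError",
    "ConfigError",
    "parse_plan_overview",
    "parse_delivery_log",
    "write_plan_overview",
    "write_delivery_log",
    "load_screen_captures",
    "load_config",
    "write_config",
]


class ParseError(ValueError):
    """Malformed plan overview or delivery log document."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ConfigError(ValueError):
    """Malformed or unrecognized configuration XML."""


# --------------------------------------------------------------------------
# low-level dialect scanner

class _Section:
    def __init__(self, name: str, line: int):
        self.name = name
        self.line = line
        self.entries: dict[str, tuple[str, int]] = {}
        self.leaves: list[tuple[int, str, int]] = []  # (pair index, value, line)

    def take(self, key: str, parse, what: str = "value"):
        if key not in self.entries:
            raise ParseError(
                f"[{self.name}] section is missing required key {key!r}", self.line
            )
        raw, line = self.entries.pop(key)
        try:
            return parse(raw)
        except (ValueError, TypeError):
            raise ParseError(
                f"key {key!r}: cannot parse {raw!r} as {what}", line
            ) from None

    def reject_unknown(self) -> None:
        if self.entries:
            key = next(iter(self.entries))
            raise ParseError(
                f"unknown key {key!r} in [{self.name}] section",
                self.entries[key][1],
            )


def _scan(document: str) -> list[_Section]:
    """Split a dialect document into sections, checking the version header."""
    sections: list[_Section] = []
    current: Optional[_Section] = None
    version_seen = False
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = _Section(line[1:-1].strip().upper(), lineno)
            sections.append(current)
            continue
        if "=" not in line:
            raise ParseError(f"expected 'KEY = value', got {line!r}", lineno)
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "FORMAT_VERSION":
            if current is not None:
                raise ParseError("FORMAT_VERSION must precede all sections", lineno)
            try:
                version = int(value)
            except ValueError:
                raise ParseError(f"bad FORMAT_VERSION {value!r}", lineno) from None
            if version != FORMAT_VERSION:
                raise ParseError(
                    f"unsupported FORMAT_VERSION {version} (supported: {FORMAT_VERSION})",
                    lineno,
                )
            version_seen = True
            continue
        if current is None:
            raise ParseError(f"key {key!r} outside any section", lineno)
        if key.upper().startswith("LEAF "):
            try:
                idx = int(key.split(None, 1)[1])
            except ValueError:
                raise ParseError(f"bad leaf index in {key!r}", lineno) from None
            current.leaves.append((idx, value, lineno))
        else:
            if key in current.entries:
                raise ParseError(f"duplicate key {key!r} in [{current.name}]", lineno)
            current.entries[key] = (value, lineno)
    if not version_seen:
        raise ParseError("missing FORMAT_VERSION header")
    return sections


def _parse_date(raw: str) -> datetime.date:
    return datetime.date.fromisoformat(raw)


def _leaf_pairs(sec: _Section) -> list[LeafPair]:
    if len(sec.leaves) != N_LEAF_PAIRS:
        raise ParseError(
            f"[{sec.name}] segment has {len(sec.leaves)} leaf pairs, "
            f"expected {N_LEAF_PAIRS}",
            sec.line,
        )
    pairs = []
    for idx, raw, line in sorted(sec.leaves):
        parts = raw.split()
        if len(parts) != 2:
            raise ParseError(f"LEAF {idx}: expected 'left right', got {raw!r}", line)
        try:
            left, right = float(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(f"LEAF {idx}: non-numeric position in {raw!r}", line) from None
        try:
            pairs.append(LeafPair(pair_index=idx, left_x=left, right_x=right))
        except ValueError as exc:
            raise ParseError(f"LEAF {idx}: {exc}", line) from None
    return pairs


def _patient(sec: _Section) -> PatientInfo:
    p = PatientInfo(name=sec.take("NAME", str), patient_id=sec.take("ID", str))
    sec.reject_unknown()
    return p


def _prescription(sec: _Section) -> Prescription:
    rx = Prescription(
        prescription_name=sec.take("NAME", str),
        dose_per_fraction=sec.take("DOSE_PER_FRACTION_GY", float, "number"),
        n_fractions=sec.take("N_FRACTIONS", int, "integer"),
        ptv_name=sec.take("PTV_NAME", str),
    )
    sec.reject_unknown()
    return rx


def _segment(sec: _Section, index: int) -> Segment:
    seg_index = sec.take("INDEX", int, "integer")
    time_s = sec.take("BEAM_ON_TIME_S", float, "number")
    sec.reject_unknown()
    try:
        return Segment(
            segment_index=seg_index, beam_on_time=time_s, leaf_pairs=_leaf_pairs(sec)
        )
    except ValueError as exc:
        raise ParseError(f"segment {index}: {exc}", sec.line) from None


def _require_one(sections: list[_Section], name: str) -> _Section:
    found = [s for s in sections if s.name == name]
    if len(found) != 1:
        raise ParseError(
            f"document must contain exactly one [{name}] section, found {len(found)}"
        )
    return found[0]


# --------------------------------------------------------------------------
# plan overview

def parse_plan_overview(document: str) -> Plan:
    """Parse a plan overview document into a :class:`Plan`.

    Leaf positions come out in cm at isocenter and beam-on times in seconds
    at the plan's nominal dose rate.  Any structural defect — malformed
    section, missing key, a segment without its 30 leaf pairs, a non-numeric
    value — raises :class:`ParseError` naming the offending line.
    """
    sections = _scan(document)
    patient = _patient(_require_one(sections, "PATIENT"))
    prescription = _prescription(_require_one(sections, "PRESCRIPTION"))

    plan_sec = _require_one(sections, "PLAN")
    plan_name = plan_sec.take("NAME", str)
    plan_date = plan_sec.take("DATE", _parse_date, "ISO date")
    nominal_rate = plan_sec.take("NOMINAL_DOSE_RATE_GY_MIN", float, "number")
    plan_sec.reject_unknown()

    groups: dict[int, list[Beam]] = {}
    current: Optional[dict] = None  # pending beam fields + its segments

    def finish_beam() -> None:
        nonlocal current
        if current is None:
            return
        try:
            beam = Beam(
                beam_id=current["id"],
                head_id=current["head"],
                gantry_angle=current["gantry"],
                segments=current["segments"],
            )
        except ValueError as exc:
            raise ParseError(f"beam {current['id']!r}: {exc}", current["line"]) from None
        groups.setdefault(current["group"], []).append(beam)
        current = None

    n_segments = 0
    for sec in sections:
        if sec.name == "BEAM":
            finish_beam()
            current = {
                "id": sec.take("ID", str),
                "group": sec.take("GROUP", int, "integer"),
                "head": sec.take("HEAD", int, "integer"),
                "gantry": sec.take("GANTRY_DEG", float, "number"),
                "segments": [],
                "line": sec.line,
            }
            sec.reject_unknown()
        elif sec.name == "SEGMENT":
            if current is None:
                raise ParseError("[SEGMENT] section before any [BEAM]", sec.line)
            n_segments += 1
            current["segments"].append(_segment(sec, n_segments))
        elif sec.name in ("PATIENT", "PRESCRIPTION", "PLAN"):
            pass
        else:
            raise ParseError(f"unknown section [{sec.name}]", sec.line)
    finish_beam()
    if not groups:
        raise ParseError("plan contains no [BEAM] section")

    try:
        return Plan(
            patient=patient,
            prescription=prescription,
            plan_name=plan_name,
            plan_date=plan_date,
            nominal_dose_rate=nominal_rate,
            beam_groups=[
                BeamGroup(group_index=g, beams=beams)
                for g, beams in sorted(groups.items())
            ],
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def write_plan_overview(plan: Plan) -> str:
    """Serialize a plan; ``parse_plan_overview(write_plan_overview(p)) == p``."""
    out = io.StringIO()
    out.write("# plan overview\n")
    out.write(f"FORMAT_VERSION = {FORMAT_VERSION}\n\n")
    out.write("[PATIENT]\n")
    out.write(f"NAME = {plan.patient.name}\n")
    out.write(f"ID = {plan.patient.patient_id}\n\n")
    out.write("[PRESCRIPTION]\n")
    _write_prescription(out, plan.prescription)
    out.write("[PLAN]\n")
    out.write(f"NAME = {plan.plan_name}\n")
    out.write(f"DATE = {plan.plan_date.isoformat()}\n")
    out.write(f"NOMINAL_DOSE_RATE_GY_MIN = {plan.nominal_dose_rate!r}\n\n")
    for group in plan.beam_groups:
        for beam in group.beams:
            _write_beam(out, beam, group_index=group.group_index)
    return out.getvalue()


def _write_prescription(out: io.StringIO, rx: Prescription) -> None:
    out.write(f"NAME = {rx.prescription_name}\n")
    out.write(f"DOSE_PER_FRACTION_GY = {rx.dose_per_fraction!r}\n")
    out.write(f"N_FRACTIONS = {rx.n_fractions}\n")
    out.write(f"PTV_NAME = {rx.ptv_name}\n\n")


def _write_beam(out: io.StringIO, beam: Beam, group_index: Optional[int] = None) -> None:
    out.write("[BEAM]\n")
    out.write(f"ID = {beam.beam_id}\n")
    if group_index is not None:
        out.write(f"GROUP = {group_index}\n")
    out.write(f"HEAD = {beam.head_id}\n")
    out.write(f"GANTRY_DEG = {beam.gantry_angle:.2f}\n\n")
    for seg in beam.segments:
        out.write("[SEGMENT]\n")
        out.write(f"INDEX = {seg.segment_index}\n")
        out.write(f"BEAM_ON_TIME_S = {seg.beam_on_time:.3f}\n")
        for pair in seg.leaf_pairs:
            out.write(f"LEAF {pair.pair_index} = {pair.left_x:.2f} {pair.right_x:.2f}\n")
        out.write("\n")


# --------------------------------------------------------------------------
# delivery log

def parse_delivery_log(document: str) -> DeliveryRecord:
    """Parse a delivery log document into a :class:`DeliveryRecord`.

    The log must carry exactly three [SOURCE] sections (one per head) with
    the day's decayed strength and dose rate.  [INTERRUPT] sections record a
    segment delivered in several partial intervals; the partials are retained
    and must sum to the segment's recorded beam-on time.
    """
    sections = _scan(document)
    patient = _patient(_require_one(sections, "PATIENT"))
    prescription = _prescription(_require_one(sections, "PRESCRIPTION"))

    frac_sec = _require_one(sections, "FRACTION")
    fraction_number = frac_sec.take("NUMBER", int, "integer")
    plan_name = frac_sec.take("PLAN_NAME", str)
    frac_sec.reject_unknown()

    source_secs = [s for s in sections if s.name == "SOURCE"]
    if not source_secs:
        raise ParseError("source info absent: no [SOURCE] section in log")
    if len(source_secs) != 3:
        raise ParseError(
            f"log must carry 3 [SOURCE] sections (one per head), found {len(source_secs)}"
        )
    sources = [_source(s) for s in source_secs]

    beams: list[Beam] = []
    current: Optional[dict] = None
    interruptions: list[Interruption] = []

    def finish_beam() -> None:
        nonlocal current
        if current is None:
            return
        try:
            beams.append(
                Beam(
                    beam_id=current["id"],
                    head_id=current["head"],
                    gantry_angle=current["gantry"],
                    segments=current["segments"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"beam {current['id']!r}: {exc}", current["line"]) from None
        current = None

    n_segments = 0
    for sec in sections:
        if sec.name == "BEAM":
            finish_beam()
            current = {
                "id": sec.take("ID", str),
                "head": sec.take("HEAD", int, "integer"),
                "gantry": sec.take("GANTRY_DEG", float, "number"),
                "segments": [],
                "line": sec.line,
            }
            sec.reject_unknown()
        elif sec.name == "SEGMENT":
            if current is None:
                raise ParseError("[SEGMENT] section before any [BEAM]", sec.line)
            n_segments += 1
            current["segments"].append(_segment(sec, n_segments))
        elif sec.name == "INTERRUPT":
            beam_id = sec.take("BEAM", str)
            seg_index = sec.take("SEGMENT", int, "integer")
            raw, line = sec.entries.pop("PARTIAL_TIMES_S", (None, sec.line))
            if raw is None:
                raise ParseError("[INTERRUPT] missing PARTIAL_TIMES_S", sec.line)
            try:
                partials = [float(tok) for tok in raw.split()]
            except ValueError:
                raise ParseError(f"non-numeric partial time in {raw!r}", line) from None
            sec.reject_unknown()
            interruptions.append(
                Interruption(
                    beam_id=beam_id, segment_index=seg_index, partial_times=partials
                )
            )
        elif sec.name in ("PATIENT", "PRESCRIPTION", "FRACTION", "SOURCE"):
            pass
        else:
            raise ParseError(f"unknown section [{sec.name}]", sec.line)
    finish_beam()
    if not beams:
        raise ParseError("log contains no [BEAM] section")

    try:
        return DeliveryRecord(
            patient=patient,
            prescription=prescription,
            plan_name=plan_name,
            fraction_number=fraction_number,
            delivered_beams=beams,
            sources=sources,
            interruptions=interruptions,
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def _source(sec: _Section) -> SourceInfo:
    info = SourceInfo(
        head_id=sec.take("HEAD", int, "integer"),
        serial=sec.take("SERIAL", str),
        calibration_date=sec.take("CALIBRATION_DATE", _parse_date, "ISO date"),
        calibration_strength=sec.take("CALIBRATION_STRENGTH_CI", float, "number"),
        calibration_dose_rate=sec.take("CALIBRATION_DOSE_RATE_GY_MIN", float, "number"),
        decayed_strength=sec.take("DECAYED_STRENGTH_CI", float, "number"),
        decayed_dose_rate=sec.take("DECAYED_DOSE_RATE_GY_MIN", float, "number"),
        as_of_date=sec.take("AS_OF_DATE", _parse_date, "ISO date"),
    )
    sec.reject_unknown()
    return info


def write_delivery_log(record: DeliveryRecord) -> str:
    """Serialize a delivery record; parse∘write is the identity."""
    out = io.StringIO()
    out.write("# treatment delivery log\n")
    out.write(f"FORMAT_VERSION = {FORMAT_VERSION}\n\n")
    out.write("[PATIENT]\n")
    out.write(f"NAME = {record.patient.name}\n")
    out.write(f"ID = {record.patient.patient_id}\n\n")
    out.write("[PRESCRIPTION]\n")
    _write_prescription(out, record.prescription)
    out.write("[FRACTION]\n")
    out.write(f"NUMBER = {record.fraction_number}\n")
    out.write(f"PLAN_NAME = {record.plan_name}\n\n")
    for src in record.sources:
        out.write("[SOURCE]\n")
        out.write(f"HEAD = {src.head_id}\n")
        out.write(f"SERIAL = {src.serial}\n")
        out.write(f"CALIBRATION_DATE = {src.calibration_date.isoformat()}\n")
        out.write(f"CALIBRATION_STRENGTH_CI = {src.calibration_strength!r}\n")
        out.write(f"CALIBRATION_DOSE_RATE_GY_MIN = {src.calibration_dose_rate!r}\n")
        out.write(f"DECAYED_STRENGTH_CI = {src.decayed_strength!r}\n")
        out.write(f"DECAYED_DOSE_RATE_GY_MIN = {src.decayed_dose_rate!r}\n")
        out.write(f"AS_OF_DATE = {src.as_of_date.isoformat()}\n\n")
    for beam in record.delivered_beams:
        _write_beam(out, beam)
    for itr in record.interruptions:
        out.write("[INTERRUPT]\n")
        out.write(f"BEAM = {itr.beam_id}\n")
        out.write(f"SEGMENT = {itr.segment_index}\n")
        out.write(
            "PARTIAL_TIMES_S = " + " ".join(f"{t:.3f}" for t in itr.partial_times) + "\n\n"
        )
    return out.getvalue()


# --------------------------------------------------------------------------
# screen captures

def load_screen_captures(
    paths: Iterable[str | os.PathLike],
) -> tuple[list[Image.Image], list[str]]:
    """Load IGRT setup screen captures for embedding in the report.

    The images are never analyzed.  A missing or unreadable file is recorded
    as a warning and processing continues; returns ``(images, warnings)``.
    """
    images: list[Image.Image] = []
    warnings: list[str] = []
    for path in paths:
        try:
            with Image.open(path) as img:
                images.append(img.copy())
        except (FileNotFoundError, OSError) as exc:
            warnings.append(f"screen capture {os.fspath(path)!r} not loaded: {exc}")
    return images, warnings


# --------------------------------------------------------------------------
# configuration XML

_CONFIG_TAG = "cobaltqa_config"


def load_config(source: str | os.PathLike) -> tuple[ToleranceConfig, GridSpec]:
    """Load tolerances, fluence criterion, machine constants, grid and the
    reference source data from a configuration XML file (path or XML text).

    Unknown elements or attributes raise :class:`ConfigError` so a
    misspelled tolerance can never silently fall back to a default.
    """
    text = source
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and not source.lstrip().startswith("<")
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ConfigError(f"configuration XML is not well-formed: {exc}") from None
    if root.tag != _CONFIG_TAG:
        raise ConfigError(f"root element must be <{_CONFIG_TAG}>, got <{root.tag}>")
    if root.attrib.get("version") != "1":
        raise ConfigError("configuration must declare version=\"1\"")

    def attrs(el: ET.Element, allowed: dict[str, type]) -> dict:
        unknown = set(el.attrib) - set(allowed)
        if unknown:
            raise ConfigError(f"unknown attribute(s) {sorted(unknown)} on <{el.tag}>")
        out = {}
        for name, typ in allowed.items():
            if name not in el.attrib:
                raise ConfigError(f"<{el.tag}> is missing attribute {name!r}")
            raw = el.attrib[name]
            try:
                out[name] = typ(raw) if typ is not datetime.date else datetime.date.fromisoformat(raw)
            except ValueError:
                raise ConfigError(f"<{el.tag}> attribute {name!r}: bad value {raw!r}") from None
        return out

    tol_kw: dict = {}
    grid_kw: dict = {}
    references: list[SourceInfo] = []
    seen: set[str] = set()
    for el in root:
        if el.tag in seen:
            raise ConfigError(f"duplicate <{el.tag}> element")
        seen.add(el.tag)
        if el.tag == "tolerances":
            a = attrs(el, {"gantry_deg": float, "mlc_mm": float, "time_s": float})
            tol_kw.update(a)
        elif el.tag == "fluence":
            a = attrs(el, {"low_cut": float, "pass_frac": float, "accept_rate": float})
            tol_kw.update(
                fluence_low_cut=a["low_cut"],
                fluence_pass_frac=a["pass_frac"],
                fluence_accept_rate=a["accept_rate"],
            )
        elif el.tag == "machine":
            a = attrs(
                el,
                {
                    "nominal_dose_rate": float,
                    "half_life_years": float,
                    "source_rate_rel_tol": float,
                },
            )
            tol_kw.update(a)
        elif el.tag == "grid":
            grid_kw = attrs(
                el,
                {"spacing": float, "x_extent": float, "y_extent": float, "leaf_width": float},
            )
        elif el.tag == "sources":
            for sub in el:
                if sub.tag != "source":
                    raise ConfigError(f"unknown element <{sub.tag}> inside <sources>")
                a = attrs(
                    sub,
                    {
                        "head": int,
                        "serial": str,
                        "calibration_date": datetime.date,
                        "calibration_strength": float,
                        "calibration_dose_rate": float,
                    },
                )
                references.append(
                    SourceInfo(
                        head_id=a["head"],
                        serial=a["serial"],
                        calibration_date=a["calibration_date"],
                        calibration_strength=a["calibration_strength"],
                        calibration_dose_rate=a["calibration_dose_rate"],
                        decayed_strength=a["calibration_strength"],
                        decayed_dose_rate=a["calibration_dose_rate"],
                        as_of_date=a["calibration_date"],
                    )
                )
        else:
            raise ConfigError(f"unknown element <{el.tag}> in configuration")

    try:
        tol = ToleranceConfig(reference_sources=references, **tol_kw)
        grid = GridSpec(**grid_kw) if grid_kw else GridSpec()
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
    return tol, grid


def write_config(tol: ToleranceConfig, grid: GridSpec) -> str:
    """Serialize a configuration to XML text (inverse of :func:`load_config`)."""
    root = ET.Element(_CONFIG_TAG, version="1")
    ET.SubElement(
        root,
        "tolerances",
        gantry_deg=repr(tol.gantry_deg),
        mlc_mm=repr(tol.mlc_mm),
        time_s=repr(tol.time_s),
    )
    ET.SubElement(
        root,
        "fluence",
        low_cut=repr(tol.fluence_low_cut),
        pass_frac=repr(tol.fluence_pass_frac),
        accept_rate=repr(tol.fluence_accept_rate),
    )
    ET.SubElement(
        root,
        "machine",
        nominal_dose_rate=repr(tol.nominal_dose_rate),
        half_life_years=repr(tol.half_life_years),
        source_rate_rel_tol=repr(tol.source_rate_rel_tol),
    )
    ET.SubElement(
        root,
        "grid",
        spacing=repr(grid.spacing),
        x_extent=repr(grid.x_extent),
        y_extent=repr(grid.y_extent),
        leaf_width=repr(grid.leaf_width),
    )
    sources_el = ET.SubElement(root, "sources")
    for src in tol.reference_sources:
        ET.SubElement(
            sources_el,
            "source",
            head=str(src.head_id),
            serial=src.serial,
            calibration_date=src.calibration_date.isoformat(),
            calibration_strength=repr(src.calibration_strength),
            calibration_dose_rate=repr(src.calibration_dose_rate),
        )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"
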