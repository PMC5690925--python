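"""Daily treatment-delivery report rendering.

One self-contained HTML document per fraction: plan and fraction
information, the IGRT setup screen captures, the full table of verification
results with failures highlighted, per-beam fluence statistics with the
planned / delivered / difference maps as embedded grayscale images, the
day's cobalt-60 source information and the overall verdict.  Styling comes
from an external CSS file (a default ships with the package) inlined at
render time so the archived document remains a single file.

Fluence images are scaled to the planned map's maximum; the difference
image is on a symmetric absolute scale, so a perfect delivery renders an
all-black difference map.  PDF export is optional at runtime and renders
the same content through matplotlib's PDF backend.
"""

from __future__ import annotations

import base64
import datetime
import html
import importlib.resources
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .checks import VerificationReportData
from .datamodel import DeliveryRecord, FluenceMap, Plan, ToleranceConfig

__all__ = ["ReportDocument", "render_report", "export_pdf"]


@dataclass
class ReportDocument:
    """A rendered report: the self-contained HTML plus the data it shows."""

    html: str
    plan: Plan
    record: DeliveryRecord
    verification: VerificationReportData
    generated_at: datetime.datetime
    capture_warnings: list[str] = field(default_factory=list)


def _default_css() -> str:
    return (
        importlib.resources.files("cobaltqa").joinpath("report.css").read_text("utf-8")
    )


def _png_data_uri(img: Image.Image) -> str:
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode("ascii")


def _gray_image(values: np.ndarray, scale: float) -> Image.Image:
    """Grayscale rendering of a non-negative map; ``scale`` maps to white."""
    if scale <= 0:
        scale = 1.0
    arr = np.clip(values / scale, 0.0, 1.0)
    # row 0 is most-negative y; display with +y up
    return Image.fromarray((arr[::-1, :] * 255).astype(np.uint8), mode="L")


def fluence_images(
    plan_map: FluenceMap, delivered_map: FluenceMap
) -> tuple[Image.Image, Image.Image, Image.Image]:
    """Planned, delivered and |difference| images on a common scale.

    Both fluence images are scaled to the planned map's maximum; the
    difference image uses the same symmetric scale, so zero difference is
    uniformly black.
    """
    peak = float(plan_map.values.max(initial=0.0))
    diff = np.abs(delivered_map.values - plan_map.values)
    return (
        _gray_image(plan_map.values, peak),
        _gray_image(delivered_map.values, peak),
        _gray_image(diff, peak),
    )


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def render_report(
    plan: Plan,
    record: DeliveryRecord,
    verification: VerificationReportData,
    captures: Sequence[Image.Image] = (),
    config: Optional[ToleranceConfig] = None,
    css_path: Optional[str] = None,
    capture_warnings: Sequence[str] = (),
    now: Optional[datetime.datetime] = None,
) -> ReportDocument:
    """Render the daily delivery report as one self-contained HTML document.

    Every verification result becomes exactly one table row; failed rows are
    highlighted, warnings marked.  Missing screen captures are noted inline
    and never abort rendering.
    """
    config = config or ToleranceConfig()
    now = now or datetime.datetime.now()
    if css_path is not None:
        with open(css_path, "r", encoding="utf-8") as fh:
            css = fh.read()
    else:
        css = _default_css()

    esc = html.escape
    out = io.StringIO()
    out.write("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>\n")
    out.write(f"<title>Delivery report — {esc(plan.plan_name)} "
              f"fraction {record.fraction_number}</title>\n")
    out.write(f"<style>\n{css}\n</style></head>\n<body>\n")

    verdict_cls = "verdict-pass" if verification.overall == "pass" else "verdict-fail"
    out.write("<h1>Daily treatment delivery report</h1>\n")
    out.write(
        f"<p class='{verdict_cls}'>Overall result: "
        f"<strong>{verification.overall.upper()}</strong> "
        f"({verification.n_pass} pass, {verification.n_fail} fail, "
        f"{verification.n_warn} warn)</p>\n"
    )
    out.write(f"<p class='meta'>Generated {esc(now.isoformat(timespec='seconds'))}</p>\n")

    out.write("<h2>Plan and fraction</h2>\n<table class='info'>\n")
    rx = plan.prescription
    for label, value in (
        ("Patient name", plan.patient.name),
        ("Patient ID", plan.patient.patient_id),
        ("Plan name", plan.plan_name),
        ("Plan date", plan.plan_date.isoformat()),
        ("Prescription", rx.prescription_name),
        ("Prescription dose", f"{rx.dose_per_fraction:g} Gy x {rx.n_fractions} fractions"),
        ("PTV target", rx.ptv_name),
        ("Fraction number", str(record.fraction_number)),
        ("Number of beams (planned)", str(len(plan.beams))),
        ("Nominal dose rate", f"{plan.nominal_dose_rate:g} Gy/min"),
    ):
        out.write(f"<tr><th>{esc(label)}</th><td>{esc(value)}</td></tr>\n")
    out.write("</table>\n")

    out.write("<h2>Image-guided setup captures</h2>\n")
    if captures:
        out.write("<div class='captures'>\n")
        for img in captures:
            out.write(f"<img src='{_png_data_uri(img)}' alt='IGRT setup capture'>\n")
        out.write("</div>\n")
    else:
        out.write("<p>No setup screen captures provided.</p>\n")
    for warning in capture_warnings:
        out.write(f"<p class='warn-note'>Note: {esc(warning)}</p>\n")

    out.write("<h2>Cobalt-60 source information</h2>\n<table class='sources'>\n")
    out.write(
        "<tr><th>Head</th><th>Serial</th><th>Calibration date</th>"
        "<th>Calibration strength (Ci)</th><th>Calibration rate (Gy/min)</th>"
        "<th>Decayed strength (Ci)</th><th>Decayed rate (Gy/min)</th>"
        "<th>As of</th></tr>\n"
    )
    for src in sorted(record.sources, key=lambda s: s.head_id):
        out.write(
            f"<tr><td>{src.head_id}</td><td>{esc(src.serial)}</td>"
            f"<td>{src.calibration_date.isoformat()}</td>"
            f"<td>{src.calibration_strength:.1f}</td>"
            f"<td>{src.calibration_dose_rate:.4f}</td>"
            f"<td>{src.decayed_strength:.1f}</td>"
            f"<td>{src.decayed_dose_rate:.4f}</td>"
            f"<td>{src.as_of_date.isoformat()}</td></tr>\n"
        )
    out.write("</table>\n")

    out.write("<h2>Verification results</h2>\n<table class='results'>\n")
    out.write(
        "<tr><th>Category</th><th>Item</th><th>Planned</th>"
        "<th>Delivered</th><th>Tolerance</th><th>Status</th></tr>\n"
    )
    for r in verification.results:
        cls = {"fail": "row-fail", "warn": "row-warn"}.get(r.status, "row-pass")
        out.write(
            f"<tr class='{cls}'><td>{esc(r.category)}</td><td>{esc(r.item)}</td>"
            f"<td>{esc(_fmt(r.planned_value))}</td><td>{esc(_fmt(r.delivered_value))}</td>"
            f"<td>{esc(_fmt(r.tolerance))}</td><td>{esc(r.status)}</td></tr>\n"
        )
    out.write("</table>\n")

    out.write("<h2>Per-beam fluence</h2>\n")
    for beam_id, stats in verification.per_beam_fluence.items():
        out.write(f"<h3>Beam {esc(beam_id)}</h3>\n")
        rate = "n/a" if stats.pass_rate is None else f"{stats.pass_rate:.1f}%"
        out.write(
            "<p>"
            f"Pass rate: <strong>{rate}</strong> over {stats.n_evaluated} pixels; "
            f"difference mean {stats.mean_diff:.3f} s, "
            f"max {stats.max_diff:.3f} s, SD {stats.sd_diff:.3f} s.</p>\n"
        )
        plan_map, delivered_map = verification.per_beam_maps[beam_id]
        imgs = fluence_images(plan_map, delivered_map)
        out.write("<div class='fluence-row'>\n")
        for label, img in zip(("Planned", "Delivered", "Difference"), imgs):
            out.write(
                "<figure>"
                f"<img src='{_png_data_uri(img)}' alt='{label} fluence map'>"
                f"<figcaption>{label}</figcaption></figure>\n"
            )
        out.write("</div>\n")

    out.write("</body></html>\n")
    return ReportDocument(
        html=out.getvalue(),
        plan=plan,
        record=record,
        verification=verification,
        generated_at=now,
        capture_warnings=list(capture_warnings),
    )


def export_pdf(document: ReportDocument, path: str) -> None:
    """Write a PDF rendering of the report to ``path``.

    Uses matplotlib's PDF backend: a summary page with the verdict and the
    verification table (failures highlighted), then one page per beam with
    the planned / delivered / difference fluence images.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    verification = document.verification
    rows = [
        (r.category, r.item, _fmt(r.planned_value), _fmt(r.delivered_value),
         _fmt(r.tolerance), r.status)
        for r in verification.results
    ]
    with PdfPages(path) as pdf:
        per_page = 28
        for start in range(0, len(rows), per_page):
            chunk = rows[start:start + per_page]
            fig, ax = plt.subplots(figsize=(8.27, 11.69))
            ax.axis("off")
            if start == 0:
                plan = document.plan
                ax.set_title(
                    f"Daily delivery report — {plan.plan_name} "
                    f"fraction {document.record.fraction_number}\n"
                    f"{plan.patient.name} ({plan.patient.patient_id}) — "
                    f"overall {verification.overall.upper()} "
                    f"({verification.n_fail} fail, {verification.n_warn} warn) — "
                    f"generated {document.generated_at.isoformat(timespec='seconds')}",
                    fontsize=9,
                )
            table = ax.table(
                cellText=[list(r[:6]) for r in chunk],
                colLabels=["Category", "Item", "Planned", "Delivered", "Tol.", "Status"],
                loc="upper center",
                cellLoc="left",
                colWidths=[0.10, 0.42, 0.14, 0.14, 0.10, 0.10],
            )
            table.auto_set_font_size(False)
            table.set_fontsize(6)
            for (row, _col), cell in table.get_celld().items():
                if row == 0:
                    continue
                status = chunk[row - 1][5]
                if status == "fail":
                    cell.set_facecolor("#ffd6d6")
                elif status == "warn":
                    cell.set_facecolor("#fff3c4")
            pdf.savefig(fig)
            plt.close(fig)

        for beam_id, (plan_map, delivered_map) in verification.per_beam_maps.items():
            imgs = fluence_images(plan_map, delivered_map)
            fig, axes = plt.subplots(1, 3, figsize=(8.27, 3.5))
            stats = verification.per_beam_fluence[beam_id]
            rate = "n/a" if stats.pass_rate is None else f"{stats.pass_rate:.1f}%"
            fig.suptitle(f"Beam {beam_id} — fluence pass rate {rate}", fontsize=10)
            for ax, label, img in zip(axes, ("Planned", "Delivered", "Difference"), imgs):
                ax.imshow(np.asarray(img), cmap="gray", vmin=0, vmax=255)
                ax.set_title(label, fontsize=8)
                ax.axis("off")
            pdf.savefig(fig)
            plt.close(fig)
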