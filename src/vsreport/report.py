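"""Summary and extended imaging-biomarker reports.

The summary report shows, per session: an axial snapshot at the displayed
diameter's slice with the segmentation overlay and the diameter endpoints
drawn, the displayed diameter value and the compartment volumes; below
them a stacked intra-/extrameatal volume bar chart and a diameter line
chart against months since the index scan.  Session-to-session change is
color coded red (growth), orange (equivocal) and green (no growth or
reduction); management decisions appear as markers with a guide at the
bottom.  The extended report adds the full measurement table, three
orthographic silhouette projections and an exported STL surface mesh per
session.

Report building is a pure function of previously computed measurements,
choices and assessments: nothing is re-measured here.  HTML is the
canonical output; PDF is a matplotlib rendering of the same content.
Given identical inputs and the same style version the outputs are
byte-stable (document metadata that would embed timestamps is stripped).
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vsreport.decision import DiameterChoice, GrowthAssessment
from vsreport.geometry import MEASUREMENT_COLUMNS, SessionMeasurements, measurements_row
from vsreport.mask_io import LabeledVolume, PatientTimeline

__all__ = [
    "STYLE_VERSION",
    "COLOR_MAP",
    "DECISION_MARKERS",
    "PanelSpec",
    "ReportSpec",
    "build_report_spec",
    "render_summary_report",
    "render_extended_report",
]

STYLE_VERSION = "1.0"

#: Growth status -> report color. Reductions are rendered green like
#: no-growth; the report uses exactly three colors.
COLOR_MAP = {
    "growth": "red",
    "equivocal": "orange",
    "no_growth": "green",
    "reduction": "green",
    "not_assessable": "green",
}

#: Marker glyphs for post-session management decisions (chart annotations).
DECISION_MARKERS = {
    "surveillance": "S",
    "SRS": "R",
    "surgery": "O",
    "discharge": "D",
}

_PNG_META = {"Software": None}  # strip version-bearing tEXt chunk
_PDF_META = {"Creator": None, "Producer": None, "CreationDate": None}

_INTRA_COLOR = "#d95f02"
_EXTRA_COLOR = "#1b9e77"


@dataclass
class PanelSpec:
    """Everything one per-session panel needs, resolved ahead of rendering."""

    date: str
    months: float
    status: str
    decision: str | None
    color: str
    diameter_label: str  # "DWT" or "DEM"
    diameter_mm: float
    v_intra: float
    v_extra: float
    v_whole: float
    suppress_volumes: bool
    display_slice: int | None
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None
    mask_slice: np.ndarray | None = None
    image_slice: np.ndarray | None = None
    spacing2: tuple[float, float] = (1.0, 1.0)


@dataclass
class ReportSpec:
    """Deterministic, render-ready description of one patient's report."""

    patient_id: str
    panels: list[PanelSpec]
    assessments: list[GrowthAssessment]
    style_version: str = STYLE_VERSION
    not_assessable: bool = False

    @property
    def months(self) -> list[float]:
        return [p.months for p in self.panels]


def build_report_spec(
    timeline: PatientTimeline,
    measurements: Sequence[SessionMeasurements],
    assessments: Sequence[GrowthAssessment],
    choices: Sequence[DiameterChoice],
    volumes: Sequence[LabeledVolume | None] | None = None,
    images: Sequence[np.ndarray | None] | None = None,
    suppress_single_slice: bool = True,
) -> ReportSpec:
    """Assemble the report description (pure; no re-measurement, no I/O).

    ``volumes`` optionally supplies the label volumes so the axial snapshot
    slices can be embedded; sessions without one render values only.
    Volumes are suppressed on panels whose tumor occupies at most one axial
    slice (volumetry is unreliable there); the toggle disables that rule.
    """
    n = len(timeline.sessions)
    if not (len(measurements) == len(choices) == n):
        raise ValueError("measurements and choices must match the session count")
    consecutive = [a for a in assessments if a.comparison == "consecutive"]

    panels: list[PanelSpec] = []
    for i, (sess, m, ch) in enumerate(zip(timeline.sessions, measurements, choices)):
        status = "not_assessable" if i == 0 else consecutive[i - 1].status
        diam = m.diameter_extra if ch.chosen == "DEM" else m.diameter_whole
        endpoints = None
        display_slice = None
        if diam is not None and diam.slice_index is not None:
            display_slice = diam.slice_index
            if diam.endpoint_a is not None:
                endpoints = (diam.endpoint_a, diam.endpoint_b)
        mask_slice = None
        spacing2 = (1.0, 1.0)
        if volumes is not None and volumes[i] is not None and display_slice is not None:
            mask_slice = np.array(volumes[i].labels[:, :, display_slice])
            spacing2 = volumes[i].spacing[:2]
        image_slice = None
        if images is not None and images[i] is not None and display_slice is not None:
            image_slice = np.array(images[i][:, :, display_slice])
        panels.append(
            PanelSpec(
                date=sess.session_date.isoformat(),
                months=round(sess.months_since_index, 2),
                status=sess.operative_status,
                decision=sess.decision_label,
                color=COLOR_MAP[status],
                diameter_label=ch.chosen,
                diameter_mm=ch.value,
                v_intra=m.v_intra,
                v_extra=m.v_extra,
                v_whole=m.v_whole,
                suppress_volumes=suppress_single_slice and m.n_axial_slices <= 1,
                display_slice=display_slice,
                endpoints=endpoints,
                mask_slice=mask_slice,
                image_slice=image_slice,
                spacing2=spacing2,
            )
        )
    return ReportSpec(
        patient_id=timeline.patient_id,
        panels=panels,
        assessments=list(assessments),
        not_assessable=(n < 2),
    )


# ---------------------------------------------------------------------------
# Chart rendering
# ---------------------------------------------------------------------------


def _save(fig, path: Path) -> None:
    fig.savefig(path, metadata=_PNG_META)
    plt.close(fig)


def _volume_bar_chart(spec: ReportSpec, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 2.6), dpi=110)
    xs = np.arange(len(spec.panels))
    intra = [0.0 if p.suppress_volumes else p.v_intra for p in spec.panels]
    extra = [0.0 if p.suppress_volumes else p.v_extra for p in spec.panels]
    ax.bar(xs, intra, width=0.6, color=_INTRA_COLOR, label="intrameatal")
    ax.bar(xs, extra, width=0.6, bottom=intra, color=_EXTRA_COLOR, label="extrameatal")
    ax.set_xticks(xs, [p.date for p in spec.panels], rotation=30, ha="right", fontsize=6)
    ax.set_ylabel("volume (cm$^3$)", fontsize=7)
    ax.legend(fontsize=6)
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    _save(fig, path)


def _diameter_line_chart(spec: ReportSpec, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 2.6), dpi=110)
    months = [p.months for p in spec.panels]
    dias = [p.diameter_mm for p in spec.panels]
    ax.plot(months, dias, "-", color="0.4", zorder=1)
    for p in spec.panels:
        ax.scatter([p.months], [p.diameter_mm], c=p.color, s=36, zorder=2)
        if p.decision:
            marker = DECISION_MARKERS.get(p.decision, "?")
            ax.annotate(
                marker,
                (p.months, p.diameter_mm),
                textcoords="offset points",
                xytext=(0, 8),
                ha="center",
                fontsize=7,
                fontweight="bold",
            )
    ax.set_xlabel("time since index scan (months)", fontsize=7)
    ax.set_ylabel("displayed diameter (mm)", fontsize=7)
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    _save(fig, path)


def _panel_snapshot(panel: PanelSpec, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(2.4, 2.4), dpi=110)
    sx, sy = panel.spacing2
    mask = panel.mask_slice
    extent = None
    if mask is not None:
        # pixel centers at i*sx, j*sy; imshow of mask.T puts x right, y up
        extent = (-0.5 * sx, (mask.shape[0] - 0.5) * sx, -0.5 * sy, (mask.shape[1] - 0.5) * sy)
    if panel.image_slice is not None:
        ax.imshow(
            panel.image_slice.T, cmap="gray", origin="lower", extent=extent, aspect="equal"
        )
    if mask is not None:
        overlay = np.zeros(mask.shape + (4,))
        overlay[mask == 1] = matplotlib.colors.to_rgba(_INTRA_COLOR, alpha=0.55)
        overlay[mask == 2] = matplotlib.colors.to_rgba(_EXTRA_COLOR, alpha=0.55)
        ax.imshow(np.transpose(overlay, (1, 0, 2)), origin="lower", extent=extent, aspect="equal")
    if panel.endpoints is not None:
        (xa, ya), (xb, yb) = panel.endpoints
        ax.plot([xa, xb], [ya, yb], "w-", lw=1.2)
        ax.plot([xa, xb], [ya, yb], "k--", lw=0.8)
    ax.set_axis_off()
    ax.set_title(f"{panel.date}  slice {panel.display_slice}", fontsize=6)
    fig.tight_layout()
    _save(fig, path)


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

_CSS = """
body { font-family: Helvetica, Arial, sans-serif; margin: 1.2em; color: #222; }
h1 { font-size: 1.2em; } h2 { font-size: 1.0em; }
table.panels td { text-align: center; vertical-align: top; padding: 0.4em;
                  border-top: 4px solid transparent; }
td.red { border-top-color: #d62728; } td.orange { border-top-color: #ff7f0e; }
td.green { border-top-color: #2ca02c; }
table.meas { border-collapse: collapse; font-size: 0.8em; }
table.meas th, table.meas td { border: 1px solid #999; padding: 0.25em 0.5em; }
.legend { font-size: 0.75em; color: #444; margin-top: 1em;
          border-top: 1px solid #ccc; padding-top: 0.5em; }
.suppressed { color: #888; font-style: italic; }
"""


def _panel_cell(panel: PanelSpec, snapshot_rel: str | None) -> str:
    lines = [f'<td class="{panel.color}">']
    lines.append(f"<b>{html.escape(panel.date)}</b><br/>")
    if snapshot_rel is not None:
        lines.append(f'<img src="{snapshot_rel}" width="180"/><br/>')
    lines.append(
        f"{panel.diameter_label} = {panel.diameter_mm:.1f} mm<br/>"
    )
    if panel.suppress_volumes:
        lines.append('<span class="suppressed">volumes not presented (&le;1 axial slice)</span><br/>')
    else:
        lines.append(
            f"V<sub>extra</sub> = {panel.v_extra:.2f} cm&sup3;, "
            f"V<sub>whole</sub> = {panel.v_whole:.2f} cm&sup3;<br/>"
        )
    lines.append(f"<small>{html.escape(panel.status)}</small>")
    lines.append("</td>")
    return "\n".join(lines)


def _legend_html() -> str:
    marks = ", ".join(
        f"<b>{glyph}</b> = {name}" for name, glyph in sorted(DECISION_MARKERS.items())
    )
    return (
        '<div class="legend">Change coding: '
        '<span style="color:#d62728">&#9632;</span> growth, '
        '<span style="color:#ff7f0e">&#9632;</span> equivocal growth, '
        '<span style="color:#2ca02c">&#9632;</span> no growth. '
        f"Decision markers: {marks}.</div>"
    )


def _headline_html(spec: ReportSpec) -> str:
    if spec.not_assessable:
        return "<p><i>Single session: longitudinal change not assessable.</i></p>"
    rows = []
    labels = {
        "index_vs_latest": "index &rarr; latest",
        "penultimate_vs_latest": "second most recent &rarr; latest",
    }
    for a in spec.assessments:
        if a.comparison in labels:
            trig = ", ".join(sorted(a.triggered_by)) or "&ndash;"
            pct = "&ndash;" if a.delta_v_pct is None else f"{a.delta_v_pct:+.1f}%"
            flag = " (diameter basis switched)" if a.diameter_basis_switched else ""
            rows.append(
                f"<tr><td>{labels[a.comparison]}</td>"
                f'<td style="color:{COLOR_MAP[a.status]}"><b>{a.status}</b>{flag}</td>'
                f"<td>{a.delta_d_mm:+.1f} mm</td><td>{a.delta_v_cm3:+.2f} cm&sup3;</td>"
                f"<td>{pct}</td><td>{trig}</td></tr>"
            )
    return (
        '<table class="meas"><tr><th>comparison</th><th>status</th>'
        "<th>&Delta;D</th><th>&Delta;V</th><th>&Delta;V%</th><th>criteria</th></tr>"
        + "".join(rows)
        + "</table>"
    )


def render_summary_report(
    spec: ReportSpec, out: str | Path, format: str = "html"
) -> Path:
    """Render the one-page summary report (HTML canonical, PDF derived).

    Chart and snapshot PNGs are written to ``<stem>_assets/`` beside the
    output file and referenced relatively, so the document is relocatable
    with its directory.  Output bytes depend only on the spec and the
    style version.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    if format not in ("html", "pdf"):
        raise ValueError(f"format must be html or pdf, got {format!r}")
    if format == "pdf":
        return _render_summary_pdf(spec, out)

    assets = out.parent / f"{out.stem}_assets"
    assets.mkdir(exist_ok=True)
    _volume_bar_chart(spec, assets / "volumes.png")
    _diameter_line_chart(spec, assets / "diameters.png")
    cells = []
    for i, panel in enumerate(spec.panels):
        rel = None
        if panel.mask_slice is not None:
            name = f"snapshot_{i:02d}.png"
            _panel_snapshot(panel, assets / name)
            rel = f"{assets.name}/{name}"
        cells.append(_panel_cell(panel, rel))

    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>VS imaging biomarker summary &mdash; {html.escape(spec.patient_id)}</title>
<style>{_CSS}</style></head>
<body>
<h1>Vestibular schwannoma imaging biomarker summary</h1>
<p>Patient <b>{html.escape(spec.patient_id)}</b> &middot; {len(spec.panels)} session(s)
&middot; style v{spec.style_version}</p>
<table class="panels"><tr>
{"".join(cells)}
</tr></table>
<h2>Longitudinal change</h2>
{_headline_html(spec)}
<table><tr>
<td><img src="{assets.name}/volumes.png" width="380"/></td>
<td><img src="{assets.name}/diameters.png" width="380"/></td>
</tr></table>
{_legend_html()}
</body></html>
"""
    out.write_text(doc, encoding="utf-8")
    return out


def _render_summary_pdf(spec: ReportSpec, out: Path) -> Path:
    n = len(spec.panels)
    fig = plt.figure(figsize=(8.3, 5.8 + 1.2 * (n > 3)), dpi=110)
    fig.suptitle(
        f"VS imaging biomarker summary — {spec.patient_id} (style v{spec.style_version})",
        fontsize=10,
    )
    for i, panel in enumerate(spec.panels):
        ax = fig.add_subplot(2, max(n, 2), i + 1)
        if panel.mask_slice is not None:
            sx, sy = panel.spacing2
            m = panel.mask_slice
            extent = (-0.5 * sx, (m.shape[0] - 0.5) * sx, -0.5 * sy, (m.shape[1] - 0.5) * sy)
            overlay = np.zeros(m.shape + (4,))
            overlay[m == 1] = matplotlib.colors.to_rgba(_INTRA_COLOR, alpha=0.8)
            overlay[m == 2] = matplotlib.colors.to_rgba(_EXTRA_COLOR, alpha=0.8)
            ax.imshow(np.transpose(overlay, (1, 0, 2)), origin="lower", extent=extent)
            if panel.endpoints is not None:
                (xa, ya), (xb, yb) = panel.endpoints
                ax.plot([xa, xb], [ya, yb], "k--", lw=0.8)
        ax.set_axis_off()
        vol_txt = (
            "volumes n/a"
            if panel.suppress_volumes
            else f"V={panel.v_whole:.2f} cm³"
        )
        ax.set_title(
            f"{panel.date}\n{panel.diameter_label}={panel.diameter_mm:.1f} mm, {vol_txt}",
            fontsize=6,
            color=panel.color,
        )
    axv = fig.add_subplot(2, 2, 3)
    xs = np.arange(n)
    intra = [0.0 if p.suppress_volumes else p.v_intra for p in spec.panels]
    extra = [0.0 if p.suppress_volumes else p.v_extra for p in spec.panels]
    axv.bar(xs, intra, width=0.6, color=_INTRA_COLOR, label="intrameatal")
    axv.bar(xs, extra, width=0.6, bottom=intra, color=_EXTRA_COLOR, label="extrameatal")
    axv.set_xticks(xs, [p.date for p in spec.panels], rotation=30, fontsize=5)
    axv.set_ylabel("volume (cm³)", fontsize=7)
    axv.legend(fontsize=5)
    axd = fig.add_subplot(2, 2, 4)
    axd.plot([p.months for p in spec.panels], [p.diameter_mm for p in spec.panels], "-", color="0.4")
    for p in spec.panels:
        axd.scatter([p.months], [p.diameter_mm], c=p.color, s=30)
    axd.set_xlabel("months since index", fontsize=7)
    axd.set_ylabel("diameter (mm)", fontsize=7)
    fig.subplots_adjust(left=0.08, right=0.97, bottom=0.12, top=0.82, hspace=0.5, wspace=0.35)
    fig.savefig(out, metadata=_PDF_META)
    plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# Extended report
# ---------------------------------------------------------------------------


def _orthographic_projections(vol: LabeledVolume, path: Path) -> None:
    """Three silhouette projections (axial, coronal, sagittal views)."""
    fg = vol.labels > 0
    fig, axes = plt.subplots(1, 3, figsize=(6.0, 2.2), dpi=110)
    views = [
        (fg.any(axis=2), (vol.spacing[0], vol.spacing[1]), "axial"),
        (fg.any(axis=1), (vol.spacing[0], vol.spacing[2]), "coronal"),
        (fg.any(axis=0), (vol.spacing[1], vol.spacing[2]), "sagittal"),
    ]
    for ax, (proj, (sa, sb), name) in zip(axes, views):
        ax.imshow(
            proj.T,
            origin="lower",
            cmap="gray_r",
            aspect=sb / sa,
            interpolation="nearest",
        )
        ax.set_title(name, fontsize=7)
        ax.set_axis_off()
    fig.tight_layout()
    _save(fig, path)


def export_surface_mesh(vol: LabeledVolume, path: Path):
    """Marching-cubes surface of the whole tumor, written as STL (mm units)."""
    import trimesh
    from skimage import measure

    fg = np.pad((vol.labels > 0).astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(fg, level=0.5, spacing=vol.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:  # marching-cubes winding can point inward
        mesh.invert()
    mesh.export(path)
    return mesh


def render_extended_report(
    timeline: PatientTimeline,
    measurements: Sequence[SessionMeasurements],
    out: str | Path,
    volumes: Sequence[LabeledVolume | None] | None = None,
) -> Path:
    """Render the extended report: full measurement table + 3D visualization.

    For every session the complete measurement row is tabulated; when the
    label volume is available three orthographic silhouettes are drawn and
    the tumor surface is exported as an STL mesh into the assets directory.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    assets = out.parent / f"{out.stem}_assets"
    assets.mkdir(exist_ok=True)

    header = "".join(f"<th>{c}</th>" for c in MEASUREMENT_COLUMNS)
    body_rows = []
    extras = []
    for i, (sess, m) in enumerate(zip(timeline.sessions, measurements)):
        row = measurements_row(sess, m)
        body_rows.append(
            "<tr>" + "".join(f"<td>{html.escape(str(row[c]))}</td>" for c in MEASUREMENT_COLUMNS) + "</tr>"
        )
        if volumes is not None and volumes[i] is not None and (volumes[i].labels > 0).any():
            proj_name = f"projections_{i:02d}.png"
            mesh_name = f"surface_{i:02d}.stl"
            _orthographic_projections(volumes[i], assets / proj_name)
            export_surface_mesh(volumes[i], assets / mesh_name)
            extras.append(
                f"<h2>Session {html.escape(sess.session_date.isoformat())}</h2>"
                f'<img src="{assets.name}/{proj_name}" width="520"/>'
                f'<p><a href="{assets.name}/{mesh_name}">surface mesh (STL)</a></p>'
            )

    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>VS imaging biomarker extended report &mdash; {html.escape(timeline.patient_id)}</title>
<style>{_CSS}</style></head>
<body>
<h1>Extended report — patient {html.escape(timeline.patient_id)}</h1>
<p>Diameters in mm, volumes in cm&sup3;; blank cells are undefined for the
session (entirely intrameatal tumor or indeterminate meatal axis).</p>
<table class="meas"><tr>{header}</tr>
{"".join(body_rows)}
</table>
{"".join(extras)}
</body></html>
"""
    out.write_text(doc, encoding="utf-8")
    return out
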