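"""Displayed-diameter selection and EAONO growth classification.

One diameter is shown per session.  Operated (postoperative / post-SRS)
tumors always display the whole-tumor maximum diameter D_WT.  Preoperative
tumors display D_WT when entirely intrameatal; otherwise the canal-geometry
rule applies: if the intrameatal extent along the porus-plane trace is at
least the extrameatal one, D_WT; else the extrameatal diameter D_EM when
the extrameatal protrusion perpendicular to the trace exceeds 2 mm, and
D_WT when it does not.

Growth between two sessions is significant when the displayed diameter
increases by more than 2 mm, or whole-tumor volume by more than 1.2 cm^3
or more than 20% (strict inequalities).  Mirrored decreases classify as
reduction.  Changes past a configurable fraction of a threshold (default
one half) but not past the threshold classify as equivocal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from vsreport.geometry import SessionMeasurements
from vsreport.mask_io import PatientTimeline

__all__ = [
    "Thresholds",
    "DiameterChoice",
    "GrowthAssessment",
    "select_display_diameter",
    "assess_growth",
    "assess_timeline",
    "ASSESSMENT_COLUMNS",
    "assessment_row",
]

Branch = Literal[
    "postoperative",
    "entirely_intrameatal",
    "intra_dominant",
    "extra_perp_gt2",
    "extra_perp_le2",
    "axis_unavailable",
]
Status = Literal["growth", "equivocal", "no_growth", "reduction", "not_assessable"]
Comparison = Literal["index_vs_latest", "penultimate_vs_latest", "consecutive"]

#: Protrusion cutoff (mm) in the selection rule's perpendicular branch.
PERP_PROTRUSION_MM = 2.0


@dataclass(frozen=True)
class Thresholds:
    """Significant-growth criteria and the equivocal band.

    diameter_mm / volume_cm3 / volume_pct are the EAONO cutoffs (a change
    must strictly exceed one of them to count as growth).  A change whose
    magnitude exceeds ``equivocal_fraction`` times a cutoff without any
    cutoff being exceeded is equivocal.
    """

    diameter_mm: float = 2.0
    volume_cm3: float = 1.2
    volume_pct: float = 20.0
    equivocal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.diameter_mm, self.volume_cm3, self.volume_pct) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.equivocal_fraction < 1:
            raise ValueError("equivocal_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DiameterChoice:
    """Which diameter a session displays and why."""

    chosen: Literal["DWT", "DEM"]
    value: float
    branch: Branch
    axis_available: bool = True


@dataclass(frozen=True)
class GrowthAssessment:
    """Categorical change between two sessions with the triggering criteria."""

    status: Status
    delta_d_mm: float | None
    delta_v_cm3: float | None
    delta_v_pct: float | None
    triggered_by: frozenset[str]
    comparison: Comparison
    diameter_basis_switched: bool = False


def select_display_diameter(
    m: SessionMeasurements, status: str, perp_cutoff_mm: float = PERP_PROTRUSION_MM
) -> DiameterChoice:
    """Choose D_WT or D_EM for display (total, deterministic).

    Postoperative and post-SRS sessions always display D_WT.  Preoperative
    sessions display D_WT when entirely intrameatal, otherwise the
    three-way rule on (d_intra_par, d_extra_par, d_extra_perp).  When the
    meatal axis could not be determined despite an extrameatal compartment,
    the choice falls back to D_WT with ``axis_available=False``.
    """
    if status in ("postoperative", "post-SRS"):
        return DiameterChoice("DWT", m.d_wt, "postoperative")
    if m.entirely_intrameatal or m.v_extra == 0.0:
        return DiameterChoice("DWT", m.d_wt, "entirely_intrameatal")
    if m.d_intra_par is None or m.d_extra_par is None or m.d_extra_perp is None:
        return DiameterChoice("DWT", m.d_wt, "axis_unavailable", axis_available=False)
    if m.d_intra_par >= m.d_extra_par:
        return DiameterChoice("DWT", m.d_wt, "intra_dominant")
    if m.d_extra_perp > perp_cutoff_mm:
        assert m.d_em is not None
        return DiameterChoice("DEM", m.d_em, "extra_perp_gt2")
    return DiameterChoice("DWT", m.d_wt, "extra_perp_le2")


def _criteria(
    dd: float, dv: float, dpct: float | None, th: Thresholds, sign: int
) -> frozenset[str]:
    hits = set()
    if sign * dd > th.diameter_mm:
        hits.add("diameter")
    if sign * dv > th.volume_cm3:
        hits.add("volume_abs")
    if dpct is not None and sign * dpct > th.volume_pct:
        hits.add("volume_pct")
    return frozenset(hits)


def assess_growth(
    baseline: SessionMeasurements,
    baseline_choice: DiameterChoice,
    follow: SessionMeasurements,
    follow_choice: DiameterChoice,
    th: Thresholds = Thresholds(),
    comparison: Comparison = "consecutive",
) -> GrowthAssessment:
    """Classify the change between two measured sessions.

    The diameter delta is taken on the displayed diameter; if the displayed
    type differs between the sessions (e.g. DEM then DWT) the delta is
    computed on D_WT for both and the assessment is flagged, keeping the
    serial dimensions comparable.  The volume delta always uses whole-tumor
    volume.  The percentage criterion is undefined for a zero baseline
    volume.
    """
    switched = baseline_choice.chosen != follow_choice.chosen
    if switched:
        dd = follow.d_wt - baseline.d_wt
    else:
        dd = follow_choice.value - baseline_choice.value
    dv = follow.v_whole - baseline.v_whole
    dpct = 100.0 * dv / baseline.v_whole if baseline.v_whole > 0 else None

    grow = _criteria(dd, dv, dpct, th, +1)
    shrink = _criteria(dd, dv, dpct, th, -1)
    if grow and not shrink:
        status: Status = "growth"
        triggered = grow
    elif shrink and not grow:
        status = "reduction"
        triggered = shrink
    else:
        triggered = frozenset()
        if grow and shrink:  # conflicting directions, e.g. diameter up, volume down
            status = "equivocal"
        else:
            f = th.equivocal_fraction
            near = (
                abs(dd) > f * th.diameter_mm
                or abs(dv) > f * th.volume_cm3
                or (dpct is not None and abs(dpct) > f * th.volume_pct)
            )
            status = "equivocal" if near else "no_growth"
    return GrowthAssessment(
        status=status,
        delta_d_mm=dd,
        delta_v_cm3=dv,
        delta_v_pct=dpct,
        triggered_by=triggered,
        comparison=comparison,
        diameter_basis_switched=switched,
    )


def assess_timeline(
    timeline: PatientTimeline,
    measurements: Sequence[SessionMeasurements],
    choices: Sequence[DiameterChoice] | None = None,
    th: Thresholds = Thresholds(),
) -> list[GrowthAssessment]:
    """All assessments of one timeline.

    Returns the consecutive-pair assessments (one per session transition,
    used for per-session report coloring) followed by the two headline
    comparisons: index vs latest and second-most-recent vs latest.  With a
    single session the list holds one ``not_assessable`` entry; with
    exactly two sessions the headline comparisons coincide numerically.
    """
    n = len(timeline.sessions)
    if len(measurements) != n:
        raise ValueError("one SessionMeasurements per session required")
    if choices is None:
        choices = [
            select_display_diameter(m, s.operative_status)
            for m, s in zip(measurements, timeline.sessions)
        ]
    if n < 2:
        return [
            GrowthAssessment(
                status="not_assessable",
                delta_d_mm=None,
                delta_v_cm3=None,
                delta_v_pct=None,
                triggered_by=frozenset(),
                comparison="index_vs_latest",
            )
        ]
    out = [
        assess_growth(measurements[i], choices[i], measurements[i + 1], choices[i + 1], th)
        for i in range(n - 1)
    ]
    out.append(
        assess_growth(
            measurements[0], choices[0], measurements[-1], choices[-1], th,
            comparison="index_vs_latest",
        )
    )
    out.append(
        assess_growth(
            measurements[-2], choices[-2], measurements[-1], choices[-1], th,
            comparison="penultimate_vs_latest",
        )
    )
    return out


ASSESSMENT_COLUMNS = [
    "patient_id",
    "comparison",
    "baseline_date",
    "follow_date",
    "status",
    "delta_d_mm",
    "delta_v_cm3",
    "delta_v_pct",
    "triggered_by",
    "diameter_basis_switched",
]


def assessment_row(patient_id, baseline_date, follow_date, a: GrowthAssessment) -> dict:
    def fmt(x):
        return "" if x is None else round(x, 4)

    return {
        "patient_id": patient_id,
        "comparison": a.comparison,
        "baseline_date": baseline_date,
        "follow_date": follow_date,
        "status": a.status,
        "delta_d_mm": fmt(a.delta_d_mm),
        "delta_v_cm3": fmt(a.delta_v_cm3),
        "delta_v_pct": fmt(a.delta_v_pct),
        "triggered_by": "|".join(sorted(a.triggered_by)),
        "diameter_basis_switched": a.diameter_basis_switched,
    }


# kept for callers that tweak a single threshold
def with_thresholds(th: Thresholds, **kwargs) -> Thresholds:
    return replace(th, **kwargs)
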