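"""Shared fixtures: small, fast phantom datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from vsreport import (
    LabeledVolume,
    clean_mask,
    measure_session,
    read_labeled_volume,
    read_timeline_manifest,
    select_display_diameter,
)
from vsreport.decision import assess_timeline
from vsreport.geometry import SessionMeasurements
from vsreport.phantom import PhantomParams, make_phantom_timeline


def make_measurements(
    d_wt: float,
    v_whole: float,
    d_em: float | None = None,
    v_extra: float | None = None,
    d_intra_par: float | None = None,
    d_extra_par: float | None = None,
    d_extra_perp: float | None = None,
    n_axial_slices: int = 10,
) -> SessionMeasurements:
    """Hand-built measurement record for classifier-level tests."""
    if v_extra is None:
        v_extra = 0.0 if d_em is None else v_whole / 2
    return SessionMeasurements(
        d_wt=d_wt,
        d_em=d_em,
        d_intra_par=d_intra_par,
        d_extra_par=d_extra_par,
        d_extra_perp=d_extra_perp,
        v_intra=v_whole - v_extra,
        v_extra=v_extra,
        v_whole=v_whole,
        n_axial_slices=n_axial_slices,
        reference_slice=5,
        entirely_intrameatal=(v_extra == 0.0),
    )


def volume_from_labels(labels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LabeledVolume:
    return LabeledVolume(np.asarray(labels, dtype=np.int16), spacing)


#: Coarse but fully featured phantom for pipeline-level tests (fast).
COARSE_PARAMS = PhantomParams(spacing=0.8, canal_angle_deg=30.0)

TIMELINE_DATES = ["2011-01-01", "2012-01-01", "2013-01-01"]


@pytest.fixture(scope="session")
def phantom_timeline_dir(tmp_path_factory):
    """A 3-session growing phantom series on disk (1.0, 1.1, 1.3 scale)."""
    out = tmp_path_factory.mktemp("phantom_series")
    manifest, truths = make_phantom_timeline(
        COARSE_PARAMS,
        [1.0, 1.1, 1.3],
        TIMELINE_DATES,
        out,
        decisions=["surveillance", "surveillance", "SRS"],
    )
    return manifest, truths


@pytest.fixture(scope="session")
def measured_timeline(phantom_timeline_dir):
    """(timeline, volumes, measurements, choices, assessments) of the series."""
    manifest, _ = phantom_timeline_dir
    timeline = read_timeline_manifest(manifest)[0]
    volumes = [clean_mask(read_labeled_volume(s.mask_path)) for s in timeline.sessions]
    measurements = [measure_session(v) for v in volumes]
    choices = [
        select_display_diameter(m, s.operative_status)
        for m, s in zip(measurements, timeline.sessions)
    ]
    assessments = assess_timeline(timeline, measurements, choices)
    return timeline, volumes, measurements, choices, assessments
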