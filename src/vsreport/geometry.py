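"""Linear and volumetric tumor measurements from a label volume.

All diameters are maximum in-plane (axial) measurements: for each axial
slice the maximum Euclidean distance between foreground pixel centers is
found via convex hull + rotating calipers, and the slice with the largest
value defines the measurement (ties break to the smallest slice index).
Distances use the pixel-center convention — no half-pixel padding — so a
single pixel has diameter zero.

The meatal axis is estimated from the porus interface: extrameatal voxels
6-adjacent to an intrameatal voxel.  Their in-plane coordinates, pooled
over all axial slices, are fit by their principal direction; ``u_par`` runs
along the porus-plane trace (ridge-parallel) and ``u_perp`` orthogonal to
it, pointing along the canal.  Directional extents d(intra,par),
d(extra,par) and d(extra,perp) are pixel-center projection ranges on the
reference axial slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from vsreport.mask_io import LabeledVolume

__all__ = [
    "InPlaneDiameter",
    "MeatalAxis",
    "SessionMeasurements",
    "clean_mask",
    "inplane_diameter",
    "max_diameter",
    "meatal_axis",
    "directional_extents",
    "region_volumes",
    "measure_session",
    "measurements_row",
    "MEASUREMENT_COLUMNS",
]

REGION_LABELS = {"whole": (1, 2), "intrameatal": (1,), "extrameatal": (2,)}


@dataclass(frozen=True)
class InPlaneDiameter:
    """Maximum in-plane diameter on one axial slice.

    ``length`` is in mm; endpoints are in-plane physical coordinates (mm)
    of the two pixel centers realizing it.  An empty region has length 0
    with undefined (None) slice and endpoints.
    """

    length: float
    slice_index: int | None
    endpoint_a: tuple[float, float] | None
    endpoint_b: tuple[float, float] | None


@dataclass(frozen=True)
class MeatalAxis:
    """Principal in-plane frame of the intra/extrameatal interface."""

    u_par: tuple[float, float]
    u_perp: tuple[float, float]
    n_interface_voxels: int


@dataclass
class SessionMeasurements:
    """Every per-session scalar the pipeline reports.

    Diameters in mm, volumes in cm^3.  ``None`` encodes "undefined": D_EM
    and the directional extents are undefined for an entirely intrameatal
    tumor, and the extents additionally require a defined meatal axis.
    """

    d_wt: float
    d_em: float | None
    d_intra_par: float | None
    d_extra_par: float | None
    d_extra_perp: float | None
    v_intra: float
    v_extra: float
    v_whole: float
    n_axial_slices: int
    reference_slice: int | None
    entirely_intrameatal: bool
    diameter_whole: InPlaneDiameter | None = None
    diameter_extra: InPlaneDiameter | None = None
    axis: MeatalAxis | None = None


# ---------------------------------------------------------------------------
# Mask cleaning
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def clean_mask(vol: LabeledVolume, min_voxels: int = 5) -> LabeledVolume:
    """Keep the largest 26-connected whole-tumor component.

    Components (of the label>0 mask) smaller than ``min_voxels`` are always
    removed; of the remainder only the largest survives, labels preserved
    within it.  Equal-size ties break to the component with the smaller
    lexicographic centroid.  An empty mask passes through unchanged.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    fg = vol.labels > 0
    if not fg.any():
        return LabeledVolume(vol.labels.copy(), vol.spacing)
    comp, n = ndimage.label(fg, structure=_STRUCT_26)
    sizes = np.bincount(comp.ravel())[1:]  # component ids 1..n
    eligible = [i + 1 for i in range(n) if sizes[i] >= max(min_voxels, 1)]
    if not eligible:
        return LabeledVolume(np.zeros_like(vol.labels), vol.spacing)
    best_size = max(sizes[i - 1] for i in eligible)
    tied = [i for i in eligible if sizes[i - 1] == best_size]
    if len(tied) == 1:
        keep = tied[0]
    else:
        centroids = ndimage.center_of_mass(fg, comp, tied)
        keep = tied[int(np.lexsort(np.asarray(centroids).T[::-1])[0])]
    out = np.where(comp == keep, vol.labels, 0).astype(vol.labels.dtype)
    return LabeledVolume(out, vol.spacing)


# ---------------------------------------------------------------------------
# In-plane diameter: convex hull + rotating calipers
# ---------------------------------------------------------------------------


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain; returns CCW hull vertices (collinear dropped)."""
    pts = np.unique(points, axis=0)  # sorts lexicographically
    if len(pts) <= 2:
        return pts

    def half(iterable):
        chain: list[np.ndarray] = []
        for p in iterable:
            while len(chain) >= 2:
                o, a = chain[-2], chain[-1]
                if (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0]) <= 0:
                    chain.pop()
                else:
                    break
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    return np.asarray(lower[:-1] + upper[:-1])


def _dist2(a, b) -> float:
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    return dx * dx + dy * dy


def _hull_diameter(hull: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Rotating calipers over a CCW convex polygon; exact antipodal search.

    Comparisons run on squared distances; the square root is taken once at
    the end, so the result is bit-identical to a brute-force maximum that
    does the same.
    """
    m = len(hull)
    if m == 1:
        return 0.0, hull[0], hull[0]
    if m == 2:
        return math.sqrt(_dist2(hull[0], hull[1])), hull[0], hull[1]

    def area2(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    best = -1.0
    pa = pb = hull[0]
    j = 1
    for i in range(m):
        ni = (i + 1) % m
        while area2(hull[i], hull[ni], hull[(j + 1) % m]) > area2(hull[i], hull[ni], hull[j]):
            j = (j + 1) % m
        for a, b in ((i, j), (ni, j), (i, (j + 1) % m)):
            d2 = _dist2(hull[a], hull[b])
            if d2 > best:
                best, pa, pb = d2, hull[a], hull[b]
    return math.sqrt(best), pa, pb


def inplane_diameter(
    slice_mask: np.ndarray, spacing: tuple[float, float], slice_index: int | None = None
) -> InPlaneDiameter:
    """Maximum distance (mm) between foreground pixel centers of one slice.

    Computed as convex hull of the spacing-scaled pixel-center coordinates
    followed by rotating calipers; equals the brute-force maximum over all
    pixel pairs.  Empty mask or single pixel -> length 0.
    """
    mask = np.asarray(slice_mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return InPlaneDiameter(0.0, None, None, None)
    pts = idx.astype(float) * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        p = tuple(map(float, pts[0]))
        return InPlaneDiameter(0.0, slice_index, p, p)
    hull = _convex_hull(pts)
    length, pa, pb = _hull_diameter(hull)
    return InPlaneDiameter(
        float(length), slice_index, tuple(map(float, pa)), tuple(map(float, pb))
    )


def max_diameter(vol: LabeledVolume, region: str = "whole") -> InPlaneDiameter:
    """Maximum in-plane diameter of a region over all axial slices.

    ``region`` is one of whole / intrameatal / extrameatal.  Ties between
    slices break to the smallest slice index; an empty region gives 0 mm
    with undefined slice.
    """
    labels = REGION_LABELS[region]
    mask = np.isin(vol.labels, labels)
    sp2 = vol.spacing[:2]
    best = InPlaneDiameter(0.0, None, None, None)
    for z in range(vol.labels.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        d = inplane_diameter(sl, sp2, slice_index=z)
        if best.slice_index is None or d.length > best.length:
            best = d
    return best


# ---------------------------------------------------------------------------
# Meatal axis and directional extents
# ---------------------------------------------------------------------------

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _interface_mask(labels: np.ndarray) -> np.ndarray:
    """Extrameatal voxels 6-adjacent to an intrameatal voxel."""
    intra = labels == 1
    if not intra.any():
        return np.zeros_like(intra)
    near_intra = ndimage.binary_dilation(intra, structure=_STRUCT_6)
    return (labels == 2) & near_intra


def meatal_axis(vol: LabeledVolume) -> MeatalAxis | None:
    """Fit the porus interface by its in-plane principal direction.

    Interface voxel in-plane coordinates (pooled over axial slices) are
    decomposed by the eigenvectors of their 2x2 covariance; ``u_par`` is the
    dominant direction (along the porus-plane trace), ``u_perp`` orthogonal.
    Returns None for fewer than 2 interface voxels or an isotropic
    covariance (within 1e-9).
    """
    iface = _interface_mask(vol.labels)
    idx = np.argwhere(iface)
    n = len(idx)
    if n < 2:
        return None
    pts = idx[:, :2].astype(float) * np.asarray(vol.spacing[:2])
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) <= 1e-9:
        return None
    u = evecs[:, 1]  # eigh sorts ascending; dominant direction last
    # deterministic sign: first nonzero component positive
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    u_par = (float(u[0]), float(u[1]))
    u_perp = (-u_par[1], u_par[0])
    return MeatalAxis(u_par=u_par, u_perp=u_perp, n_interface_voxels=n)


def _projection_range(idx2d: np.ndarray, spacing2: np.ndarray, direction) -> float:
    if len(idx2d) == 0:
        return 0.0
    pts = idx2d.astype(float) * spacing2
    proj = pts @ np.asarray(direction, dtype=float)
    return float(proj.max() - proj.min())


def directional_extents(
    vol: LabeledVolume, axis: MeatalAxis, reference_slice: int | None = None
) -> tuple[float, float, float]:
    """(d_intra_par, d_extra_par, d_extra_perp) in mm on the reference slice.

    The reference slice is the slice of the whole-tumor maximum diameter
    (computed here when not supplied).  If a compartment is absent on it,
    that compartment falls back to the axial slice with the most interface
    voxels.  Extents are max-min of pixel-center projections onto ``u_par``
    (parallel) or ``u_perp`` (perpendicular); an absent compartment gives 0.
    """
    if axis is None:
        raise ValueError("no meatal axis")
    if reference_slice is None:
        reference_slice = max_diameter(vol, "whole").slice_index
    if reference_slice is None:
        return (0.0, 0.0, 0.0)
    iface = _interface_mask(vol.labels)
    iface_counts = iface.sum(axis=(0, 1))
    fallback = int(np.argmax(iface_counts)) if iface_counts.any() else None
    sp2 = np.asarray(vol.spacing[:2])

    def compartment_idx(label: int) -> np.ndarray:
        sl = vol.labels[:, :, reference_slice] == label
        if not sl.any() and fallback is not None:
            sl = vol.labels[:, :, fallback] == label
        return np.argwhere(sl)

    intra = compartment_idx(1)
    extra = compartment_idx(2)
    return (
        _projection_range(intra, sp2, axis.u_par),
        _projection_range(extra, sp2, axis.u_par),
        _projection_range(extra, sp2, axis.u_perp),
    )


# ---------------------------------------------------------------------------
# Volumes and the aggregate measurement
# ---------------------------------------------------------------------------


def region_volumes(vol: LabeledVolume) -> tuple[float, float, float]:
    """(V_intra, V_extra, V_whole) in cm^3; V_whole = V_intra + V_extra exactly."""
    n_intra = int(np.count_nonzero(vol.labels == 1))
    n_extra = int(np.count_nonzero(vol.labels == 2))
    vox_cm3 = vol.voxel_volume_mm3 / 1000.0
    return (n_intra * vox_cm3, n_extra * vox_cm3, (n_intra + n_extra) * vox_cm3)


def measure_session(vol: LabeledVolume) -> SessionMeasurements:
    """Compute every per-session measurement from a cleaned, canonical volume."""
    v_intra, v_extra, v_whole = region_volumes(vol)
    d_whole = max_diameter(vol, "whole")
    n_slices = int(np.count_nonzero((vol.labels > 0).any(axis=(0, 1))))
    entirely_intrameatal = v_extra == 0.0  # vacuously true for an empty mask

    d_extra = None
    d_em = None
    axis = None
    extents: tuple[float | None, float | None, float | None] = (None, None, None)
    if v_extra > 0:
        d_extra = max_diameter(vol, "extrameatal")
        d_em = d_extra.length
        axis = meatal_axis(vol)
        if axis is not None:
            extents = directional_extents(vol, axis, reference_slice=d_whole.slice_index)

    return SessionMeasurements(
        d_wt=d_whole.length,
        d_em=d_em,
        d_intra_par=extents[0],
        d_extra_par=extents[1],
        d_extra_perp=extents[2],
        v_intra=v_intra,
        v_extra=v_extra,
        v_whole=v_whole,
        n_axial_slices=n_slices,
        reference_slice=d_whole.slice_index,
        entirely_intrameatal=entirely_intrameatal,
        diameter_whole=d_whole,
        diameter_extra=d_extra,
        axis=axis,
    )


#: Column order of the flat per-session CSV (diameters mm, volumes cm^3).
MEASUREMENT_COLUMNS = [
    "patient_id",
    "date",
    "months_since_index",
    "status",
    "d_wt_mm",
    "d_em_mm",
    "d_intra_par_mm",
    "d_extra_par_mm",
    "d_extra_perp_mm",
    "v_intra_cm3",
    "v_extra_cm3",
    "v_whole_cm3",
    "n_axial_slices",
    "reference_slice",
    "entirely_intrameatal",
]


def measurements_row(session, m: SessionMeasurements) -> dict:
    """Flatten one session's measurements for CSV export."""

    def fmt(x):
        return "" if x is None else round(x, 4)

    return {
        "patient_id": session.patient_id,
        "date": session.session_date.isoformat(),
        "months_since_index": round(session.months_since_index, 2),
        "status": session.operative_status,
        "d_wt_mm": fmt(m.d_wt),
        "d_em_mm": fmt(m.d_em),
        "d_intra_par_mm": fmt(m.d_intra_par),
        "d_extra_par_mm": fmt(m.d_extra_par),
        "d_extra_perp_mm": fmt(m.d_extra_perp),
        "v_intra_cm3": fmt(m.v_intra),
        "v_extra_cm3": fmt(m.v_extra),
        "v_whole_cm3": fmt(m.v_whole),
        "n_axial_slices": m.n_axial_slices,
        "reference_slice": "" if m.reference_slice is None else m.reference_slice,
        "entirely_intrameatal": m.entirely_intrameatal,
    }
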