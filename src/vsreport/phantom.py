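"""Synthetic two-compartment vestibular schwannoma phantoms.

The phantom emulates the anatomy the measurements assume: an intrameatal
capsule (cylinder with a hemispherical medial cap, flat at the porus) lying
along the internal-auditory-canal axis, joined across the porus plane to an
extrameatal ellipsoid.  The canal axis lies in the axial plane at a
configurable angle, so every in-plane measurement is exercised at oblique
orientations.  All ground-truth quantities have closed forms:

* compartment volumes (capsule and plane-clipped ellipsoid),
* maximum in-plane diameters (midplane cross-section geometry),
* the porus-plane trace direction (the meatal-axis ground truth),
* directional extents along / across that trace.

The ellipsoid center is pulled one voxel inside the porus plane so the two
voxelized compartments stay 26-connected; the clipped cap is inside the
capsule and is accounted for exactly.  Optional seeded boundary jitter
emulates segmentation noise for robustness tests; with jitter the volume
truths are nominal (noise-free) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from vsreport.mask_io import (
    LabeledVolume,
    write_labeled_volume,
    write_timeline_manifest,
)

__all__ = ["PhantomParams", "PhantomTruth", "make_phantom", "make_phantom_timeline"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and discretization of one phantom.

    All lengths in mm.  ``extra_axes`` are the extrameatal ellipsoid
    semi-axes (along-canal, along-ridge, inferior-superior); all-zero means
    an entirely intrameatal tumor.  ``canal_angle_deg`` rotates the canal
    axis in the axial plane.  ``porus_offset`` shifts the porus plane from
    the volume center along the canal direction.  ``boundary_jitter`` is
    the amplitude of seeded smooth surface noise.
    """

    spacing: float | tuple[float, float, float] = 0.5
    canal_angle_deg: float = 30.0
    intra_length: float = 10.0
    intra_radius: float = 4.0
    extra_axes: tuple[float, float, float] = (9.0, 6.0, 5.0)
    porus_offset: float = 0.0
    boundary_jitter: float = 0.0
    seed: int = 0
    shape: tuple[int, int, int] | None = None
    margin: float = 2.0

    def __post_init__(self) -> None:
        sp = self.spacing_tuple
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be positive")
        if self.intra_length < 0 or self.intra_radius <= 0:
            raise ValueError("intrameatal capsule needs radius > 0, length >= 0")
        if any(a < 0 for a in self.extra_axes):
            raise ValueError("ellipsoid semi-axes must be >= 0")
        if any(a > 0 for a in self.extra_axes) and not all(a > 0 for a in self.extra_axes):
            raise ValueError("ellipsoid semi-axes must be all zero or all positive")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")
        radii = [self.intra_radius] + [a for a in self.extra_axes if a > 0]
        if self.boundary_jitter >= min(radii):
            raise ValueError("boundary_jitter must be smaller than the smallest radius")

    @property
    def spacing_tuple(self) -> tuple[float, float, float]:
        if isinstance(self.spacing, (int, float)):
            return (float(self.spacing),) * 3
        return tuple(float(s) for s in self.spacing)

    @property
    def has_extrameatal(self) -> bool:
        return all(a > 0 for a in self.extra_axes)

    def scaled(self, factor: float) -> "PhantomParams":
        """Scale every linear tumor dimension (volumes scale by factor^3)."""
        return replace(
            self,
            intra_length=self.intra_length * factor,
            intra_radius=self.intra_radius * factor,
            extra_axes=tuple(a * factor for a in self.extra_axes),
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form ground truth for one phantom."""

    d_wt: float
    d_em: float | None
    v_intra: float
    v_extra: float
    v_whole: float
    u_par: tuple[float, float] | None
    d_intra_par: float | None
    d_extra_par: float | None
    d_extra_perp: float | None
    entirely_intrameatal: bool


def _ellipsoid_cap_volume(a: float, b: float, c: float, h: float) -> float:
    """Volume of the ellipsoid cap of height h cut perpendicular to axis a."""
    t0 = a - h
    integral = (a - a**3 / (3 * a**2)) - (t0 - t0**3 / (3 * a**2))
    return math.pi * b * c * integral


def _stadium_boundary(L: float, r: float, n: int = 720) -> np.ndarray:
    """Boundary samples of the capsule midplane cross-section in (t, s)."""
    phi = np.linspace(math.pi / 2, 3 * math.pi / 2, n)
    arc = np.column_stack([-L + r * np.cos(phi), r * np.sin(phi)])
    corners = np.array([[0.0, r], [0.0, -r], [-L, r], [-L, -r]])
    return np.vstack([arc, corners])


def _ellipse_boundary(a: float, b: float, center_t: float, n: int = 720) -> np.ndarray:
    phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center_t + a * np.cos(phi), b * np.sin(phi)])


def phantom_truth(p: PhantomParams) -> PhantomTruth:
    """Analytic measurements implied by the phantom parameters."""
    L, r = p.intra_length, p.intra_radius
    v_intra = (math.pi * r * r * L + (2.0 / 3.0) * math.pi * r**3) / 1000.0

    if not p.has_extrameatal:
        d_wt = max(L + r, 2 * r)
        return PhantomTruth(
            d_wt=d_wt, d_em=None,
            v_intra=v_intra, v_extra=0.0, v_whole=v_intra,
            u_par=None, d_intra_par=None, d_extra_par=None, d_extra_perp=None,
            entirely_intrameatal=True,
        )

    a, b, c = p.extra_axes
    delta = min(a, max(p.spacing_tuple))  # overlap pulling the ellipsoid into the canal
    v_cap = _ellipsoid_cap_volume(a, b, c, delta) / 1000.0
    v_extra = (4.0 / 3.0) * math.pi * a * b * c / 1000.0 - v_cap

    pts = np.vstack([_stadium_boundary(L, r), _ellipse_boundary(a, b, a - delta)])
    d_wt = float(pdist(pts).max())

    theta = math.radians(p.canal_angle_deg)
    ridge = np.array([-math.sin(theta), math.cos(theta)])
    if ridge[0] < 0 or (ridge[0] == 0 and ridge[1] < 0):
        ridge = -ridge

    return PhantomTruth(
        d_wt=d_wt,
        d_em=2 * max(a, b),
        v_intra=v_intra,
        v_extra=v_extra,
        v_whole=v_intra + v_extra,
        u_par=(float(ridge[0]), float(ridge[1])),
        d_intra_par=2 * r,
        d_extra_par=2 * b,
        d_extra_perp=2 * a - delta,
        entirely_intrameatal=False,
    )


def _jitter_field(rng: np.random.Generator, amplitude: float, n_waves: int = 8):
    """Smooth seeded noise field f(x) with |f| <= amplitude, in mm."""
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wavelengths = rng.uniform(5.0, 15.0, size=n_waves)
    k = dirs * (2 * math.pi / wavelengths)[:, None]
    phases = rng.uniform(0, 2 * math.pi, size=n_waves)
    amps = rng.uniform(0.5, 1.0, size=n_waves)
    scale = amplitude / amps.sum()

    def f(t, s, h):
        coords = np.stack([t, s, h], axis=-1)
        acc = np.zeros(t.shape)
        for i in range(n_waves):
            acc += amps[i] * np.sin(coords @ k[i] + phases[i])
        return scale * acc

    return f


def make_phantom(p: PhantomParams) -> tuple[LabeledVolume, PhantomTruth]:
    """Voxelize the phantom; deterministic given the seed.

    Returns the label volume (1 = intrameatal capsule, 2 = extrameatal
    ellipsoid, split at the porus plane) and its closed-form truth.

    Raises
    ------
    ValueError
        If an explicit ``shape`` is too small to contain the tumor (any
        tumor voxel would touch the array border).
    """
    sp = np.array(p.spacing_tuple)
    L, r = p.intra_length, p.intra_radius
    a, bb, c = p.extra_axes
    theta = math.radians(p.canal_angle_deg)
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    v = np.array([-math.sin(theta), math.cos(theta), 0.0])
    w = np.array([0.0, 0.0, 1.0])

    reach = L + r + 2 * a + abs(p.porus_offset) + p.boundary_jitter + p.margin
    if p.shape is None:
        shape = tuple(int(math.ceil(2 * reach / s)) | 1 for s in sp)
    else:
        shape = tuple(int(n) for n in p.shape)

    center = (np.array(shape) - 1) / 2.0 * sp
    porus = center + p.porus_offset * u

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]) * sp[0],
        np.arange(shape[1]) * sp[1],
        np.arange(shape[2]) * sp[2],
        indexing="ij",
    )
    x = ii - porus[0]
    y = jj - porus[1]
    z = kk - porus[2]
    t = x * u[0] + y * u[1] + z * u[2]
    s = x * v[0] + y * v[1] + z * v[2]
    h = z  # w is the third axis

    if p.boundary_jitter > 0:
        rng = np.random.default_rng(p.seed)
        f = _jitter_field(rng, p.boundary_jitter)(t, s, h)
    else:
        f = 0.0

    r_eff = r + f
    radial2 = s * s + h * h
    in_shaft = (t >= -L) & (t <= 0.0) & (radial2 <= r_eff * r_eff)
    cap_d2 = (t + L) ** 2 + radial2
    in_cap = (t < -L) & (cap_d2 <= r_eff * r_eff)
    labels = np.zeros(shape, dtype=np.int16)
    labels[in_shaft | in_cap] = 1

    if p.has_extrameatal:
        delta = min(a, float(sp.max()))
        m0 = a - delta
        q = np.sqrt(((t - m0) / a) ** 2 + (s / bb) ** 2 + (h / c) ** 2)
        in_ell = q <= 1.0 + f / min(a, bb, c)
        labels[in_ell & (t > 0.0) & (labels == 0)] = 2

    border = np.zeros(shape, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    if (labels[border] != 0).any():
        raise ValueError("volume bounds too small to contain the phantom")

    return LabeledVolume(labels, tuple(sp)), phantom_truth(p)


def make_phantom_timeline(
    p0: PhantomParams,
    growth_factors: list[float],
    dates: list[str],
    out_dir: str | Path,
    statuses: list[str] | None = None,
    decisions: list[str | None] | None = None,
    patient_id: str = "phantom-001",
) -> tuple[Path, list[PhantomTruth]]:
    """Write a longitudinal phantom series plus its manifest.

    ``growth_factors[i]`` scales every linear tumor dimension of session i
    relative to ``p0`` (so volume scales with the cube).  Produces
    ``<patient>_<date>_mask.nii.gz`` files, a ``manifest.csv`` consumable
    by :func:`vsreport.mask_io.read_timeline_manifest`, and a
    ``truth.csv`` table of the analytic per-session measurements.
    """
    if len(growth_factors) != len(dates):
        raise ValueError("one growth factor per session date required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    statuses = statuses or ["preoperative"] * len(dates)
    decisions = decisions or [None] * len(dates)

    rows = []
    truths: list[PhantomTruth] = []
    truth_rows = []
    for date, factor, status, decision in zip(dates, growth_factors, statuses, decisions):
        params = p0.scaled(factor)
        vol, truth = make_phantom(params)
        name = f"{patient_id}_{date}_mask.nii.gz"
        write_labeled_volume(vol, out_dir / name)
        rows.append(
            {
                "patient_id": patient_id,
                "date": date,
                "status": status,
                "mask_path": name,
                "decision": decision or "",
            }
        )
        truths.append(truth)
        truth_rows.append(
            {
                "patient_id": patient_id,
                "date": date,
                "growth_factor": factor,
                "d_wt_mm": round(truth.d_wt, 4),
                "d_em_mm": "" if truth.d_em is None else round(truth.d_em, 4),
                "v_intra_cm3": round(truth.v_intra, 6),
                "v_extra_cm3": round(truth.v_extra, 6),
                "v_whole_cm3": round(truth.v_whole, 6),
            }
        )
    manifest = write_timeline_manifest(rows, out_dir / "manifest.csv")

    import csv

    with open(out_dir / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(truth_rows[0].keys()))
        writer.writeheader()
        writer.writerows(truth_rows)
    return manifest, truths
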