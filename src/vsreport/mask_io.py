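"""Reading and validation of label volumes and timeline manifests.

Label convention: 0 = background, 1 = intrameatal tumor, 2 = extrameatal
tumor.  Volumes are reoriented to the RAS+ canonical frame on load so that
the third array axis is always inferior-superior; an "axial slice" is a 2D
section across that axis everywhere in this package.  Voxels are never
resampled: measurements are taken at the native (possibly anisotropic)
spacing.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "LabeledVolume",
    "SessionRecord",
    "PatientTimeline",
    "ManifestError",
    "read_labeled_volume",
    "write_labeled_volume",
    "read_timeline_manifest",
]

#: Mean Gregorian month length used to convert date differences to months.
DAYS_PER_MONTH = 30.44

VALID_LABELS = frozenset({0, 1, 2})
OPERATIVE_STATUSES = frozenset({"preoperative", "postoperative", "post-SRS"})


class ManifestError(ValueError):
    """Raised when a timeline manifest cannot be used (index session invalid)."""


@dataclass
class LabeledVolume:
    """A canonicalized 3D label mask with physical voxel spacing.

    Attributes
    ----------
    labels
        3D integer array; values in {0, 1, 2}.
    spacing
        (sx, sy, sz) voxel edge lengths in mm along the canonical axes.
    orientation
        Anatomical frame tag of the canonicalized array ("RAS").
    axial_axis
        Index of the inferior-superior axis; fixed to 2 after
        canonicalization.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown label value(s): {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class SessionRecord:
    """One imaging session of one patient as listed in the manifest."""

    patient_id: str
    session_date: _dt.date
    operative_status: str
    mask_path: Path
    image_path: Path | None = None
    decision_label: str | None = None
    months_since_index: float = 0.0

    def __post_init__(self) -> None:
        if self.operative_status not in OPERATIVE_STATUSES:
            raise ValueError(
                f"operative_status must be one of {sorted(OPERATIVE_STATUSES)}, "
                f"got {self.operative_status!r}"
            )
        if self.months_since_index < 0:
            raise ValueError("months_since_index must be >= 0")


@dataclass
class PatientTimeline:
    """Date-ordered sessions of one patient.

    The index session is the earliest scan; headline growth comparisons are
    made index -> latest and second-most-recent -> latest.
    """

    patient_id: str
    sessions: list[SessionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("a timeline needs at least one session")
        dates = [s.session_date for s in self.sessions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("session dates must be strictly increasing")

    @property
    def index(self) -> SessionRecord:
        return self.sessions[0]

    @property
    def most_recent(self) -> SessionRecord:
        return self.sessions[-1]

    @property
    def second_most_recent(self) -> SessionRecord | None:
        return self.sessions[-2] if len(self.sessions) >= 2 else None

    def __len__(self) -> int:
        return len(self.sessions)


def _canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_labeled_volume(
    path: str | Path,
    label_map: Mapping[int, int] | None = None,
) -> LabeledVolume:
    """Load a NIfTI label mask, canonicalize it and validate its labels.

    Parameters
    ----------
    path
        A ``.nii`` or ``.nii.gz`` file with integer-valued voxels.
    label_map
        Optional remapping applied to the raw values before validation, for
        masks that encode the compartments with other integers
        (e.g. ``{0: 0, 3: 1, 4: 2}``).

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, non-NIfTI content, non-integer voxels, labels outside
        {0, 1, 2} after remapping, or degenerate spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    img = _canonicalize(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: voxel values are not integral")
        data = rounded.astype(np.int16)
    else:
        data = data.astype(np.int16, copy=False)
    if label_map is not None:
        out = np.zeros_like(data)
        for src, dst in label_map.items():
            out[data == src] = dst
        data = out
    bad = set(np.unique(data)) - VALID_LABELS
    if bad:
        raise ValueError(f"{path}: unknown label value(s) {sorted(bad)}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: degenerate voxel spacing {zooms}")
    return LabeledVolume(labels=data, spacing=tuple(float(z) for z in zooms))


def write_labeled_volume(vol: LabeledVolume, path: str | Path) -> Path:
    """Write a LabeledVolume as NIfTI with an RAS-aligned diagonal affine."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Timeline manifests
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("patient_id", "date", "status", "mask_path")


def _parse_rows(path: Path) -> list[dict]:
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ManifestError(f"{path}: JSON manifest must be a list of records")
        return [dict(r) for r in rows]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [dict(r) for r in reader]


def read_timeline_manifest(
    path: str | Path,
    errors: list[str] | None = None,
    require_mask_files: bool = True,
) -> list[PatientTimeline]:
    """Parse a CSV or JSON manifest into per-patient timelines.

    Each row needs ``patient_id``, ``date`` (ISO-8601), ``status``
    (preoperative / postoperative / post-SRS) and ``mask_path``; optional
    ``image_path`` and ``decision`` columns carry the MR image for overlays
    and the post-session management decision.  Relative paths are resolved
    against the manifest's directory.  Rows are grouped by patient and
    sorted by date; ``months_since_index`` is the day difference to the
    index scan divided by 30.44.

    Invalid rows are skipped and a diagnostic is appended to ``errors`` (if
    given); the manifest is rejected with :class:`ManifestError` only when a
    patient's index (earliest) session is itself invalid, or when duplicate
    (patient, date) pairs occur.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    collected: list[str] = errors if errors is not None else []
    raw = _parse_rows(path)

    per_patient: dict[str, list[tuple[_dt.date, dict, int]]] = {}
    bad_dates: dict[str, list[int]] = {}
    for i, row in enumerate(raw):
        missing = [k for k in _REQUIRED_KEYS if not row.get(k)]
        if missing:
            collected.append(f"row {i}: missing field(s) {missing}")
            continue
        pid = str(row["patient_id"])
        try:
            date = _dt.date.fromisoformat(str(row["date"]).strip())
        except ValueError:
            collected.append(f"row {i}: unparseable date {row['date']!r}")
            bad_dates.setdefault(pid, []).append(i)
            continue
        per_patient.setdefault(pid, []).append((date, row, i))

    timelines: list[PatientTimeline] = []
    for pid in sorted(per_patient):
        entries = sorted(per_patient[pid], key=lambda e: e[0])
        dates = [e[0] for e in entries]
        if len(set(dates)) != len(dates):
            dupes = sorted({d for d in dates if dates.count(d) > 1})
            raise ManifestError(f"patient {pid}: duplicate session date(s) {dupes}")
        index_date = dates[0]
        sessions: list[SessionRecord] = []
        for date, row, i in entries:
            mask_path = Path(str(row["mask_path"]))
            if not mask_path.is_absolute():
                mask_path = path.parent / mask_path
            row_errors: list[str] = []
            if require_mask_files and not mask_path.exists():
                row_errors.append(f"row {i}: mask file not found: {mask_path}")
            status = str(row["status"]).strip()
            if status not in OPERATIVE_STATUSES:
                row_errors.append(f"row {i}: unknown operative status {status!r}")
            if row_errors:
                collected.extend(row_errors)
                if date == index_date:
                    raise ManifestError(
                        f"patient {pid}: index session invalid: " + "; ".join(row_errors)
                    )
                continue
            image_path = row.get("image_path") or None
            if image_path:
                image_path = Path(str(image_path))
                if not image_path.is_absolute():
                    image_path = path.parent / image_path
            sessions.append(
                SessionRecord(
                    patient_id=pid,
                    session_date=date,
                    operative_status=status,
                    mask_path=mask_path,
                    image_path=image_path,
                    decision_label=(row.get("decision") or None),
                    months_since_index=(date - index_date).days / DAYS_PER_MONTH,
                )
            )
        if sessions:
            timelines.append(PatientTimeline(patient_id=pid, sessions=sessions))
    return timelines


def write_timeline_manifest(
    rows: Sequence[Mapping[str, object]], path: str | Path
) -> Path:
    """Write manifest rows (dicts with the documented keys) as CSV."""
    path = Path(path)
    cols = ["patient_id", "date", "status", "mask_path", "image_path", "decision"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in cols})
    return path
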