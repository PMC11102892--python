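"""On-disk formats for the cystic-renal-lesion (CRL) toolkit.

Every artifact that touches the filesystem goes through this module so that
the rest of the package is pure computation on in-memory arrays:

* 3D CT phase volumes and binary lesion masks — NIfTI-1 (``.nii`` / ``.nii.gz``)
  via nibabel, reoriented to RAS before axis extraction;
* user interaction point sets — JSON with ``positive`` / ``negative`` lists of
  ``[z, y, x]`` integer triples;
* case-level malignancy predictions — CSV with header
  ``study_id,prob_malignant,label``;
* cohort manifests — CSV with header
  ``study_id,label,phase1_path,phase2_path,mask_path`` (extra columns allowed).

Conventions (used everywhere downstream): voxel arrays are indexed ``(z, y, x)``
0-based, spacing is ``(dz, dy, dx)`` in millimetres, HU values are floats in
memory, masks are ``uint8`` with values {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PhaseVolume",
    "MultiPhaseStudy",
    "InteractionSet",
    "PredictionRecord",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_interactions",
    "write_interactions",
    "read_predictions",
    "write_predictions",
    "read_manifest",
    "write_manifest",
    "load_study",
]

#: canonical phase order — corticomedullary first, then nephrogenic
PHASE_ORDER = ("corticomedullary", "nephrogenic")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates this module's contracts."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhaseVolume:
    """One 3D CT phase: HU voxel grid in (z, y, x) order plus spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase: str = "corticomedullary"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError("not a 3D volume")
        if any(s < 8 for s in self.voxels.shape):
            raise FormatError(
                f"grid dimensions must be >= 8 per axis, got {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise FormatError(f"spacing must be 3 finite positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class MultiPhaseStudy:
    """Ordered CT phases + optional lesion mask + optional malignancy label.

    Phase order is fixed corticomedullary-first; all phases (and the mask)
    share one grid shape and spacing.
    """

    phases: list[PhaseVolume]
    mask: Optional[np.ndarray] = None
    label: Optional[str] = None  # "benign" | "malignant"
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.phases:
            raise FormatError("study needs at least one phase")
        shape = self.phases[0].shape
        spacing = self.phases[0].spacing
        for p in self.phases:
            if p.shape != shape or p.spacing != spacing:
                raise FormatError("all phases must share shape and spacing")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != shape:
                raise FormatError("mask shape differs from phase shape")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise FormatError("mask values must be in {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        if self.label is not None and self.label not in ("benign", "malignant"):
            raise FormatError(f"label must be benign/malignant, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phases[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.phases[0].spacing


@dataclass
class InteractionSet:
    """Positive (foreground) and negative (background) indicator voxels.

    Coordinates are 0-based ``(z, y, x)`` tuples; the two sets are disjoint.
    """

    positive: list[tuple[int, int, int]] = field(default_factory=list)
    negative: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positive = [tuple(int(c) for c in p) for p in self.positive]  # type: ignore[misc]
        self.negative = [tuple(int(c) for c in p) for p in self.negative]  # type: ignore[misc]
        if set(self.positive) & set(self.negative):
            raise FormatError("positive and negative interaction sets overlap")

    def check_bounds(self, shape: Sequence[int]) -> "InteractionSet":
        for pt in self.positive + self.negative:
            if len(pt) != 3 or any(c < 0 or c >= n for c, n in zip(pt, shape)):
                raise FormatError(f"interaction {pt} outside grid {tuple(shape)}")
        return self

    def merged(self, other: "InteractionSet") -> "InteractionSet":
        """Union of two interaction sets (deduplicated, order-preserving)."""
        pos = list(dict.fromkeys(self.positive + other.positive))
        neg = list(dict.fromkeys(self.negative + other.negative))
        return InteractionSet(pos, neg)

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


@dataclass
class PredictionRecord:
    """Case-level malignancy probability, optionally with the true label."""

    study_id: str
    prob_malignant: float
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.prob_malignant = float(self.prob_malignant)
        if not (0.0 <= self.prob_malignant <= 1.0):
            raise FormatError(
                f"probability must lie in [0, 1], got {self.prob_malignant}"
            )
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise FormatError(f"label must be 0/1, got {self.label}")


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    # normalize orientation to RAS so (x, y, z) file axes have a fixed meaning
    return nib.as_closest_canonical(img)


def read_volume(
    path: str | Path, phase: str = "corticomedullary", study_id: str = ""
) -> PhaseVolume:
    """Read a 3D NIfTI image as a :class:`PhaseVolume`.

    The image is reoriented to RAS, then the (x, y, z) data axes are reversed
    into the canonical (z, y, x) in-memory order with spacing (dz, dy, dx).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    img = _canonical(nib.load(str(path)))
    if img.ndim != 3:
        raise FormatError(f"not a 3D volume: {path} has {img.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise FormatError(f"non-finite or non-positive spacing in {path}: {zooms}")
    data = np.asarray(img.dataobj, dtype=np.float32)
    # file order is (x, y, z) after RAS normalization -> transpose to (z, y, x)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return PhaseVolume(voxels=voxels, spacing=spacing, phase=phase, study_id=study_id)


def write_volume(vol: PhaseVolume, path: str | Path, dtype=np.float32) -> Path:
    """Write a :class:`PhaseVolume` as NIfTI-1 with an RAS diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(vol.voxels.astype(dtype).transpose(2, 1, 0))
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary {0,1} mask stored as NIfTI; returns a (z, y, x) uint8 grid."""
    vol = read_volume(path, phase="mask")
    mask = vol.voxels
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise FormatError(f"mask at {path} has values outside {{0,1}}: {vals[:10]}")
    return mask.astype(np.uint8)


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> Path:
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise FormatError("mask values must be in {0, 1}")
    vol = PhaseVolume(mask.astype(np.uint8), spacing, phase="mask")
    return write_volume(vol, path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# interactions (JSON)
# ---------------------------------------------------------------------------


def read_interactions(
    path: str | Path, grid_shape: Optional[Sequence[int]] = None
) -> InteractionSet:
    """Read an interaction JSON file; bounds-checked if ``grid_shape`` given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(obj, dict) or "positive" not in obj or "negative" not in obj:
        raise FormatError(f"{path}: expected keys 'positive' and 'negative'")
    iset = InteractionSet(
        positive=[tuple(p) for p in obj["positive"]],
        negative=[tuple(p) for p in obj["negative"]],
    )
    if grid_shape is not None:
        iset.check_bounds(grid_shape)
    return iset


def write_interactions(iset: InteractionSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "positive": [list(p) for p in iset.positive],
                "negative": [list(p) for p in iset.negative],
            },
            indent=1,
        )
    )
    return path


# ---------------------------------------------------------------------------
# predictions (CSV)
# ---------------------------------------------------------------------------

_PRED_COLUMNS = ["study_id", "prob_malignant", "label"]


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _PRED_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        label = None
        if "label" in df.columns and not pd.isna(row["label"]):
            label = int(row["label"])
        records.append(
            PredictionRecord(
                study_id=str(row["study_id"]),
                prob_malignant=float(row["prob_malignant"]),
                label=label,
            )
        )
    return records


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "study_id": [r.study_id for r in records],
            "prob_malignant": [r.prob_malignant for r in records],
            "label": [r.label if r.label is not None else np.nan for r in records],
        }
    )
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# cohort manifests (CSV)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["study_id", "label", "phase1_path", "phase2_path", "mask_path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; paths are resolved relative to the CSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing manifest: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    base = path.parent
    for col in df.columns:
        if col.endswith("_path"):
            df[col] = [
                str((base / p)) if (p == p and not Path(str(p)).is_absolute()) else p
                for p in df[col]
            ]
    df["study_id"] = df["study_id"].astype(str)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    out = df.copy()
    base = path.parent.resolve()
    for col in out.columns:
        if col.endswith("_path"):
            resolved = []
            for p in out[col]:
                if p != p:  # NaN
                    resolved.append(p)
                    continue
                q = Path(str(p))
                try:
                    resolved.append(str(q.resolve().relative_to(base)))
                except ValueError:
                    resolved.append(str(q))
            out[col] = resolved
    out.to_csv(path, index=False)
    return path


def load_study(row: pd.Series | dict) -> MultiPhaseStudy:
    """Load one manifest row into a :class:`MultiPhaseStudy` (phases + mask)."""
    sid = str(row["study_id"])
    phases = [
        read_volume(row["phase1_path"], phase=PHASE_ORDER[0], study_id=sid),
        read_volume(row["phase2_path"], phase=PHASE_ORDER[1], study_id=sid),
    ]
    mask = None
    mp = row.get("mask_path") if hasattr(row, "get") else row["mask_path"]
    if mp == mp and mp is not None:  # not NaN
        mask = read_mask(mp)
    label = row.get("label") if hasattr(row, "get") else row["label"]
    label = None if label is None or label != label else str(label)
    return MultiPhaseStudy(phases=phases, mask=mask, label=label, study_id=sid)
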