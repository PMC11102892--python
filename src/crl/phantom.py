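"""Synthetic multi-phase CT phantoms of kidney-embedded cystic renal lesions.

Real CRL cohorts are private, so this module renders seeded, fully
reproducible stand-ins whose benign/malignant ground truth is defined by the
standard contrast-enhancement rule: a solid component that gains >= 15 HU
over its unenhanced baseline in some post-contrast phase marks the lesion
malignant; lesions with no solid component, or whose components enhance
< 15 HU, are benign.

Each study has two phases in fixed order — corticomedullary, then
nephrogenic — rendered as background, a kidney ellipsoid (bright cortex in
the corticomedullary phase), a spherical fluid lesion (phase-constant HU),
and optionally a solid component (mural nodule on the cyst wall, or a thin
septum) whose HU follows a per-phase trajectory:

* ``fast_in_fast_out`` — strong corticomedullary enhancement that washes out
  by the nephrogenic phase (clear-cell-carcinoma-like);
* ``gradual`` — moderate, relatively homogeneous enhancement across both
  phases (papillary/chromophobe-like).

Rendering is followed by Gaussian smoothing (partial-volume surrogate) and
additive Gaussian HU noise. The ground-truth mask covers the whole lesion
(fluid + solid); the solid fraction is kept below 25% of the lesion volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .formats_io import (
    MANIFEST_COLUMNS,
    MultiPhaseStudy,
    PhaseVolume,
    write_manifest,
    write_mask,
    write_volume,
)

__all__ = [
    "SolidComponent",
    "PhantomSpec",
    "CohortManifest",
    "generate_study",
    "generate_cohort",
    "simulate_enhancement_check",
    "ENHANCEMENT_THRESHOLD_HU",
]

#: HU gain over baseline that defines enhancement (malignancy of the solid part)
ENHANCEMENT_THRESHOLD_HU = 15.0

#: maximum solid fraction of the lesion volume (cohort inclusion rule)
MAX_SOLID_FRACTION = 0.25


@dataclass
class SolidComponent:
    """Solid sub-region of the lesion with a per-phase enhancement trajectory.

    ``delta_hu`` is the HU gain over ``baseline_hu`` in (corticomedullary,
    nephrogenic) order; the component enhances iff max(delta_hu) >= 15.
    """

    kind: str = "nodule"  # "nodule" | "septum"
    baseline_hu: float = 30.0
    delta_hu: tuple[float, float] = (40.0, 10.0)
    radius_mm: float = 6.0  # nodule radius, or septum thickness for "septum"
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)  # placement axis

    def __post_init__(self) -> None:
        if self.kind not in ("nodule", "septum"):
            raise ValueError(f"unknown solid component kind {self.kind!r}")
        if len(self.delta_hu) != 2:
            raise ValueError("delta_hu must give (corticomedullary, nephrogenic)")

    @property
    def enhances(self) -> bool:
        return max(self.delta_hu) >= ENHANCEMENT_THRESHOLD_HU


@dataclass
class PhantomSpec:
    """Full description of one synthetic study (deterministic given seed)."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    background_hu: float = -30.0
    kidney_center_mm: Optional[tuple[float, float, float]] = None  # default: grid centre
    kidney_semiaxes_mm: tuple[float, float, float] = (30.0, 24.0, 24.0)
    kidney_hu: tuple[float, float] = (170.0, 130.0)  # cortex HU per phase
    medulla_offset_hu: float = -50.0  # medulla is darker, mostly corticomedullary
    lesion_center_mm: Optional[tuple[float, float, float]] = None
    lesion_radius_mm: float = 12.0
    fluid_hu: float = 10.0
    solid: Optional[SolidComponent] = None
    noise_sd: float = 10.0
    smoothing_sigma_mm: float = 1.0
    include_baseline_phase: bool = False
    min_radius_mm: float = 5.0
    seed: int = 0
    study_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lesion_radius_mm < self.min_radius_mm:
            raise ValueError(
                f"lesion radius {self.lesion_radius_mm} mm below minimum "
                f"{self.min_radius_mm} mm"
            )

    @property
    def label(self) -> str:
        """Ground-truth label: malignant iff an enhancing solid component exists."""
        return "malignant" if (self.solid is not None and self.solid.enhances) else "benign"

    def _centers(self) -> tuple[np.ndarray, np.ndarray]:
        extent = np.array(self.grid_shape) * np.array(self.spacing)
        kid = (
            np.asarray(self.kidney_center_mm, float)
            if self.kidney_center_mm is not None
            else extent / 2.0
        )
        les = (
            np.asarray(self.lesion_center_mm, float)
            if self.lesion_center_mm is not None
            else kid
        )
        return kid, les


def _coord_grids(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _validate_geometry(spec: PhantomSpec) -> None:
    kid, les = spec._centers()
    extent = np.array(spec.grid_shape) * np.array(spec.spacing)
    semi = np.asarray(spec.kidney_semiaxes_mm, float)
    # lesion inside kidney
    rel = (les - kid) / semi
    if np.sqrt((rel**2).sum()) + spec.lesion_radius_mm / semi.min() > 1.0 + 1e-9:
        raise ValueError("lesion escapes the kidney ellipsoid")
    # kidney inside grid
    if np.any(kid - semi < -1e-9) or np.any(kid + semi > extent + 1e-9):
        raise ValueError("kidney ellipsoid escapes the grid")


def _render_solid_mask(spec: PhantomSpec, zz, yy, xx) -> np.ndarray:
    """Boolean mask of the solid component, clipped to the lesion interior."""
    assert spec.solid is not None
    _, les = spec._centers()
    solid = spec.solid
    r2_lesion = (zz - les[0]) ** 2 + (yy - les[1]) ** 2 + (xx - les[2]) ** 2
    inside_lesion = r2_lesion <= spec.lesion_radius_mm**2
    d = np.asarray(solid.direction, float)
    d = d / (np.linalg.norm(d) + 1e-12)
    if solid.kind == "nodule":
        # mural nodule: sphere centred on the cyst wall, kept inside the lesion
        c = les + d * max(spec.lesion_radius_mm - solid.radius_mm, 0.0)
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        mask = (r2 <= solid.radius_mm**2) & inside_lesion
    else:
        # septum: thin planar slab through the lesion centre, normal to d
        dist = np.abs((zz - les[0]) * d[0] + (yy - les[1]) * d[1] + (xx - les[2]) * d[2])
        mask = (dist <= solid.radius_mm / 2.0) & inside_lesion
    return mask


def generate_study(spec: PhantomSpec) -> MultiPhaseStudy:
    """Render one seeded multi-phase study from its spec.

    Paint order per phase: background -> kidney (cortex shell brighter in the
    corticomedullary phase, darker medulla core) -> lesion fluid -> solid
    component; then Gaussian smoothing and additive Gaussian noise. The
    returned study carries the ground-truth lesion mask and the label implied
    by the enhancement rule. Identical specs (same seed) render bit-identical
    volumes.
    """
    _validate_geometry(spec)
    shape, spacing = spec.grid_shape, spec.spacing
    kid, les = spec._centers()
    zz, yy, xx = _coord_grids(shape, spacing)
    semi = np.asarray(spec.kidney_semiaxes_mm, float)

    ell = (
        ((zz - kid[0]) / semi[0]) ** 2
        + ((yy - kid[1]) / semi[1]) ** 2
        + ((xx - kid[2]) / semi[2]) ** 2
    )
    kidney = ell <= 1.0
    medulla = ell <= 0.55  # inner core rendered darker (corticomedullary contrast)

    r2_lesion = (zz - les[0]) ** 2 + (yy - les[1]) ** 2 + (xx - les[2]) ** 2
    lesion = r2_lesion <= spec.lesion_radius_mm**2
    solid_mask = (
        _render_solid_mask(spec, zz, yy, xx) if spec.solid is not None else None
    )
    if solid_mask is not None:
        frac = solid_mask.sum() / max(lesion.sum(), 1)
        if frac >= MAX_SOLID_FRACTION:
            raise ValueError(
                f"solid fraction {frac:.2f} >= {MAX_SOLID_FRACTION} of lesion volume"
            )

    phase_names = ["corticomedullary", "nephrogenic"]
    phase_idx = [0, 1]
    if spec.include_baseline_phase:
        phase_names = ["unenhanced"] + phase_names
        phase_idx = [None] + phase_idx  # type: ignore[list-item]

    rng = np.random.default_rng(spec.seed)
    sigma_vox = [spec.smoothing_sigma_mm / s for s in spacing]
    phases: list[PhaseVolume] = []
    for name, idx in zip(phase_names, phase_idx):
        img = np.full(shape, spec.background_hu, dtype=np.float64)
        if idx is None:  # unenhanced baseline: kidney at a flat pre-contrast HU
            img[kidney] = 35.0
        else:
            img[kidney] = spec.kidney_hu[idx]
            if idx == 0:
                img[medulla] = spec.kidney_hu[idx] + spec.medulla_offset_hu
        img[lesion] = spec.fluid_hu
        if solid_mask is not None:
            base = spec.solid.baseline_hu  # type: ignore[union-attr]
            delta = 0.0 if idx is None else spec.solid.delta_hu[idx]  # type: ignore[union-attr]
            img[solid_mask] = base + delta
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        phases.append(
            PhaseVolume(
                voxels=img.astype(np.float32),
                spacing=spacing,
                phase=name,
                study_id=spec.study_id,
            )
        )

    return MultiPhaseStudy(
        phases=phases,
        mask=lesion.astype(np.uint8),
        label=spec.label,
        study_id=spec.study_id,
    )


def solid_mask_of(spec: PhantomSpec) -> Optional[np.ndarray]:
    """Ground-truth solid-component mask of a spec (None for pure cysts)."""
    if spec.solid is None:
        return None
    zz, yy, xx = _coord_grids(spec.grid_shape, spec.spacing)
    return _render_solid_mask(spec, zz, yy, xx).astype(np.uint8)


def simulate_enhancement_check(
    study: MultiPhaseStudy,
    solid_mask: np.ndarray,
    baseline_hu: float,
    erode_for_smoothing_mm: float = 2.0,
) -> float:
    """Measured enhancement: mean corticomedullary HU in the solid region
    minus the component's unenhanced baseline HU.

    The mask is eroded by ``erode_for_smoothing_mm`` (about two smoothing
    supports) before averaging so partial-volume edge voxels do not bias the
    estimate; if erosion empties the mask the full mask is used.
    """
    solid_mask = np.asarray(solid_mask).astype(bool)
    if not solid_mask.any():
        raise ValueError("solid mask is empty")
    cortico = next(
        (p for p in study.phases if p.phase == "corticomedullary"), study.phases[0]
    )
    n_erode = int(math.ceil(erode_for_smoothing_mm / min(cortico.spacing)))
    eroded = solid_mask
    if n_erode > 0:
        cand = ndimage.binary_erosion(solid_mask, iterations=n_erode)
        if cand.any():
            eroded = cand
    return float(cortico.voxels[eroded].mean() - baseline_hu)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Generated cohort: manifest table + per-study specs and metadata paths."""

    table: pd.DataFrame
    prevalence: float
    seed: int
    path: Optional[Path] = None
    specs: list[PhantomSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def _random_spec(
    rng: np.random.Generator,
    study_id: str,
    malignant: bool,
    pattern: Optional[str],
    grid_shape,
    spacing,
    noise_sd: float,
    benign_solid_prob: float = 0.5,
) -> PhantomSpec:
    """Draw one study's geometry/trajectory from the documented ranges."""
    extent = np.array(grid_shape) * np.array(spacing)
    semi = extent * np.array([0.40, 0.32, 0.32]) * rng.uniform(0.9, 1.1, 3)
    kid = extent / 2.0 + rng.uniform(-0.02, 0.02, 3) * extent
    # cohort lesions are large relative to the kidney (cystic lesions reach
    # several cm in vivo); a generous radius keeps mural nodules and septa
    # several voxels wide after smoothing at coarse grids
    radius = max(float(rng.uniform(0.15, 0.25) * extent.min()), 5.0)
    # lesion centre inside the kidney core so the sphere stays inside the ellipsoid
    while True:
        off = rng.uniform(-0.4, 0.4, 3) * semi
        rel = off / semi
        if np.sqrt((rel**2).sum()) + radius / semi.min() <= 0.98:
            break
    direction = rng.normal(size=3)
    solid: Optional[SolidComponent] = None
    if malignant:
        if pattern == "fast_in_fast_out":
            delta = (float(rng.uniform(30, 50)), float(rng.uniform(4, 12)))
        else:  # gradual / homogeneous enhancement
            delta = (float(rng.uniform(18, 30)), float(rng.uniform(20, 35)))
        kind = "nodule" if rng.uniform() < 0.7 else "septum"
        # malignant septa are *thickened* (the Bosniak III cue), >= ~3 mm,
        # while benign septa below stay thin (<= 2 mm, Bosniak II)
        size = (
            float(rng.uniform(0.35, 0.5) * radius)
            if kind == "nodule"
            else min(float(rng.uniform(3.0, 5.0)), 0.3 * radius)
        )
        solid = SolidComponent(
            kind=kind,
            baseline_hu=float(rng.uniform(25, 35)),
            delta_hu=delta,
            radius_mm=size,
            direction=tuple(direction),
        )
    elif rng.uniform() < benign_solid_prob:
        # benign complexity: a non-enhancing septum or nodule (< 15 HU gain)
        delta = (float(rng.uniform(0, 10)), float(rng.uniform(0, 10)))
        kind = "septum" if rng.uniform() < 0.5 else "nodule"
        size = (
            float(rng.uniform(0.25, 0.4) * radius)
            if kind == "nodule"
            else min(float(rng.uniform(1.0, 2.0)), 0.2 * radius)
        )
        solid = SolidComponent(
            kind=kind,
            baseline_hu=float(rng.uniform(25, 35)),
            delta_hu=delta,
            radius_mm=size,
            direction=tuple(direction),
        )
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing=tuple(spacing),
        kidney_center_mm=tuple(kid),
        kidney_semiaxes_mm=tuple(semi),
        lesion_center_mm=tuple(kid + off),
        lesion_radius_mm=radius,
        solid=solid,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        study_id=study_id,
    )


def generate_cohort(
    n: int,
    prevalence: float,
    out_dir: str | Path,
    pattern_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
    noise_sd: float = 10.0,
    allow_degenerate: bool = False,
) -> CohortManifest:
    """Generate ``n`` studies on disk plus a manifest CSV.

    The malignant count is ``int(n * prevalence + 0.5)`` (round half up);
    malignant cases split between the ``fast_in_fast_out`` and ``gradual``
    trajectory patterns per ``pattern_mix`` (default 50/50). Half of the
    benign lesions carry a non-enhancing solid component so that component
    presence alone does not reveal the label. Every file path and random
    draw is a pure function of ``seed``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not (0.0 < prevalence < 1.0) and not allow_degenerate:
        raise ValueError(
            "degenerate prevalence (0 or 1) requires allow_degenerate=True"
        )
    pattern_mix = pattern_mix or {"fast_in_fast_out": 0.5, "gradual": 0.5}
    total = sum(pattern_mix.values())
    patterns = list(pattern_mix)
    weights = np.array([pattern_mix[p] / total for p in patterns])

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_mal = int(n * prevalence + 0.5)
    labels = ["malignant"] * n_mal + ["benign"] * (n - n_mal)
    rng.shuffle(labels)

    rows = []
    specs = []
    for i, label in enumerate(labels):
        sid = f"s{i:04d}"
        pattern = patterns[rng.choice(len(patterns), p=weights)] if label == "malignant" else None
        spec = _random_spec(
            rng, sid, label == "malignant", pattern, grid_shape, spacing, noise_sd
        )
        study = generate_study(spec)
        p1 = write_volume(study.phases[0], out_dir / f"{sid}_cortico.nii.gz")
        p2 = write_volume(study.phases[1], out_dir / f"{sid}_nephro.nii.gz")
        pm = write_mask(study.mask, spacing, out_dir / f"{sid}_mask.nii.gz")
        smask = solid_mask_of(spec)
        sm_path = None
        if smask is not None:
            sm_path = write_mask(smask, spacing, out_dir / f"{sid}_solid.nii.gz")
        meta = {
            "study_id": sid,
            "label": label,
            "pattern": pattern,
            "baseline_hu": spec.solid.baseline_hu if spec.solid else None,
            "delta_hu": list(spec.solid.delta_hu) if spec.solid else None,
            "solid_mask_path": sm_path.name if sm_path else None,
            "lesion_radius_mm": spec.lesion_radius_mm,
            "seed": spec.seed,
        }
        meta_path = out_dir / f"{sid}_meta.json"
        meta_path.write_text(json.dumps(meta, indent=1))
        rows.append(
            {
                "study_id": sid,
                "label": label,
                "phase1_path": str(p1),
                "phase2_path": str(p2),
                "mask_path": str(pm),
                "meta_path": str(meta_path),
            }
        )
        specs.append(spec)

    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["meta_path"])
    manifest_path = out_dir / "manifest.csv"
    write_manifest(df, manifest_path)
    # keep absolute paths in the returned table for immediate use
    return CohortManifest(
        table=df, prevalence=n_mal / n, seed=seed, path=manifest_path, specs=specs
    )
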