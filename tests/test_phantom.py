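"""Phantom generator: label rule, determinism, cohort construction."""

import numpy as np
import pytest

from crl.formats_io import read_manifest
from crl.phantom import (
    ENHANCEMENT_THRESHOLD_HU,
    MAX_SOLID_FRACTION,
    PhantomSpec,
    SolidComponent,
    generate_cohort,
    generate_study,
    simulate_enhancement_check,
    solid_mask_of,
)

GRID = (32, 32, 32)
SP = (1.5, 1.5, 1.5)


def _spec(delta=None, noise=10.0, seed=0, radius=12.0, solid_radius=6.0):
    solid = None
    if delta is not None:
        solid = SolidComponent(
            kind="nodule", baseline_hu=30.0, delta_hu=delta, radius_mm=solid_radius
        )
    return PhantomSpec(
        grid_shape=GRID,
        spacing=SP,
        kidney_semiaxes_mm=(19.0, 15.0, 15.0),  # fits the 48 mm grid extent
        lesion_radius_mm=radius,
        solid=solid,
        noise_sd=noise,
        seed=seed,
    )


def test_fast_in_fast_out_is_malignant():
    spec = _spec(delta=(40.0, 10.0))
    study = generate_study(spec)
    assert spec.label == "malignant" and study.label == "malignant"
    # fast-in, fast-out: corticomedullary gain >= rule, nephrogenic below it
    assert spec.solid.delta_hu[0] >= ENHANCEMENT_THRESHOLD_HU
    assert spec.solid.delta_hu[1] < ENHANCEMENT_THRESHOLD_HU


def test_non_enhancing_component_is_benign():
    assert _spec(delta=(10.0, 5.0)).label == "benign"
    assert _spec(delta=None).label == "benign"


def test_benign_cyst_phases_differ_only_by_noise():
    from scipy import ndimage

    spec = _spec(delta=None, noise=5.0)
    study = generate_study(spec)
    # interior of the mask: free of partial-volume bleed from the
    # phase-dependent kidney rim, so the fluid is phase-constant up to noise
    m = ndimage.binary_erosion(study.mask.astype(bool), iterations=2)
    diff = study.phases[0].voxels[m].mean() - study.phases[1].voxels[m].mean()
    assert abs(diff) < 3 * 5.0 * np.sqrt(2.0 / m.sum()) + 0.2


def test_same_seed_gives_bit_identical_volumes():
    a = generate_study(_spec(delta=(40.0, 10.0), seed=7))
    b = generate_study(_spec(delta=(40.0, 10.0), seed=7))
    for pa, pb in zip(a.phases, b.phases):
        np.testing.assert_array_equal(pa.voxels, pb.voxels)


def test_enhancement_check_recovers_rendered_delta():
    # noiseless rendering: mean corticomedullary HU in the (interior of the)
    # solid region minus the baseline recovers the generated +40 HU gain
    spec = _spec(delta=(40.0, 10.0), noise=0.0, radius=14.0, solid_radius=7.0)
    study = generate_study(spec)
    smask = solid_mask_of(spec)
    delta = simulate_enhancement_check(study, smask, spec.solid.baseline_hu)
    assert delta == pytest.approx(40.0, abs=0.5)


def test_enhancement_check_benign_below_rule():
    spec = _spec(delta=(8.0, 4.0), noise=0.0, radius=14.0, solid_radius=7.0)
    study = generate_study(spec)
    delta = simulate_enhancement_check(
        study, solid_mask_of(spec), spec.solid.baseline_hu
    )
    assert abs(delta) < ENHANCEMENT_THRESHOLD_HU


def test_enhancement_check_empty_mask_errors():
    study = generate_study(_spec())
    with pytest.raises(ValueError, match="empty"):
        simulate_enhancement_check(study, np.zeros(GRID, np.uint8), 30.0)


def test_lesion_escaping_kidney_rejected():
    spec = _spec()
    spec.lesion_center_mm = (2.0, 2.0, 2.0)
    with pytest.raises(ValueError, match="escapes"):
        generate_study(spec)


def test_excessive_solid_fraction_rejected():
    spec = _spec(delta=(40.0, 10.0), radius=8.0)
    spec.solid.radius_mm = 7.5
    with pytest.raises(ValueError, match="solid fraction"):
        generate_study(spec)


def test_cohort_counts_and_label_rule(tmp_path):
    manifest = generate_cohort(
        n=20, prevalence=0.3, out_dir=tmp_path, seed=7, grid_shape=GRID, spacing=SP
    )
    labels = manifest.table["label"].value_counts().to_dict()
    assert labels == {"benign": 14, "malignant": 6}
    assert manifest.prevalence == pytest.approx(0.3)
    # every malignant spec satisfies the >= 15 HU rule pre-noise, every benign
    # spec stays below it, and solid fractions respect the < 25% inclusion rule
    for spec in manifest.specs:
        if spec.label == "malignant":
            assert max(spec.solid.delta_hu) >= ENHANCEMENT_THRESHOLD_HU
        elif spec.solid is not None:
            assert max(spec.solid.delta_hu) < ENHANCEMENT_THRESHOLD_HU
        if spec.solid is not None:
            smask = solid_mask_of(spec)
            study = generate_study(spec)
            frac = smask.sum() / study.mask.sum()
            assert frac < MAX_SOLID_FRACTION
    # manifest file round-trips
    df = read_manifest(manifest.path)
    assert len(df) == 20 and set(df["label"]) == {"benign", "malignant"}


def test_different_seeds_move_lesions(tmp_path):
    a = generate_cohort(4, 0.5, tmp_path / "a", seed=1, grid_shape=GRID, spacing=SP)
    b = generate_cohort(4, 0.5, tmp_path / "b", seed=2, grid_shape=GRID, spacing=SP)
    centers_a = [s.lesion_center_mm for s in a.specs]
    centers_b = [s.lesion_center_mm for s in b.specs]
    assert centers_a != centers_b


def test_degenerate_prevalence_needs_flag(tmp_path):
    with pytest.raises(ValueError, match="degenerate"):
        generate_cohort(4, 0.0, tmp_path, seed=1, grid_shape=GRID, spacing=SP)
    m = generate_cohort(
        4, 0.0, tmp_path, seed=1, grid_shape=GRID, spacing=SP, allow_degenerate=True
    )
    assert set(m.table["label"]) == {"benign"}
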