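"""Shared fixtures: seeded phantom cohorts and trained networks.

The expensive session fixtures (trained P-net/R-net, trained SETD) emulate
the full study at desk scale: 32^3 grids at 1.5 mm spacing, reduced network
widths, and short training schedules. All seeds are fixed so every run of
the suite sees identical data and weights.
"""

from __future__ import annotations

import pytest

from crl.phantom import generate_cohort
from crl.segmodel import SegNetConfig, SegTrainConfig, train_segnet
from crl.setd import SETDConfig, SETDTrainConfig, train_setd

GRID = (32, 32, 32)
SPACING = (1.5, 1.5, 1.5)


@pytest.fixture(scope="session")
def seg_cohort(tmp_path_factory):
    """40-study segmentation cohort: 30 train / 10 held-out."""
    out = tmp_path_factory.mktemp("seg_cohort")
    manifest = generate_cohort(
        n=40, prevalence=0.35, out_dir=out, seed=11, grid_shape=GRID, spacing=SPACING
    )
    df = manifest.table
    return {
        "train": df.iloc[:30].reset_index(drop=True),
        "test": df.iloc[30:].reset_index(drop=True),
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def trained_seg(tmp_path_factory, seg_cohort):
    """P-net and R-net trained on the segmentation cohort's training split."""
    out = tmp_path_factory.mktemp("seg_weights")
    pnet_ckpt, pnet_log = train_segnet(
        seg_cohort["train"],
        "pnet",
        SegTrainConfig(max_epochs=8, patience=7, learning_rate=3e-3, seed=1),
        SegNetConfig(in_channels=1, seed=2),
        out_dir=out,
    )
    rnet_ckpt, rnet_log = train_segnet(
        seg_cohort["train"],
        "rnet",
        SegTrainConfig(max_epochs=8, patience=7, learning_rate=3e-3, seed=3),
        SegNetConfig(in_channels=4, seed=4),
        out_dir=out,
        pnet_checkpoint=pnet_ckpt,
    )
    return {
        "pnet": pnet_ckpt,
        "rnet": rnet_ckpt,
        "pnet_log": pnet_log,
        "rnet_log": rnet_log,
    }


@pytest.fixture(scope="session")
def setd_cohort(tmp_path_factory):
    """60-study classification cohort: 48 train / 12 held-out."""
    out = tmp_path_factory.mktemp("setd_cohort")
    manifest = generate_cohort(
        n=60, prevalence=0.35, out_dir=out, seed=21, grid_shape=GRID, spacing=SPACING
    )
    df = manifest.table
    return {
        "train": df.iloc[:48].reset_index(drop=True),
        "test": df.iloc[48:].reset_index(drop=True),
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def trained_setd(tmp_path_factory, setd_cohort):
    """SETD classifier trained on the classification cohort's training split."""
    out = tmp_path_factory.mktemp("setd_weights")
    ckpt, log = train_setd(
        setd_cohort["train"],
        SETDConfig(stage_widths=(4, 8, 16), crop_size=24, gru_hidden=16, seed=5),
        SETDTrainConfig(seed=6),
        out_dir=out,
    )
    return {"ckpt": ckpt, "log": log}


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small 8-study cohort on 24^3 grids for smoke tests."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest = generate_cohort(
        n=8,
        prevalence=0.5,
        out_dir=out,
        seed=33,
        grid_shape=(24, 24, 24),
        spacing=SPACING,
    )
    return manifest
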