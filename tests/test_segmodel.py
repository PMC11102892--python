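"""P-net / R-net contracts: shapes, probabilities, training smoke tests."""

import numpy as np
import pytest

from crl.formats_io import InteractionSet, PhaseVolume, load_study
from crl.segmodel import (
    SegNetConfig,
    SegTrainConfig,
    build_segnet,
    load_checkpoint,
    normalize_hu,
    pnet_predict,
    rnet_refine,
    threshold_mask,
    train_segnet,
)

SP = (1.5, 1.5, 1.5)


def test_config_channel_invariants():
    with pytest.raises(ValueError):
        SegNetConfig(in_channels=2)
    with pytest.raises(ValueError):
        SegTrainConfig(max_epochs=2, patience=2)


def test_normalize_hu_window():
    x = np.array([-200.0, -100.0, 100.0, 300.0, 500.0])
    np.testing.assert_allclose(normalize_hu(x), [0.0, 0.0, 0.5, 1.0, 1.0])


def test_zeroed_head_outputs_half_everywhere():
    cfg = SegNetConfig(in_channels=1, base_width=4, depth=3, seed=0)
    net = build_segnet(cfg)
    net.out_conv.params["w"][...] = 0.0
    net.out_conv.params["b"][...] = 0.0
    vol = PhaseVolume(np.random.default_rng(0).normal(50, 40, (16, 16, 16)), SP)
    prob = pnet_predict(vol, net, cfg)
    np.testing.assert_array_equal(prob, np.full((16, 16, 16), 0.5, np.float32))


def test_non_divisible_shape_padded_and_cropped_back():
    cfg = SegNetConfig(in_channels=1, base_width=4, depth=4, seed=0)
    net = build_segnet(cfg)
    vol = PhaseVolume(np.random.default_rng(1).normal(50, 40, (15, 16, 17)), SP)
    prob = pnet_predict(vol, net, cfg)
    assert prob.shape == (15, 16, 17)
    assert np.all((prob >= 0) & (prob <= 1))


def test_threshold_ties_count_as_foreground():
    prob = np.array([[[0.49, 0.5, 0.51]]])
    np.testing.assert_array_equal(threshold_mask(prob), [[[0, 1, 1]]])


def test_rnet_accepts_empty_interactions_and_rejects_bad_shapes():
    cfg = SegNetConfig(in_channels=4, base_width=4, depth=3, seed=0)
    net = build_segnet(cfg)
    vol = PhaseVolume(np.random.default_rng(2).normal(50, 40, (16, 16, 16)), SP)
    prob = rnet_refine(vol, np.full((16, 16, 16), 0.3, np.float32), InteractionSet(), net, cfg)
    assert prob.shape == (16, 16, 16)
    with pytest.raises(ValueError, match="shape"):
        rnet_refine(vol, np.zeros((8, 8, 8), np.float32), InteractionSet(), net, cfg)


def test_translation_moves_prediction_with_the_image():
    # convolutional sanity: shifting the input by the pooling period shifts
    # the output correspondingly, up to border/normalization effects
    cfg = SegNetConfig(in_channels=1, base_width=4, depth=3, seed=1)
    net = build_segnet(cfg)
    rng = np.random.default_rng(2)
    img = np.zeros((32, 32, 32), np.float32)
    img[10:18, 12:20, 8:16] = 150.0
    img += rng.normal(0, 5, img.shape).astype(np.float32)
    p1 = pnet_predict(PhaseVolume(img, SP), net, cfg)
    p2 = pnet_predict(PhaseVolume(np.roll(img, 4, axis=0), SP), net, cfg)
    interior = np.s_[10:-10, 8:-8, 8:-8]
    diff = np.abs(np.roll(p1, 4, axis=0)[interior] - p2[interior])
    assert diff.mean() < 0.1


def _train_smoke(tmp_path, which, pnet_ckpt=None, seed=0):
    from crl.phantom import generate_cohort

    cohort = generate_cohort(
        n=2, prevalence=0.5, out_dir=tmp_path / f"c{seed}", seed=41,
        grid_shape=(24, 24, 24), spacing=SP,
    )
    return train_segnet(
        cohort.table,
        which,
        SegTrainConfig(max_epochs=2, patience=1, seed=seed),
        SegNetConfig(in_channels=1 if which == "pnet" else 4, base_width=4, depth=3, seed=seed),
        out_dir=tmp_path / f"w{seed}",
        pnet_checkpoint=pnet_ckpt,
    )


def test_training_smoke_checkpoint_and_log(tmp_path):
    ckpt, log = _train_smoke(tmp_path, "pnet")
    assert ckpt.exists()
    assert len(log) == 2 and {"epoch", "train_loss", "val_dice"} <= set(log.columns)
    model, cfg = load_checkpoint(ckpt)
    assert cfg.in_channels == 1


def test_training_is_seeded_deterministic(tmp_path):
    _, log_a = _train_smoke(tmp_path / "a", "pnet", seed=7)
    _, log_b = _train_smoke(tmp_path / "b", "pnet", seed=7)
    assert log_a["train_loss"].tolist() == log_b["train_loss"].tolist()


def test_rnet_requires_pnet_checkpoint(tmp_path):
    with pytest.raises(ValueError, match="P-net checkpoint"):
        _train_smoke(tmp_path, "rnet", pnet_ckpt=None)


def test_trained_pnet_beats_floor_on_held_out_phantoms(trained_seg, seg_cohort):
    from crl.evalstats import overlap_metrics

    model, cfg = load_checkpoint(trained_seg["pnet"])
    dices = []
    for _, row in seg_cohort["test"].iterrows():
        s = load_study(row)
        prob = pnet_predict(s.phases[0], model, cfg)
        assert np.all((prob >= 0) & (prob <= 1))
        dices.append(overlap_metrics(threshold_mask(prob), s.mask).dice)
    assert float(np.mean(dices)) > 0.6


def test_click_in_false_negative_region_raises_probability(trained_seg, seg_cohort):
    from crl.interact import robot_click

    pnet, pcfg = load_checkpoint(trained_seg["pnet"])
    rnet, rcfg = load_checkpoint(trained_seg["rnet"])
    raised = 0
    checked = 0
    for _, row in seg_cohort["test"].iterrows():
        s = load_study(row)
        prob0 = pnet_predict(s.phases[0], pnet, pcfg)
        iset = robot_click(threshold_mask(prob0), s.mask, k=3, spacing=s.spacing)
        if not iset.positive:
            continue
        refined = rnet_refine(s.phases[0], prob0, iset, rnet, rcfg)
        for click in iset.positive:
            checked += 1
            if refined[click] > prob0[click]:
                raised += 1
    assert checked > 0
    assert raised / checked > 0.75  # trained R-net corrects the indicated FNs
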