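"""Evaluation statistics: overlap metrics, ROC/AUC, DeLong, decision curves.

The worked classification examples use confusion counts reported for
radiologist Bosniak-2019 dichotomization and the SETD classifier on
multicenter cohorts (validation: 11 malignant / 72 benign; test: 17
malignant / 145 benign) and check that the module recovers the published
accuracy and binary-rater AUC values from raw counts.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crl.evalstats import (
    ConfusionCounts,
    confusion_from_predictions,
    decision_curve,
    delong_components,
    delong_test,
    evaluate_segmentation_cohort,
    overlap_metrics,
    roc_auc,
)
from crl.formats_io import PredictionRecord


def binary_records(tp, fn, tn, fp):
    """Case-level records of a binary (0/1-scored) rater."""
    recs = []
    recs += [PredictionRecord(f"tp{i}", 1.0, 1) for i in range(tp)]
    recs += [PredictionRecord(f"fn{i}", 0.0, 1) for i in range(fn)]
    recs += [PredictionRecord(f"tn{i}", 0.0, 0) for i in range(tn)]
    recs += [PredictionRecord(f"fp{i}", 1.0, 0) for i in range(fp)]
    return recs


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def test_overlap_identity_and_disjoint_and_worked_example():
    a = np.zeros((4, 4, 4), np.uint8)
    a[:2] = 1
    m = overlap_metrics(a, a)
    assert (m.dice, m.iou, m.sen, m.spe) == (1.0, 1.0, 1.0, 1.0)

    # |A|=4, |B|=6, |A∩B|=3
    pred = np.zeros(16, np.uint8)
    truth = np.zeros(16, np.uint8)
    pred[:4] = 1
    truth[1:7] = 1
    m = overlap_metrics(pred.reshape(4, 2, 2), truth.reshape(4, 2, 2))
    assert m.dice == pytest.approx(0.6)
    assert m.iou == pytest.approx(3 / 7)

    b = np.zeros((4, 4, 4), np.uint8)
    b[2:] = 1
    m = overlap_metrics(a, b)
    assert m.dice == 0.0 and m.iou == 0.0 and m.sen == 0.0


def test_overlap_empty_conventions_and_shape_check():
    empty = np.zeros((3, 3, 3), np.uint8)
    m = overlap_metrics(empty, empty)
    assert m.dice == 1.0 and m.iou == 1.0
    with pytest.raises(ValueError, match="shapes differ"):
        overlap_metrics(empty, np.zeros((3, 3, 4), np.uint8))


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**24 - 1))
def test_dice_iou_algebraic_identity(bits):
    rng = np.random.default_rng(bits)
    a = rng.uniform(size=(5, 5, 5)) > 0.5
    b = rng.uniform(size=(5, 5, 5)) > 0.5
    m = overlap_metrics(a, b)
    assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou))


# ---------------------------------------------------------------------------
# confusion counts / accuracy (published worked examples)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tp,fn,tn,fp,acc",
    [
        (11, 0, 49, 23, 60 / 83),  # Bosniak rater, validation cohort
        (11, 0, 65, 7, 76 / 83),  # SETD, validation cohort
        (15, 2, 124, 21, 139 / 162),  # Bosniak rater, test cohort
    ],
)
def test_accuracy_from_published_confusion_counts(tp, fn, tn, fp, acc):
    conf = confusion_from_predictions(binary_records(tp, fn, tn, fp))
    assert (conf.tp, conf.fn, conf.tn, conf.fp) == (tp, fn, tn, fp)
    assert conf.acc == pytest.approx(acc)
    assert conf.sen == pytest.approx(tp / (tp + fn))
    assert conf.spe == pytest.approx(tn / (tn + fp))


def test_confusion_requires_labels_and_positive_total():
    with pytest.raises(ValueError, match="unlabeled"):
        confusion_from_predictions([PredictionRecord("a", 0.4)])
    with pytest.raises(ValueError):
        ConfusionCounts(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tp,fn,tn,fp,expected",
    [
        (11, 0, 49, 23, (1.0 + 49 / 72) / 2),  # published 0.840
        (15, 2, 124, 21, (15 / 17 + 124 / 145) / 2),  # published 0.869
    ],
)
def test_binary_rater_auc_is_mean_of_sen_and_spe(tp, fn, tn, fp, expected):
    r = roc_auc(binary_records(tp, fn, tn, fp), n_boot=50, seed=0)
    assert r.auc == pytest.approx(expected, abs=1e-12)
    assert round(r.auc, 3) in (0.840, 0.869)


def test_perfectly_separated_scores():
    recs = [PredictionRecord(f"p{i}", 0.9, 1) for i in range(5)] + [
        PredictionRecord(f"n{i}", 0.1, 0) for i in range(5)
    ]
    r = roc_auc(recs, n_boot=100, seed=0)
    assert r.auc == 1.0 and r.ci95 == (1.0, 1.0)
    assert r.fpr[0] == 0.0 and r.tpr[-1] == 1.0


def test_auc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    s = rng.uniform(size=30)
    a1 = roc_auc([PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(s, y))], 50, 0).auc
    s2 = 1 / (1 + np.exp(-5 * (s - 0.5)))  # strictly monotone
    a2 = roc_auc([PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(s2, y))], 50, 0).auc
    assert a1 == pytest.approx(a2)


def test_bootstrap_ci_contains_point_and_shrinks_with_n():
    rng = np.random.default_rng(1)

    def make(n):
        y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        s = np.clip(y * 0.3 + rng.uniform(size=n) * 0.7, 0, 1)
        return [PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(s, y))]

    small = roc_auc(make(40), n_boot=400, seed=2)
    large = roc_auc(make(160), n_boot=400, seed=2)
    assert small.ci95[0] <= small.auc <= small.ci95[1]
    assert large.ci95[0] <= large.auc <= large.ci95[1]
    assert (large.ci95[1] - large.ci95[0]) < (small.ci95[1] - small.ci95[0])


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([PredictionRecord("a", 0.2, 1), PredictionRecord("b", 0.7, 1)], 10, 0)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def brute_force_placements(scores, labels):
    """U-statistic placements over all positive-negative pairs (oracle)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def test_delong_components_match_brute_force_u_statistics():
    rng = np.random.default_rng(3)
    for trial in range(20):
        m = rng.integers(2, 6)
        n = rng.integers(2, 6)
        labels = np.array([1] * m + [0] * n)
        scores = np.round(rng.uniform(size=m + n), 1)  # coarse grid forces ties
        (v10, v01), var = delong_components(scores, labels)
        bv10, bv01 = brute_force_placements(scores, labels)
        np.testing.assert_allclose(v10, bv10, atol=1e-10)
        np.testing.assert_allclose(v01, bv01, atol=1e-10)
        bvar = np.var(bv10, ddof=1) / m + np.var(bv01, ddof=1) / n
        assert var == pytest.approx(bvar, abs=1e-10)


def test_delong_self_comparison_is_degenerate_p_one():
    recs = [
        PredictionRecord("a", 0.9, 1),
        PredictionRecord("b", 0.4, 1),
        PredictionRecord("c", 0.3, 0),
        PredictionRecord("d", 0.2, 0),
    ]
    res = delong_test(recs, recs)
    assert res.p == 1.0 and res.z == 0.0 and res.degenerate
    assert res.auc_a == res.auc_b


def test_delong_z_sign_matches_auc_difference():
    rng = np.random.default_rng(4)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0])
    good = np.clip(y * 0.5 + rng.uniform(size=12) * 0.5, 0, 1)
    binary = (rng.uniform(size=12) > 0.4).astype(float)
    ra = [PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(good, y))]
    rb = [PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(binary, y))]
    res = delong_test(ra, rb)
    assert np.sign(res.z) == np.sign(res.auc_a - res.auc_b)
    assert 0.0 <= res.p <= 1.0


def test_delong_needs_two_cases_per_class():
    with pytest.raises(ValueError, match="2 cases per class"):
        delong_components(np.array([0.9, 0.3, 0.2]), np.array([1, 0, 0]))


def test_delong_rejects_unpaired_inputs():
    ra = [PredictionRecord("a", 0.5, 1), PredictionRecord("b", 0.4, 0)]
    rb = [PredictionRecord("a", 0.5, 1), PredictionRecord("X", 0.4, 0)]
    with pytest.raises(ValueError, match="unpaired"):
        delong_test(ra, rb)
    with pytest.raises(ValueError, match="unpaired"):
        delong_test(ra, ra[:1])


# ---------------------------------------------------------------------------
# decision curve analysis
# ---------------------------------------------------------------------------


def test_dca_identities_and_perfect_predictor():
    rng = np.random.default_rng(5)
    y = np.array([1] * 6 + [0] * 14)
    perfect = [PredictionRecord(str(i), float(t), int(t)) for i, t in enumerate(y)]
    curve = decision_curve(perfect)
    pi = 6 / 20
    np.testing.assert_array_equal(curve.nb_none, 0.0)
    np.testing.assert_allclose(
        curve.nb_all, pi - (1 - pi) * curve.thresholds / (1 - curve.thresholds)
    )
    np.testing.assert_allclose(curve.nb_model, pi)
    # treat-all approaches prevalence as t -> 0+
    assert curve.nb_all[0] == pytest.approx(pi, abs=0.01)
    # the perfect predictor dominates treat-all at every t > 0
    assert np.all(curve.nb_model >= curve.nb_all - 1e-12)


def test_dca_matches_direct_recount():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 20)
    s = rng.uniform(size=20)
    recs = [PredictionRecord(str(i), p, int(t)) for i, (p, t) in enumerate(zip(s, y))]
    ts = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
    curve = decision_curve(recs, ts)
    for i, t in enumerate(ts):
        tp = int(((s >= t) & (y == 1)).sum())
        fp = int(((s >= t) & (y == 0)).sum())
        assert curve.nb_model[i] == pytest.approx((tp - fp * t / (1 - t)) / 20)


def test_dca_threshold_domain():
    recs = [PredictionRecord("a", 0.5, 1), PredictionRecord("b", 0.4, 0)]
    with pytest.raises(ValueError, match="strictly inside"):
        decision_curve(recs, np.array([0.0, 0.5]))


# ---------------------------------------------------------------------------
# cohort segmentation report
# ---------------------------------------------------------------------------


def _mask_pair(dice_target):
    truth = np.zeros((8, 8, 8), np.uint8)
    truth.flat[:10] = 1
    pred = np.zeros((8, 8, 8), np.uint8)
    inter = round(dice_target * 10)
    pred.flat[:inter] = 1
    pred.flat[10 : 10 + (10 - inter)] = 1
    return pred, truth  # |A| = |B| = 10, dice = inter / 10


def test_cohort_report_mean_and_sample_sd(tmp_path):
    import pandas as pd

    from crl.formats_io import write_mask

    rows = []
    preds = {}
    for i, d in enumerate([0.8, 0.9]):
        pred, truth = _mask_pair(d)
        mp = write_mask(truth, (1, 1, 1), tmp_path / f"s{i}_mask.nii.gz")
        rows.append(
            {
                "study_id": f"s{i}",
                "label": "benign",
                "phase1_path": "x",
                "phase2_path": "x",
                "mask_path": str(mp),
            }
        )
        preds[f"s{i}"] = pred
    manifest = pd.DataFrame(rows)
    table = evaluate_segmentation_cohort(manifest, preds)
    summary = table.iloc[-1]
    assert summary["dice"] == pytest.approx(0.85)
    assert summary["dice_sd"] == pytest.approx(np.std([0.8, 0.9], ddof=1), abs=1e-6)

    single = evaluate_segmentation_cohort(manifest.iloc[:1], preds)
    assert single.attrs["single_study"] and single.iloc[-1]["dice_sd"] == 0.0

    with pytest.raises(ValueError, match="missing prediction"):
        evaluate_segmentation_cohort(manifest, {"s0": preds["s0"]})
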