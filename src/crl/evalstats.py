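"""Evaluation metrics and statistics for segmentation and classification.

Segmentation: voxel-level Dice, IOU, sensitivity and specificity, plus
mean +/- sd cohort tables. Classification: case-level confusion counts and
accuracy, ROC/AUC with a seeded stratified-bootstrap 95% CI (DeLong-variance
CI by flag), the DeLong test for two correlated AUCs, and decision-curve
analysis (net benefit against treat-all / treat-none).

Conventions pinned here: probabilities are dichotomized at 0.5 by default
with ties counting positive; a binary (0/1-scored) rater traces the
two-segment ROC through (1 - SPE, SEN), so its AUC is (SEN + SPE) / 2;
Dice = 2*IOU/(1+IOU) is an algebraic identity of the counts; cohort tables
use the sample (n-1) standard deviation; both-empty masks score Dice 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .formats_io import PredictionRecord, read_mask

__all__ = [
    "ConfusionCounts",
    "OverlapMetrics",
    "ROCResult",
    "DeLongResult",
    "NetBenefitCurve",
    "overlap_metrics",
    "confusion_from_predictions",
    "roc_auc",
    "delong_test",
    "delong_components",
    "decision_curve",
    "evaluate_segmentation_cohort",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass
class OverlapMetrics:
    dice: float
    iou: float
    sen: float
    spe: float


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    degenerate: bool = False  # zero paired variance


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float


# ---------------------------------------------------------------------------
# segmentation overlap
# ---------------------------------------------------------------------------


def overlap_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> OverlapMetrics:
    """Voxel-level Dice / IOU / SEN / SPE between two binary grids.

    Dice = 2|A∩B|/(|A|+|B|), IOU = |A∩B|/|A∪B|; both-empty masks score
    Dice = IOU = 1 (and SEN = 1 with an empty truth).
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(truth_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = int((~a & ~b).sum())
    union = tp + fp + fn
    dice = 1.0 if (tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    iou = 1.0 if union == 0 else tp / union
    sen = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    spe = 1.0 if (tn + fp) == 0 else tn / (tn + fp)
    return OverlapMetrics(dice=dice, iou=iou, sen=sen, spe=spe)


# ---------------------------------------------------------------------------
# case-level classification
# ---------------------------------------------------------------------------


def _labels_scores(records: Sequence[PredictionRecord]):
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.study_id} is unlabeled")
    y = np.array([r.label for r in records], dtype=int)
    s = np.array([r.prob_malignant for r in records], dtype=float)
    return y, s


def confusion_from_predictions(
    records: Sequence[PredictionRecord], threshold: float = 0.5
) -> ConfusionCounts:
    """Dichotomize at ``threshold`` (ties positive) and count TP/FP/TN/FN."""
    y, s = _labels_scores(records)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


def roc_auc(
    records: Sequence[PredictionRecord],
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ROCResult:
    """Empirical ROC and AUC with a 95% CI.

    AUC is the trapezoidal area under the empirical ROC (ties contribute
    1/2), so a binary 0/1 rater scores (SEN + SPE)/2. The default CI is a
    seeded stratified bootstrap percentile interval; ``ci_method='delong'``
    uses the DeLong variance instead.
    """
    y, s = _labels_scores(records)
    if len(set(y)) < 2:
        raise ValueError("ROC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    if ci_method == "delong":
        _, var = delong_components(s, y)
        half = norm.ppf(0.975) * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    else:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            yy = np.concatenate([y[bp], y[bn]])
            ss = np.concatenate([s[bp], s[bn]])
            aucs[b] = roc_auc_score(yy, ss)
        ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
    return ROCResult(auc=auc, ci95=ci, fpr=fpr, tpr=tpr)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """Mid-rank (fast DeLong) structural components of one AUC.

    Returns ((v10, v01), var) where v10/v01 are the per-positive and
    per-negative placement values and var the DeLong variance of the AUC.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError(
            "DeLong variance needs at least 2 cases per class "
            f"(got {m} positive, {n} negative)"
        )
    all_s = np.concatenate([pos, neg])
    r_all = rankdata(all_s)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    # placements: fraction of the other class below each score (ties = 1/2)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return (v10, v01), float(var)


def delong_test(
    records_a: Sequence[PredictionRecord],
    records_b: Sequence[PredictionRecord],
) -> DeLongResult:
    """DeLong comparison of two correlated AUCs on the same cases.

    Records must be paired: same study ids (same order) and same labels.
    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov); two-sided normal p.
    Degenerate zero-variance comparisons (e.g. a model against itself)
    report p = 1 with ``degenerate=True``.
    """
    if len(records_a) != len(records_b):
        raise ValueError("unpaired inputs: different case counts")
    for ra, rb in zip(records_a, records_b):
        if ra.study_id != rb.study_id or ra.label != rb.label:
            raise ValueError(f"unpaired inputs at study {ra.study_id}")
    y, sa = _labels_scores(records_a)
    _, sb = _labels_scores(records_b)
    if len(set(y)) < 2:
        raise ValueError("both classes required")

    (v10a, v01a), var_a = delong_components(sa, y)
    (v10b, v01b), var_b = delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    cov = (
        np.cov(v10a, v10b, ddof=1)[0, 1] / m + np.cov(v01a, v01b, ddof=1)[0, 1] / n
    )
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-15:
        return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=0.0, p=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# decision curve analysis
# ---------------------------------------------------------------------------


def decision_curve(
    records: Sequence[PredictionRecord],
    thresholds: Optional[np.ndarray] = None,
) -> NetBenefitCurve:
    """Net benefit of the model vs treat-all and treat-none strategies.

    nb_model(t) = (TP - FP * t/(1-t)) / n with "positive" meaning prob >= t;
    nb_all(t) = pi - (1 - pi) * t/(1-t) with pi the prevalence; nb_none = 0.
    """
    y, s = _labels_scores(records)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    pi = y.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        nb_model[i] = (tp - fp * odds[i]) / n
    nb_all = pi - (1.0 - pi) * odds
    return NetBenefitCurve(
        thresholds=thresholds,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(thresholds),
        prevalence=float(pi),
    )


# ---------------------------------------------------------------------------
# cohort-level segmentation report
# ---------------------------------------------------------------------------


def evaluate_segmentation_cohort(
    manifest: pd.DataFrame,
    pred_masks: dict[str, np.ndarray] | str,
    out_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Per-study overlap metrics plus a mean +/- sd summary row.

    ``pred_masks`` maps study_id to a binary grid, or names a directory
    containing ``<study_id>_pred.nii.gz`` files. Sample (n-1) standard
    deviation; a single study reports sd 0 with the ``single_study`` flag.
    """
    rows = []
    for _, row in manifest.iterrows():
        sid = str(row["study_id"])
        truth = read_mask(row["mask_path"])
        if isinstance(pred_masks, dict):
            if sid not in pred_masks:
                raise ValueError(f"missing prediction for study {sid}")
            pred = pred_masks[sid]
        else:
            from pathlib import Path

            p = Path(pred_masks) / f"{sid}_pred.nii.gz"
            if not p.exists():
                raise ValueError(f"missing prediction for study {sid}: {p}")
            pred = read_mask(p)
        m = overlap_metrics(pred, truth)
        rows.append(
            {"study_id": sid, "dice": m.dice, "iou": m.iou, "sen": m.sen, "spe": m.spe}
        )
    df = pd.DataFrame(rows)
    single = len(df) == 1
    summary = {
        "study_id": "mean±sd",
        **{
            c: df[c].mean() for c in ("dice", "iou", "sen", "spe")
        },
    }
    sds = {
        f"{c}_sd": (0.0 if single else float(df[c].std(ddof=1)))
        for c in ("dice", "iou", "sen", "spe")
    }
    out = df.copy()
    for k, v in sds.items():
        summary[k] = v
    out = pd.concat([out, pd.DataFrame([summary])], ignore_index=True)
    out.attrs["single_study"] = single
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
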