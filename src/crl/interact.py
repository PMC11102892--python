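"""Simulated radiologist ("robot user") and the iterative refinement loop.

The robot inspects a predicted mask against the ground truth, finds the
connected components of mis-segmented voxels, and places one indicator
point per component — positive clicks inside false-negative regions, negative
clicks inside false-positive regions — at each component's most interior
voxel (the maximum of the Euclidean distance transform, lexicographic
``(z, y, x)`` tie-break). Those clicks drive the P-net -> R-net loop:
interactions accumulate across rounds, R-net is re-run, and the loop stops
at ``max_rounds`` or when the Dice improvement drops below ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .formats_io import InteractionSet, MultiPhaseStudy
from .segmodel import (
    SegNetConfig,
    UNet3D,
    pnet_predict,
    rnet_refine,
    threshold_mask,
)

__all__ = ["RefinementTrace", "robot_click", "refine_loop"]


@dataclass
class RefinementTrace:
    """Per-round record of the interactive refinement of one study."""

    rounds: list[dict] = field(default_factory=list)
    max_rounds: int = 4
    clicks_per_round: int = 3

    def add(self, iset: InteractionSet, dice_before: float, dice_after: float):
        if not (0.0 <= dice_before <= 1.0 and 0.0 <= dice_after <= 1.0):
            raise ValueError("Dice values must lie in [0, 1]")
        if len(self.rounds) >= self.max_rounds + 1:
            raise ValueError("trace longer than max_rounds")
        self.rounds.append(
            {
                "interactions": iset,
                "dice_before": float(dice_before),
                "dice_after": float(dice_after),
            }
        )


def _component_clicks(error_mask: np.ndarray, k: int, spacing) -> list[tuple[int, int, int]]:
    """One most-interior click for each of the k largest error components."""
    labels, n = ndimage.label(error_mask)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # k largest components; stable order for ties (smaller label id first)
    order = np.argsort(-sizes, kind="stable")[:k] + 1
    edt = ndimage.distance_transform_edt(error_mask, sampling=spacing)
    clicks = []
    for lab in order:
        comp = labels == lab
        d = np.where(comp, edt, -1.0)
        # lexicographic (z, y, x) tie-break among voxels attaining the max:
        # argwhere enumerates in raster order, so the first hit is minimal
        cand = np.argwhere(d == d.max())
        clicks.append(tuple(int(c) for c in cand[0]))
    return clicks


def robot_click(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    k: int = 3,
    spacing=None,
) -> InteractionSet:
    """Place up to ``k`` positive and ``k`` negative indicator points.

    Positive clicks go to the k largest connected false-negative components
    (truth and not predicted), negative clicks to the k largest false-positive
    components, each at the voxel maximizing the interior Euclidean distance
    transform (``spacing``-aware when given). Equal masks yield an empty set.
    """
    pred_mask = np.asarray(pred_mask).astype(bool)
    truth_mask = np.asarray(truth_mask).astype(bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {truth_mask.shape}"
        )
    spacing = tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)
    fn = truth_mask & ~pred_mask
    fp = pred_mask & ~truth_mask
    return InteractionSet(
        positive=_component_clicks(fn, k, spacing),
        negative=_component_clicks(fp, k, spacing),
    )


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else float(2.0 * (a & b).sum() / denom)


def refine_loop(
    study: MultiPhaseStudy,
    pnet: UNet3D,
    pnet_cfg: SegNetConfig,
    rnet: UNet3D,
    rnet_cfg: SegNetConfig,
    truth_mask: Optional[np.ndarray] = None,
    max_rounds: int = 4,
    k: int = 3,
    epsilon: float = 1e-3,
    manual_interactions: Optional[list[InteractionSet]] = None,
) -> tuple[RefinementTrace, np.ndarray]:
    """Run the interactive refinement of one study; returns (trace, mask).

    Round 0 is the P-net prediction. Each later round adds robot clicks
    against ``truth_mask`` (or consumes the next manual InteractionSet),
    accumulates them with all earlier interactions, and re-runs R-net. Stops
    after ``max_rounds`` refinement rounds, when no mis-segmentation is left,
    or when the Dice improvement falls below ``epsilon`` (robot mode only —
    Dice needs the ground truth).
    """
    if truth_mask is None and manual_interactions is None:
        raise ValueError(
            "robot mode requires truth_mask; otherwise pass manual_interactions"
        )
    vol = study.phases[0]
    trace = RefinementTrace(max_rounds=max_rounds, clicks_per_round=k)
    prob0 = pnet_predict(vol, pnet, pnet_cfg)
    current_mask = threshold_mask(prob0)

    def dice_now(m):
        return _dice(m, truth_mask) if truth_mask is not None else np.nan

    d0 = dice_now(current_mask)
    trace.add(InteractionSet(), d0 if truth_mask is not None else 0.0,
              d0 if truth_mask is not None else 0.0)
    if max_rounds == 0:
        return trace, current_mask

    accumulated = InteractionSet()
    prev_dice = d0
    for rnd in range(max_rounds):
        if truth_mask is not None:
            new = robot_click(current_mask, truth_mask, k=k, spacing=vol.spacing)
            if len(new) == 0:  # perfect segmentation: nothing to indicate
                trace.add(new, prev_dice, prev_dice)
                break
        else:
            if rnd >= len(manual_interactions):
                break
            new = manual_interactions[rnd]
        accumulated = accumulated.merged(new)
        prob = rnet_refine(vol, prob0, accumulated, rnet, rnet_cfg)
        current_mask = threshold_mask(prob)
        d = dice_now(current_mask)
        trace.add(new, prev_dice, d if truth_mask is not None else 0.0)
        if truth_mask is not None:
            if d - prev_dice < epsilon:
                break
            prev_dice = d
    return trace, current_mask
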