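"""SETD: spatial encoder + temporal decoder malignancy classifier.

Each CT phase of a study is cropped to a cubic patch around the lesion-mask
centroid, HU-normalized, and passed through a shared residual 3D
convolutional encoder; global average pooling yields one feature vector per
phase. The per-phase features form a short temporal sequence in fixed order
(corticomedullary, then nephrogenic) that a two-layer GRU decodes; the final
hidden state goes through a linear layer and sigmoid to give the probability
of malignancy. Enhancement *trajectories* across phases (fast-in/fast-out vs
gradual vs non-enhancing) are exactly what the recurrent decoder can read
and a single-phase model cannot.

Training uses class-weighted binary cross-entropy (weights default to
inverse class frequency) with early stopping on validation AUC, restoring
the best weights — the standard recipe against overfitting on small,
imbalanced cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .formats_io import (
    FormatError,
    MultiPhaseStudy,
    PredictionRecord,
    load_study,
    write_predictions,
)
from .segmodel import DEFAULT_HU_WINDOW, normalize_hu

__all__ = [
    "SETDConfig",
    "SETDTrainConfig",
    "SETDNet",
    "build_setd",
    "setd_forward",
    "train_setd",
    "predict_cohort",
    "save_setd",
    "load_setd",
    "crop_around_mask",
]


@dataclass
class SETDConfig:
    """Architecture config for the SETD classifier.

    ``stage_blocks`` counts residual blocks per encoder stage; the default is
    a reduced-depth encoder for CPU training, and ``(3, 4, 6, 3)`` — the
    classic deep residual stage pattern — is available by configuration with
    a fourth width. ``pretrained`` optionally names a weights file.
    """

    stage_widths: tuple[int, ...] = (8, 16, 32)
    stage_blocks: tuple[int, ...] = (1, 1, 1)
    gru_hidden: int = 32
    gru_layers: int = 2
    encoder_norm: bool = False  # instance norm in the encoder (off: preserve HU scale)
    lowpass_init: bool = True  # box-filter/identity-biased encoder init
    crop_size: int = 48
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    pretrained: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.gru_layers != 2:
            raise ValueError("the temporal decoder uses exactly two GRU layers")
        if len(self.stage_widths) != len(self.stage_blocks):
            raise ValueError("stage_widths and stage_blocks must align")
        if self.crop_size % 2 ** (len(self.stage_widths) - 1) != 0:
            raise ValueError("crop_size must be divisible by 2^(n_stages-1)")


@dataclass
class SETDTrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 1e-3
    max_epochs: int = 60
    patience: int = 20  # early-stop patience on validation AUC
    batch_size: int = 4
    val_fraction: float = 0.2
    class_weights: Optional[tuple[float, float]] = None  # (w_benign, w_malignant)
    augment: bool = True  # random flips + crop-centre jitter during training
    jitter_vox: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be > 0")


class _Identity(nn.Module):
    def forward(self, x):
        return x

    def backward(self, gy):
        return gy


class _ResBlock(nn.Module):
    """Basic residual block: conv-[IN]-ReLU-conv-[IN] + identity, ReLU.

    Normalization is optional: the malignancy cue is the *absolute* HU level
    of the solid component, which per-sample normalization would erase, so
    the encoder defaults to norm-free blocks with a 1/2-scaled residual
    branch for stability.
    """

    def __init__(self, c, rng, dtype=np.float32, norm=False):
        super().__init__()
        mk_norm = (lambda: nn.InstanceNorm3d(c, dtype)) if norm else _Identity
        self.c1 = nn.Conv3d(c, c, 3, rng, dtype)
        self.n1 = mk_norm()
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv3d(c, c, 3, rng, dtype)
        if not norm:
            self.c2.params["w"] *= 0.5
        self.n2 = mk_norm()
        self.r2 = nn.ReLU()
        self.children.extend([self.c1, self.n1, self.r1, self.c2, self.n2, self.r2])

    def forward(self, x):
        h = self.r1.forward(self.n1.forward(self.c1.forward(x)))
        h = self.n2.forward(self.c2.forward(h))
        return self.r2.forward(x + h)

    def backward(self, gy):
        g = self.r2.backward(gy)
        gh = self.n1.backward(
            self.r1.backward(self.c2.backward(self.n2.backward(g)))
        )
        return g + self.c1.backward(gh)


class SETDNet(nn.Module):
    """Shared-weight per-phase encoder + 2-layer GRU + linear sigmoid head."""

    def __init__(self, cfg: SETDConfig, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        widths = cfg.stage_widths
        stem_conv = nn.Conv3d(1, widths[0], 3, rng, dtype)
        if cfg.lowpass_init:
            # bias the stem toward local-mean (box) filters: pooled encoder
            # features then approximate lesion intensity statistics already at
            # initialization, which the temporal decoder can combine linearly;
            # training refines from there instead of searching from scratch
            stem_conv.params["w"] *= 0.3
            stem_conv.params["w"] += 1.0 / 27.0
        self.stem = [stem_conv]
        if cfg.encoder_norm:
            self.stem.append(nn.InstanceNorm3d(widths[0], dtype))
        self.stem.append(nn.ReLU())
        self.children.extend(self.stem)
        self.stages: list[list[nn.Module]] = []
        for i, (w, nb) in enumerate(zip(widths, cfg.stage_blocks)):
            stage: list[nn.Module] = []
            if i > 0:
                trans = nn.Conv3d(widths[i - 1], w, 1, rng, dtype)
                if cfg.lowpass_init:
                    # partial identity so intensity features pass through widening
                    trans.params["w"] *= 0.3
                    for j in range(w):
                        trans.params["w"][j, j % widths[i - 1], 0, 0, 0] += 1.0
                stage += [trans]
                if cfg.encoder_norm:
                    stage.append(nn.InstanceNorm3d(w, dtype))
                stage += [nn.ReLU(), nn.MaxPool2x()]
            stage += [_ResBlock(w, rng, dtype, cfg.encoder_norm) for _ in range(nb)]
            self.children.extend(stage)
            self.stages.append(stage)
        self.gru = nn.GRU(2 * widths[-1], cfg.gru_hidden, cfg.gru_layers, rng, dtype)
        self.head = nn.Linear(cfg.gru_hidden, 1, rng, dtype)
        self.children.extend([self.gru, self.head])

    # -- encoder ------------------------------------------------------------

    def encode(self, patch: np.ndarray) -> np.ndarray:
        """(1, S, S, S) normalized patch -> feature vector (2 * widths[-1],).

        The spatial feature map is reduced by global average *and* global max
        pooling, concatenated: the average summarizes the bulk appearance,
        the max preserves small high-intensity structures (enhancing mural
        nodules and septa occupy only a few voxels of the lesion crop and
        would otherwise be diluted away).
        """
        x = patch
        for lay in self.stem:
            x = lay.forward(x)
        for stage in self.stages:
            for lay in stage:
                x = lay.forward(x)
        c = x.shape[0]
        self._enc_spatial = x.shape[1:]
        flat = x.reshape(c, -1)
        self._enc_argmax = flat.argmax(axis=1)
        return np.concatenate([flat.mean(axis=1), flat[np.arange(c), self._enc_argmax]])

    def encode_backward(self, gfeat: np.ndarray) -> None:
        c = gfeat.shape[0] // 2
        nvox = int(np.prod(self._enc_spatial))
        g = np.broadcast_to(
            (gfeat[:c] / nvox).reshape(-1, 1, 1, 1), (c,) + self._enc_spatial
        ).astype(gfeat.dtype).copy()
        gflat = g.reshape(c, -1)
        gflat[np.arange(c), self._enc_argmax] += gfeat[c:]
        for stage in reversed(self.stages):
            for lay in reversed(stage):
                g = lay.backward(g)
        for lay in reversed(self.stem):
            g = lay.backward(g)

    # -- full forward -------------------------------------------------------

    def forward_logit(self, patches: Sequence[np.ndarray]) -> float:
        """Per-phase patches (each (1,S,S,S)) in fixed order -> malignancy logit."""
        feats = [self.encode(p) for p in patches]
        seq = np.stack(feats)[:, None, :]  # (T, B=1, F)
        h = self.gru.forward(seq)
        logit = self.head.forward(h)
        self._patches = list(patches)
        return float(logit[0, 0])

    def backward_logit(self, glogit: float) -> None:
        g = np.array([[glogit]], dtype=self.head.params["w"].dtype)
        gh = self.head.backward(g)
        gseq = self.gru.backward(gh)  # (T, 1, F)
        # the encoder is shared across phases and its layer caches hold only
        # the most recent pass, so re-encode each phase before its backward
        for t in range(len(self._patches) - 1, -1, -1):
            self.encode(self._patches[t])
            self.encode_backward(gseq[t, 0])
        self._patches = None


def build_setd(cfg: SETDConfig, dtype=np.float32) -> SETDNet:
    net = SETDNet(cfg, dtype)
    if cfg.pretrained:
        with np.load(cfg.pretrained, allow_pickle=False) as data:
            net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net


def crop_around_mask(
    voxels: np.ndarray, mask: np.ndarray, size: int, offset=None
) -> np.ndarray:
    """Cubic crop of ``size`` voxels centred on the mask centroid (plus an
    optional integer ``offset``), zero-padded at the grid border so the
    output is always (size, size, size)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    centroid = np.round(np.array(np.nonzero(mask)).mean(axis=1)).astype(int)
    if offset is not None:
        centroid = centroid + np.asarray(offset, int)
    half = size // 2
    out = np.zeros((size, size, size), dtype=np.float32)
    lo = centroid - half
    hi = lo + size
    src = [slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, voxels.shape)]
    dst = [
        slice(max(-l, 0), max(-l, 0) + (s.stop - s.start))
        for l, s in zip(lo, src)
    ]
    out[tuple(dst)] = voxels[tuple(src)]
    return out


def _patches(
    study: MultiPhaseStudy,
    mask: np.ndarray,
    cfg: SETDConfig,
    rng: Optional[np.random.Generator] = None,
    jitter_vox: int = 0,
    flips: bool = False,
):
    """Per-phase encoder inputs: lesion-masked, HU-normalized cubic crops.

    The lesion segmentation gates the crop (voxels outside the mask are
    zeroed) so the encoder sees the lesion's own enhancement pattern rather
    than the far brighter surrounding renal cortex. With ``rng`` given, the
    crop centre is jittered by up to ``jitter_vox`` voxels and random axis
    flips are applied (training augmentation only)."""
    if len(study.phases) < 2:
        raise ValueError(
            "the temporal decoder requires a multi-phase sequence (>= 2 phases)"
        )
    mask = np.asarray(mask)
    offset = None
    if rng is not None and jitter_vox > 0:
        offset = rng.integers(-jitter_vox, jitter_vox + 1, 3)
    mcrop = crop_around_mask(mask.astype(np.float32), mask, cfg.crop_size, offset)
    out = [
        (
            normalize_hu(
                crop_around_mask(p.voxels, mask, cfg.crop_size, offset), cfg.hu_window
            )
            * mcrop
        )[None]
        for p in study.phases
    ]
    if rng is not None and flips:
        axes = [ax for ax in (1, 2, 3) if rng.uniform() < 0.5]
        if axes:
            out = [np.ascontiguousarray(np.flip(p, axis=axes)) for p in out]
    return out


def setd_forward(
    study: MultiPhaseStudy,
    lesion_mask: np.ndarray,
    net: SETDNet,
    phase_order: Optional[Sequence[int]] = None,
) -> float:
    """Malignancy probability for one study (deterministic given weights).

    ``phase_order`` permutes the phase sequence before decoding (used only to
    demonstrate the temporal decoder's order sensitivity)."""
    patches = _patches(study, np.asarray(lesion_mask), net.cfg)
    if phase_order is not None:
        patches = [patches[i] for i in phase_order]
    logit = net.forward_logit(patches)
    return float(nn.sigmoid(np.array([logit]))[0])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_setd(net: SETDNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=json.dumps(asdict(net.cfg)), **net.state_dict())
    return path


def load_setd(path: str | Path) -> SETDNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("stage_widths", "stage_blocks", "hu_window"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    net = SETDNet(SETDConfig(**cfg_dict))
    net.load_state_dict(state)
    return net


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def inverse_frequency_weights(labels: Sequence[int]) -> tuple[float, float]:
    """(w_benign, w_malignant) proportional to inverse class frequency,
    normalized so the weights average to 1 over the training set."""
    labels = np.asarray(labels)
    n = len(labels)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"single-class training set (benign={n_neg}, malignant={n_pos})"
        )
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def train_setd(
    manifest: pd.DataFrame,
    cfg: SETDConfig,
    train_cfg: SETDTrainConfig,
    out_dir: str | Path = ".",
) -> tuple[Path, pd.DataFrame]:
    """Train the SETD classifier on a labeled cohort; returns (ckpt, log).

    80/20 seeded-shuffle train/validation split (stratified), inverse-class-
    frequency weighted cross-entropy unless weights are given, early stopping
    on validation AUC with best-weight restoration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(train_cfg.seed)

    studies, labels, masks = [], [], []
    for _, row in manifest.iterrows():
        s = load_study(row)
        if s.mask is None:
            raise ValueError(f"study {s.study_id} has no lesion mask")
        if s.label is None:
            raise ValueError(f"study {s.study_id} has no label")
        studies.append(s)
        labels.append(1 if s.label == "malignant" else 0)
        masks.append(s.mask)
    labels = np.asarray(labels)

    w_neg, w_pos = (
        train_cfg.class_weights
        if train_cfg.class_weights is not None
        else inverse_frequency_weights(labels)
    )

    # stratified seeded split
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * train_cfg.val_fraction)))
        val_idx.extend(idx[:n_val])
    val_idx = np.asarray(sorted(val_idx))
    train_idx = np.asarray([i for i in range(len(studies)) if i not in set(val_idx)])
    if len(set(labels[train_idx])) < 2:
        raise ValueError("single-class training split")

    net = build_setd(cfg)
    opt = nn.Adam(net, lr=train_cfg.learning_rate, weight_decay=train_cfg.weight_decay)
    patch_cache = [_patches(s, m, cfg) for s, m in zip(studies, masks)]

    def val_auc():
        scores = [net.forward_logit(patch_cache[i]) for i in val_idx]
        y = labels[val_idx]
        if len(set(y)) < 2:
            return np.nan
        return float(roc_auc_score(y, scores))

    best = (-np.inf, net.state_dict())
    bad = 0
    rows = []
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        net.zero_grad()
        for j, i in enumerate(order):
            if train_cfg.augment:
                patches = _patches(
                    studies[i], masks[i], cfg, rng,
                    jitter_vox=train_cfg.jitter_vox, flips=True,
                )
            else:
                patches = patch_cache[i]
            logit = net.forward_logit(patches)
            loss, glogit = nn.weighted_bce_loss(logit, int(labels[i]), w_pos, w_neg)
            net.backward_logit(glogit)
            losses.append(loss)
            if (j + 1) % train_cfg.batch_size == 0 or j == len(order) - 1:
                opt.step()
                net.zero_grad()
        auc = val_auc()
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": auc})
        score = auc if np.isfinite(auc) else -np.mean(losses)
        # >= keeps the most recent of equally good epochs: with a small
        # validation set the AUC plateaus early while augmentation keeps
        # improving the underlying features
        if score >= best[0]:
            best = (score, net.state_dict())
            bad = 0
        else:
            bad += 1
            if bad > train_cfg.patience:
                break
    net.load_state_dict(best[1])

    ckpt = save_setd(net, out_dir / "setd.npz")
    log = pd.DataFrame(rows)
    log.to_csv(out_dir / "setd_train_log.csv", index=False)
    return ckpt, log


def predict_cohort(
    manifest: pd.DataFrame,
    net: SETDNet,
    out_csv: Optional[str | Path] = None,
) -> list[PredictionRecord]:
    """One malignancy probability per manifest study (CSV written if asked)."""
    records = []
    for _, row in manifest.iterrows():
        try:
            s = load_study(row)
        except (FormatError, FileNotFoundError) as exc:
            raise FormatError(f"study {row['study_id']}: {exc}") from exc
        if s.mask is None:
            raise FormatError(f"study {s.study_id}: missing lesion mask")
        prob = setd_forward(s, s.mask, net)
        label = None
        if s.label is not None:
            label = 1 if s.label == "malignant" else 0
        records.append(
            PredictionRecord(study_id=s.study_id, prob_malignant=prob, label=label)
        )
    if out_csv is not None:
        write_predictions(records, out_csv)
    return records
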