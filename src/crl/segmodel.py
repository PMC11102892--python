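"""Two-stage interactive segmentation networks.

P-net is a 1-channel 3D U-Net that produces the initial automatic lesion
segmentation from the raw (HU-normalized) volume. R-net is the same U-Net
with 4 input channels — normalized image, initial segmentation probability,
and the foreground/background geodesic interaction channels — and produces
the refined segmentation. Both output a per-voxel foreground probability;
the binary mask is probability >= 0.5 (ties count as foreground).

The U-Net here is deliberately small (base width 8, 4 resolution levels) so
seeded CPU training on phantom cohorts finishes in minutes; widths, depth
and all training hyperparameters are config fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nn
from .formats_io import InteractionSet, PhaseVolume, load_study
from .geodesic import encode_interactions

__all__ = [
    "SegNetConfig",
    "SegTrainConfig",
    "UNet3D",
    "build_segnet",
    "normalize_hu",
    "pnet_predict",
    "rnet_refine",
    "train_segnet",
    "save_checkpoint",
    "load_checkpoint",
    "threshold_mask",
]

DEFAULT_HU_WINDOW = (-100.0, 300.0)


@dataclass
class SegNetConfig:
    """Architecture config. P-net: in_channels=1; R-net: in_channels=4."""

    in_channels: int = 1
    base_width: int = 8
    depth: int = 4  # resolution levels
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    lambda_intensity: float = 1.0  # geodesic weight for the R-net channels
    seed: int = 0

    def __post_init__(self):
        if self.in_channels not in (1, 4):
            raise ValueError("in_channels must be 1 (P-net) or 4 (R-net)")


@dataclass
class SegTrainConfig:
    loss: str = "dice_plus_cross_entropy"  # or "dice"
    learning_rate: float = 3e-3
    max_epochs: int = 10
    patience: int = 5  # early-stop patience on validation Dice
    batch_size: int = 2
    val_fraction: float = 0.2
    augment_flips: bool = False
    clicks_per_round: int = 3  # robot clicks when building R-net pairs
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


def normalize_hu(voxels: np.ndarray, hu_window=DEFAULT_HU_WINDOW) -> np.ndarray:
    """Clip to the HU window and min-max rescale to [0, 1] (float32)."""
    lo, hi = hu_window
    return np.clip((np.asarray(voxels, np.float32) - lo) / (hi - lo), 0.0, 1.0)


class UNet3D(nn.Module):
    """3D U-Net: conv(3)-IN-ReLU x2 per level, 2x max-pool / nearest-up,
    skip concatenation, 1x1x1 logit head."""

    def __init__(self, in_channels, base_width=8, depth=4, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        widths = [base_width * 2**l for l in range(depth)]
        self.widths = widths

        def block(cin, cout):
            layers = [
                nn.Conv3d(cin, cout, 3, rng, dtype),
                nn.InstanceNorm3d(cout, dtype),
                nn.ReLU(),
                nn.Conv3d(cout, cout, 3, rng, dtype),
                nn.InstanceNorm3d(cout, dtype),
                nn.ReLU(),
            ]
            self.children.extend(layers)
            return layers

        self.enc = []
        cin = in_channels
        for w in widths:
            self.enc.append(block(cin, w))
            cin = w
        self.pools = [nn.MaxPool2x() for _ in range(depth - 1)]
        self.ups = [nn.Upsample2x() for _ in range(depth - 1)]
        self.children.extend(self.pools + self.ups)
        self.dec = []
        for l in range(depth - 2, -1, -1):
            self.dec.append(block(widths[l + 1] + widths[l], widths[l]))
        self.out_conv = nn.Conv3d(widths[0], 1, 1, rng, dtype)
        self.children.append(self.out_conv)

    @staticmethod
    def _run(layers, x):
        for lay in layers:
            x = lay.forward(x)
        return x

    @staticmethod
    def _run_back(layers, g):
        for lay in reversed(layers):
            g = lay.backward(g)
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (C, D, H, W) -> logits (1, D, H, W). Pads spatial dims up to a
        multiple of 2^(depth-1) and crops the output back."""
        mult = 2 ** (self.depth - 1)
        shape = x.shape[1:]
        pads = [(0, (-s) % mult) for s in shape]
        self._pads, self._orig = pads, shape
        if any(p[1] for p in pads):
            x = np.pad(x, [(0, 0)] + pads)
        skips = []
        for l in range(self.depth):
            x = self._run(self.enc[l], x)
            if l < self.depth - 1:
                skips.append(x)
                x = self.pools[l].forward(x)
        self._skip_channels = []
        for i, l in enumerate(range(self.depth - 2, -1, -1)):
            x = self.ups[i].forward(x)
            skip = skips[l]
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = self._run(self.dec[i], x)
        logits = self.out_conv.forward(x)
        d, h, w = self._orig
        return logits[:, :d, :h, :w]

    def backward(self, glogits: np.ndarray) -> None:
        pads = self._pads
        if any(p[1] for p in pads):
            glogits = np.pad(glogits, [(0, 0)] + pads)
        g = self.out_conv.backward(glogits)
        gskips = {}
        for i in range(len(self.dec) - 1, -1, -1):
            l = self.depth - 2 - i
            g = self._run_back(self.dec[i], g)
            n_up = g.shape[0] - self._skip_channels[i]
            gskips[l] = g[n_up:]
            g = self.ups[i].backward(g[:n_up])
        for l in range(self.depth - 1, -1, -1):
            if l < self.depth - 1:
                g = self.pools[l].backward(g)
                g = g + gskips[l]
            g = self._run_back(self.enc[l], g)


def build_segnet(cfg: SegNetConfig, dtype=np.float32) -> UNet3D:
    rng = np.random.default_rng(cfg.seed)
    return UNet3D(cfg.in_channels, cfg.base_width, cfg.depth, rng, dtype)


def threshold_mask(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask from probabilities; a tie (== threshold) is foreground."""
    return (prob >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def pnet_predict(volume: PhaseVolume, model: UNet3D, cfg: SegNetConfig) -> np.ndarray:
    """Initial automatic segmentation: per-voxel foreground probability."""
    x = normalize_hu(volume.voxels, cfg.hu_window)[None]
    logits = model.forward(x)
    return nn.sigmoid(logits[0]).astype(np.float32)


def rnet_input(
    volume: PhaseVolume,
    initial_seg: np.ndarray,
    iset: InteractionSet,
    cfg: SegNetConfig,
) -> np.ndarray:
    """Stack the 4 R-net channels: image, initial seg, fg/bg geodesic maps."""
    if initial_seg.shape != volume.shape:
        raise ValueError(
            f"initial segmentation shape {initial_seg.shape} != volume {volume.shape}"
        )
    img = normalize_hu(volume.voxels, cfg.hu_window)
    fg, bg = encode_interactions(
        volume, iset, lambda_intensity=cfg.lambda_intensity, hu_window=cfg.hu_window
    )
    return np.stack(
        [
            img,
            initial_seg.astype(np.float32),
            fg.values.astype(np.float32),
            bg.values.astype(np.float32),
        ]
    )


def rnet_refine(
    volume: PhaseVolume,
    initial_seg: np.ndarray,
    iset: InteractionSet,
    model: UNet3D,
    cfg: SegNetConfig,
) -> np.ndarray:
    """Refined per-voxel probability from image + initial seg + interactions."""
    x = rnet_input(volume, initial_seg, iset, cfg)
    logits = model.forward(x)
    return nn.sigmoid(logits[0]).astype(np.float32)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: nn.Module, cfg, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(cfg)), **state)
    return path


def load_checkpoint(path: str | Path, config_cls=SegNetConfig):
    """Returns (model, config) for SegNetConfig checkpoints."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("hu_window",):
        if key in cfg_dict and cfg_dict[key] is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    cfg = config_cls(**cfg_dict)
    model = build_segnet(cfg)
    model.load_state_dict(state)
    return model, cfg


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    a = pred.astype(bool)
    b = truth.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _split(n: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return order[n_val:], order[:n_val]


def _maybe_flip(x, t, rng, enabled):
    if not enabled:
        return x, t
    for ax in (1, 2, 3):
        if rng.uniform() < 0.5:
            x = np.flip(x, axis=ax)
            t = np.flip(t, axis=ax - 1)
    return np.ascontiguousarray(x), np.ascontiguousarray(t)


def train_segnet(
    manifest: pd.DataFrame,
    which: str,
    train_cfg: SegTrainConfig,
    net_cfg: Optional[SegNetConfig] = None,
    out_dir: str | Path = ".",
    pnet_checkpoint: Optional[str | Path] = None,
) -> tuple[Path, pd.DataFrame]:
    """Train P-net or R-net on a cohort manifest; returns (checkpoint, log).

    R-net training pairs are synthesized by running the P-net checkpoint on
    each study and letting the robot user place clicks against the ground
    truth (the spec's robot-in-the-loop pair construction), then training the
    4-channel net to predict the truth mask. The best-validation-Dice weights
    are checkpointed; the log has one row per epoch (loss, val Dice). Fully
    seeded and deterministic in single-threaded mode.
    """
    from .interact import robot_click  # local import to avoid a cycle

    if which not in ("pnet", "rnet"):
        raise ValueError("which must be 'pnet' or 'rnet'")
    if "mask_path" not in manifest.columns or manifest["mask_path"].isna().all():
        raise ValueError("manifest has no masks; segmentation training needs masks")
    if len(manifest) < 2:
        raise ValueError("need at least 2 studies")
    if which == "rnet" and pnet_checkpoint is None:
        raise ValueError("R-net training requires a trained P-net checkpoint")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net_cfg = net_cfg or SegNetConfig(in_channels=1 if which == "pnet" else 4)
    if which == "rnet" and net_cfg.in_channels != 4:
        raise ValueError("R-net config must have in_channels=4")
    if which == "pnet" and net_cfg.in_channels != 1:
        raise ValueError("P-net config must have in_channels=1")

    rng = np.random.default_rng(train_cfg.seed)
    studies = [load_study(row) for _, row in manifest.iterrows()]
    for s in studies:
        if s.mask is None:
            raise ValueError(f"study {s.study_id} has no mask")

    # build (input, target) pairs
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    if which == "pnet":
        for s in studies:
            x = normalize_hu(s.phases[0].voxels, net_cfg.hu_window)[None]
            pairs.append((x, s.mask.astype(np.float32)))
    else:
        pnet_model, pnet_cfg = load_checkpoint(pnet_checkpoint)
        for s in studies:
            vol = s.phases[0]
            prob = pnet_predict(vol, pnet_model, pnet_cfg)
            iset = robot_click(
                threshold_mask(prob), s.mask, k=train_cfg.clicks_per_round,
                spacing=vol.spacing,
            )
            pairs.append((rnet_input(vol, prob, iset, net_cfg), s.mask.astype(np.float32)))

    train_idx, val_idx = _split(len(pairs), train_cfg.val_fraction, rng)
    model = build_segnet(net_cfg)
    opt = nn.Adam(model, lr=train_cfg.learning_rate)

    def val_dice():
        if len(val_idx) == 0:
            return np.nan
        scores = []
        for i in val_idx:
            x, t = pairs[i]
            prob = nn.sigmoid(model.forward(x)[0])
            scores.append(_dice(threshold_mask(prob), t))
        return float(np.mean(scores))

    best = (-np.inf, model.state_dict())
    bad_epochs = 0
    rows = []
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        model.zero_grad()
        for j, i in enumerate(order):
            x, t = pairs[i]
            x, t = _maybe_flip(x, t, rng, train_cfg.augment_flips)
            logits = model.forward(x)
            loss, grad = nn.dice_bce_loss(
                logits, t[None], bce_weight=0.0 if train_cfg.loss == "dice" else 1.0
            )
            model.backward(grad)
            losses.append(loss)
            if (j + 1) % train_cfg.batch_size == 0 or j == len(order) - 1:
                opt.step()
                model.zero_grad()
        vd = val_dice()
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": vd})
        score = vd if np.isfinite(vd) else -np.mean(losses)
        if score > best[0]:
            best = (score, model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > train_cfg.patience:
                break
    model.load_state_dict(best[1])

    ckpt = save_checkpoint(model, net_cfg, out_dir / f"{which}.npz")
    log = pd.DataFrame(rows)
    log.to_csv(out_dir / f"{which}_train_log.csv", index=False)
    return ckpt, log
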