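"""Minimal numpy neural-network layers with hand-coded backpropagation.

All model code in this package (the P-net/R-net 3D U-Nets and the SETD
encoder/GRU classifier) runs on these layers. Tensors are single-sample,
channel-first ``(C, D, H, W)`` float arrays; the GRU uses ``(B, features)``
batches. Every layer caches what its backward pass needs, accumulates
parameter gradients in-place, and returns the gradient w.r.t. its input.
Correctness is pinned by finite-difference gradient checks in the test
suite.

Conventions:
* parameters live in ``layer.params`` as ``{name: array}`` with matching
  ``layer.grads``;
* ``zero_grad`` / ``state_dict`` / ``load_state_dict`` walk ``layer.children``
  recursively;
* convolutions are 3x3x3 (same padding) or 1x1x1, stride 1 — downsampling is
  2x max pooling, upsampling is 2x nearest neighbour, so every gradient is a
  plain GEMM or reshape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "MaxPool2x",
    "Upsample2x",
    "Linear",
    "GRU",
    "Adam",
    "sigmoid",
    "dice_bce_loss",
    "weighted_bce_loss",
]


def sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Module:
    """Base: parameter/grad registry plus recursive traversal."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: list[Module] = []

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def modules(self):
        yield self
        for c in self.children:
            yield from c.modules()

    def zero_grad(self):
        for m in self.modules():
            for g in m.grads.values():
                g[...] = 0.0

    def parameters(self):
        for i, m in enumerate(self.modules()):
            for name in m.params:
                yield f"{i}.{name}", m.params[name], m.grads[name]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: p.copy() for key, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, p, _ in self.parameters():
            p[...] = state[key]

    def astype(self, dtype):
        for m in self.modules():
            for k in m.params:
                m.params[k] = m.params[k].astype(dtype)
                m.grads[k] = m.grads[k].astype(dtype)
        return self


class Conv3d(Module):
    """3D convolution, kernel 1 or 3, stride 1, same padding."""

    def __init__(self, cin, cout, kernel=3, rng=None, dtype=np.float32):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, kernel
        fan_in = cin * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, kernel, kernel, kernel))
        self.add_param("w", w.astype(dtype))
        self.add_param("b", np.zeros(cout, dtype=dtype))

    def forward(self, x):
        c, d, h, w_ = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
        self._xp, self._shape = xp, (d, h, w_)
        n = d * h * w_
        W, b = self.params["w"], self.params["b"]
        y = np.broadcast_to(b.reshape(-1, 1), (self.cout, n)).copy()
        for oz in range(k):
            for oy in range(k):
                for ox in range(k):
                    xs = xp[:, oz : oz + d, oy : oy + h, ox : ox + w_].reshape(c, n)
                    y += W[:, :, oz, oy, ox] @ xs
        return y.reshape(self.cout, d, h, w_)

    def backward(self, gy):
        d, h, w_ = self._shape
        n = d * h * w_
        k = self.k
        xp = self._xp
        W = self.params["w"]
        gyf = gy.reshape(self.cout, n)
        self.grads["b"] += gy.sum(axis=(1, 2, 3))
        gxp = np.zeros_like(xp)
        for oz in range(k):
            for oy in range(k):
                for ox in range(k):
                    xs = xp[:, oz : oz + d, oy : oy + h, ox : ox + w_].reshape(
                        self.cin, n
                    )
                    self.grads["w"][:, :, oz, oy, ox] += gyf @ xs.T
                    gxp[:, oz : oz + d, oy : oy + h, ox : ox + w_] += (
                        W[:, :, oz, oy, ox].T @ gyf
                    ).reshape(self.cin, d, h, w_)
        pad = k // 2
        self._xp = None
        if pad:
            return gxp[:, pad : pad + d, pad : pad + h, pad : pad + w_]
        return gxp


class InstanceNorm3d(Module):
    """Per-channel normalization over the spatial axes, with affine."""

    eps = 1e-5

    def __init__(self, c, dtype=np.float32):
        super().__init__()
        self.add_param("gamma", np.ones(c, dtype=dtype))
        self.add_param("beta", np.zeros(c, dtype=dtype))

    def forward(self, x):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        g = self.params["gamma"].reshape(-1, 1, 1, 1)
        b = self.params["beta"].reshape(-1, 1, 1, 1)
        return g * self._xhat + b

    def backward(self, gy):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (gy * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] += gy.sum(axis=(1, 2, 3))
        gxh = gy * self.params["gamma"].reshape(-1, 1, 1, 1)
        m = gxh.mean(axis=(1, 2, 3), keepdims=True)
        mx = (gxh * xhat).mean(axis=(1, 2, 3), keepdims=True)
        self._xhat = None
        return (gxh - m - xhat * mx) * inv


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2x(Module):
    """2x2x2 max pooling (even spatial dims required)."""

    def forward(self, x):
        c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "odd shape into MaxPool2x"
        xb = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        self._idx = xb.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xb, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        c, d, h, w = self._inshape
        gb = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gb, self._idx[..., None], gy[..., None], axis=-1)
        g = (
            gb.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        self._idx = None
        return g


class Upsample2x(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        c, d, h, w = gy.shape
        return gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class Linear(Module):
    def __init__(self, din, dout, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / (din + dout))
        self.add_param("w", rng.uniform(-bound, bound, (dout, din)).astype(dtype))
        self.add_param("b", np.zeros(dout, dtype=dtype))

    def forward(self, x):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy):
        self.grads["w"] += gy.T @ self._x
        self.grads["b"] += gy.sum(axis=0)
        g = gy @ self.params["w"]
        self._x = None
        return g


class GRU(Module):
    """Stacked gated recurrent unit over a (T, B, input) sequence.

    Gate layout per layer follows the conventional chunking [r, z, n]:
        r = sigm(Wi_r x + bi_r + Wh_r h + bh_r)
        z = sigm(Wi_z x + bi_z + Wh_z h + bh_z)
        n = tanh(Wi_n x + bi_n + r * (Wh_n h + bh_n))
        h' = (1 - z) * n + z * h
    Backward is full BPTT through all layers and timesteps.
    """

    def __init__(self, input_size, hidden_size, num_layers=2, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.input_size, self.hidden, self.layers = input_size, hidden_size, num_layers
        bound = 1.0 / np.sqrt(hidden_size)
        for l in range(num_layers):
            din = input_size if l == 0 else hidden_size
            self.add_param(
                f"wi{l}", rng.uniform(-bound, bound, (3 * hidden_size, din)).astype(dtype)
            )
            self.add_param(
                f"wh{l}",
                rng.uniform(-bound, bound, (3 * hidden_size, hidden_size)).astype(dtype),
            )
            self.add_param(f"bi{l}", np.zeros(3 * hidden_size, dtype=dtype))
            self.add_param(f"bh{l}", np.zeros(3 * hidden_size, dtype=dtype))

    def forward(self, seq):
        """seq: (T, B, input) -> final hidden state of the top layer (B, H)."""
        t_len, batch, _ = seq.shape
        hdim = self.hidden
        self._caches = []
        x_seq = seq
        for l in range(self.layers):
            wi, wh = self.params[f"wi{l}"], self.params[f"wh{l}"]
            bi, bh = self.params[f"bi{l}"], self.params[f"bh{l}"]
            h = np.zeros((batch, hdim), dtype=seq.dtype)
            outs, caches = [], []
            for t in range(t_len):
                x = x_seq[t]
                gi = x @ wi.T + bi
                gh = h @ wh.T + bh
                r = sigmoid(gi[:, :hdim] + gh[:, :hdim]).astype(seq.dtype)
                z = sigmoid(gi[:, hdim : 2 * hdim] + gh[:, hdim : 2 * hdim]).astype(
                    seq.dtype
                )
                ghn = gh[:, 2 * hdim :]
                n = np.tanh(gi[:, 2 * hdim :] + r * ghn)
                h_new = (1.0 - z) * n + z * h
                caches.append((x, h, r, z, n, ghn))
                outs.append(h_new)
                h = h_new
            self._caches.append(caches)
            x_seq = np.stack(outs)
        self._top_out = x_seq
        return x_seq[-1]

    def backward(self, gh_final):
        """gh_final: gradient w.r.t. the final top-layer hidden state."""
        t_len = self._top_out.shape[0]
        hdim = self.hidden
        # per-layer gradient on each timestep's output, filled top-down
        g_out = [
            np.zeros((t_len,) + gh_final.shape, dtype=gh_final.dtype)
            for _ in range(self.layers)
        ]
        g_out[-1][-1] = gh_final
        g_input = None
        for l in range(self.layers - 1, -1, -1):
            wi, wh = self.params[f"wi{l}"], self.params[f"wh{l}"]
            caches = self._caches[l]
            gh_next = np.zeros_like(gh_final)
            din = wi.shape[1]
            g_x_seq = np.zeros((t_len, gh_final.shape[0], din), dtype=gh_final.dtype)
            for t in range(t_len - 1, -1, -1):
                x, h_prev, r, z, n, ghn = caches[t]
                gh = g_out[l][t] + gh_next
                gz = gh * (h_prev - n)
                gn = gh * (1.0 - z)
                gh_prev = gh * z
                gn_pre = gn * (1.0 - n * n)
                gr = gn_pre * ghn
                g_gh_n = gn_pre * r
                gr_pre = gr * r * (1.0 - r)
                gz_pre = gz * z * (1.0 - z)
                g_gi = np.concatenate([gr_pre, gz_pre, gn_pre], axis=1)
                g_gh = np.concatenate([gr_pre, gz_pre, g_gh_n], axis=1)
                self.grads[f"wi{l}"] += g_gi.T @ x
                self.grads[f"bi{l}"] += g_gi.sum(axis=0)
                self.grads[f"wh{l}"] += g_gh.T @ h_prev
                self.grads[f"bh{l}"] += g_gh.sum(axis=0)
                g_x_seq[t] = g_gi @ wi
                gh_next = gh_prev + g_gh @ wh
            if l > 0:
                g_out[l - 1] += g_x_seq
            else:
                g_input = g_x_seq
        self._caches = None
        self._top_out = None
        return g_input


class Adam:
    """Adam with decoupled weight decay (single-threaded, deterministic)."""

    def __init__(self, module: Module, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.module = module
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p, _ in module.parameters()}
        self.v = {k: np.zeros_like(p) for k, p, _ in module.parameters()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, p, g in self.module.parameters():
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.wd:
                p *= 1.0 - self.lr * self.wd
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# losses (return loss value and gradient w.r.t. logits)
# ---------------------------------------------------------------------------


def _bce_with_logits(z, t):
    # numerically stable: max(z,0) - z*t + log(1 + exp(-|z|))
    return np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))


def dice_bce_loss(
    logits: np.ndarray, target: np.ndarray, eps: float = 1.0, bce_weight: float = 1.0
):
    """Soft-Dice + binary cross-entropy on voxel logits.

    Returns (loss, grad w.r.t. logits). Standard compound loss for heavily
    class-imbalanced volumetric segmentation; ``bce_weight=0`` gives pure
    soft-Dice.
    """
    z = logits.astype(np.float64)
    t = target.astype(np.float64)
    n = z.size
    p = sigmoid(z)
    bce = bce_weight * _bce_with_logits(z, t).mean()
    g_bce = bce_weight * (p - t) / n

    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    dice = (2.0 * inter + eps) / denom
    # d(dice)/dp_i = (2 t_i * denom - (2 inter + eps)) / denom^2
    ddice_dp = (2.0 * t * denom - (2.0 * inter + eps)) / (denom * denom)
    g_dice = -ddice_dp * p * (1.0 - p)

    loss = bce + (1.0 - dice)
    return float(loss), (g_bce + g_dice).astype(logits.dtype)


def weighted_bce_loss(logit: float, target: int, w_pos: float, w_neg: float):
    """Class-weighted binary cross-entropy on a single case logit.

    Equivalent to 2-way weighted cross-entropy with a single sigmoid logit.
    Returns (loss, grad w.r.t. logit).
    """
    z = float(logit)
    t = float(target)
    w = w_pos if target == 1 else w_neg
    p = float(sigmoid(np.array([z]))[0])
    loss = w * float(_bce_with_logits(np.array([z]), np.array([t]))[0])
    return loss, w * (p - t)
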