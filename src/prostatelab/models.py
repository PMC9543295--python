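"""Desk-scale trainable 3-class segmentation models ("digital radiologists").

A compact CPU segmentation framework: 3x3 convolutions, ReLU, 2x2
average-pool downsampling, nearest-neighbour upsampling, optional U-Net-style
skip connections, and a per-pixel 3-class softmax head, trained with Adam on
a class-balanced cross-entropy restricted to prostate voxels.  Four named
architectures preserve the input/output contracts of the networks commonly
used for prostate-MRI cancer detection:

``spcnet_like``
    2.5D encoder-decoder (three consecutive slices of T2w and ADC, 6 input
    channels), no skips.
``unet_like``
    2.5D encoder-decoder with skip connections.
``branched_unet_like``
    2.5D with skips and two decoder heads — a cancer-vs-normal head and an
    aggressive-vs-indolent head — merged into a 3-class output.
``deeplab_like_2d``
    2D single-slice input (2 channels) with a dilated bottleneck.

The ``_like`` suffix is deliberate: these are small stand-ins that keep the
training conventions (2.5D vs 2D input, branched heads, softmax, masked
class-balanced loss, per-architecture learning-rate presets) at a size that
trains in minutes on one CPU.  Widths and epochs are configurable; the
historical hyperparameters (batch 22, 30 epochs, per-architecture learning
rates) are retained as the config defaults, with a "desk" preset used by the
study pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ImageVolume, stack_adjacent_slices

ARCHS = ("spcnet_like", "unet_like", "branched_unet_like", "deeplab_like_2d")

#: per-architecture default learning rates
ARCH_LR = {"spcnet_like": 1e-4, "branched_unet_like": 1e-4,
           "unet_like": 1e-5, "deeplab_like_2d": 1e-3}

N_CLASSES = 3


@dataclass
class TrainConfig:
    arch: str = "spcnet_like"
    input_mode: str = "auto"      # "stack3" | "single_slice" | "auto"
    lr: float | None = None       # None -> per-arch default
    batch_size: int = 22
    epochs: int = 30
    n_folds: int = 5
    seed: int = 0
    class_weight_mode: str = "dataset"   # "dataset" | "none"
    weight_cap: float = 100.0
    width: int = 8

    def resolved(self) -> "TrainConfig":
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}")
        mode = self.input_mode
        if mode == "auto":
            mode = "single_slice" if self.arch == "deeplab_like_2d" else "stack3"
        if self.arch == "deeplab_like_2d" and mode != "single_slice":
            raise ValueError("deeplab_like_2d requires single_slice input")
        if self.arch != "deeplab_like_2d" and mode != "stack3":
            raise ValueError(f"{self.arch} requires stack3 input")
        lr = self.lr if self.lr is not None else ARCH_LR[self.arch]
        return replace(self, input_mode=mode, lr=lr)

    @property
    def in_channels(self) -> int:
        return 2 if self.input_mode == "single_slice" else 6


# ---------------------------------------------------------------------------
# layers (forward + manual backward, Adam state per parameter)
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Conv2D:
    """Same-padded KxK convolution (optionally dilated) via shifted tensordots."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, dilation: int = 1):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.dilation = k, dilation
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        N, C, H, Wd = x.shape
        k, d = self.k, self.dilation
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((N, self.W.value.shape[0], H, Wd))
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i * d:i * d + H, j * d:j * d + Wd]
                out += np.tensordot(patch, self.W.value[:, :, i, j],
                                    axes=([1], [1])).transpose(0, 3, 1, 2)
        return out + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        N, C, H, Wd = x.shape
        k, d = self.k, self.dilation
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i * d:i * d + H, j * d:j * d + Wd]
                self.W.grad[:, :, i, j] += np.tensordot(
                    dy, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i * d:i * d + H, j * d:j * d + Wd] += np.tensordot(
                    dy, self.W.value[:, :, i, j], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p:p + H, p:p + Wd] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2:
    def params(self):
        return []

    def forward(self, x):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("pooling needs even spatial dimensions")
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class Upsample2:
    def params(self):
        return []

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class _Seq:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SegModel:
    """Small encoder-decoder with a per-pixel softmax head.

    Output per slice is ``(3, H, W)`` class probabilities summing to 1.
    ``branched_unet_like`` computes the 3-class output as the product of a
    cancer head and a conditional aggressiveness head:
    ``p = (q_normal, q_cancer * r_indolent, q_cancer * r_aggressive)``.
    """

    def __init__(self, config: TrainConfig):
        cfg = config.resolved()
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2 ** 20]))
        w = cfg.width
        cin = cfg.in_channels
        skips = cfg.arch in ("unet_like", "branched_unet_like")
        dil = 2 if cfg.arch == "deeplab_like_2d" else 1
        self.skips = skips
        self.enc1 = _Seq(Conv2D(cin, w, rng), ReLU())
        self.pool1 = AvgPool2()
        self.enc2 = _Seq(Conv2D(w, 2 * w, rng), ReLU())
        self.pool2 = AvgPool2()
        self.bottleneck = _Seq(Conv2D(2 * w, 4 * w, rng, dilation=dil), ReLU())
        self.up1 = Upsample2()
        self.dec2 = _Seq(Conv2D(4 * w + (2 * w if skips else 0), 2 * w, rng), ReLU())
        self.up2 = Upsample2()
        self.dec1 = _Seq(Conv2D(2 * w + (w if skips else 0), w, rng), ReLU())
        if cfg.arch == "branched_unet_like":
            self.heads = [Conv2D(w, 2, rng, k=1), Conv2D(w, 2, rng, k=1)]
        else:
            self.heads = [Conv2D(w, N_CLASSES, rng, k=1)]
        self._cache = {}

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        blocks = [self.enc1, self.enc2, self.bottleneck, self.dec2, self.dec1]
        out = [p for b in blocks for p in b.params()]
        for h in self.heads:
            out.extend(h.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool1.forward(e1))
        bt = self.bottleneck.forward(self.pool2.forward(e2))
        u1 = self.up1.forward(bt)
        d2_in = np.concatenate([u1, e2], axis=1) if self.skips else u1
        d2 = self.dec2.forward(d2_in)
        u2 = self.up2.forward(d2)
        d1_in = np.concatenate([u2, e1], axis=1) if self.skips else u2
        feat = self.dec1.forward(d1_in)
        self._cache = {"e1c": e1.shape[1], "e2c": e2.shape[1]}
        if len(self.heads) == 1:
            probs = _softmax(self.heads[0].forward(feat))
            self._cache["probs"] = probs
        else:
            q = _softmax(self.heads[0].forward(feat))   # (normal, cancer)
            r = _softmax(self.heads[1].forward(feat))   # (indolent, aggressive)
            probs = np.stack([q[:, 0], q[:, 1] * r[:, 0], q[:, 1] * r[:, 1]], axis=1)
            self._cache.update(q=q, r=r, probs=probs)
        return probs

    def _backward_from_heads(self, dfeat_parts):
        dfeat = sum(dfeat_parts)
        dd1 = self.dec1.backward(dfeat)
        if self.skips:
            du2, de1_skip = dd1[:, :-self._cache["e1c"]], dd1[:, -self._cache["e1c"]:]
        else:
            du2, de1_skip = dd1, 0.0
        dd2 = self.dec2.backward(self.up2.backward(du2))
        if self.skips:
            du1, de2_skip = dd2[:, :-self._cache["e2c"]], dd2[:, -self._cache["e2c"]:]
        else:
            du1, de2_skip = dd2, 0.0
        dbt = self.bottleneck.backward(self.up1.backward(du1))
        de2 = self.pool2.backward(dbt) + de2_skip
        de1 = self.pool1.backward(self.enc2.backward(de2)) + de1_skip
        self.enc1.backward(de1)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray,
                          weight_map: np.ndarray) -> float:
        """Weighted cross-entropy over weighted pixels; accumulates gradients.

        ``y`` holds class indices 0..2 (-1 = ignore); ``weight_map`` is zero
        outside the prostate so no gradient flows from masked voxels.
        """
        probs = self.forward(x)
        wsum = weight_map.sum()
        if wsum == 0:
            return 0.0
        N, _, H, W = probs.shape
        yi = np.clip(y, 0, N_CLASSES - 1)
        ii, hh, ww = np.meshgrid(np.arange(N), np.arange(H), np.arange(W),
                                 indexing="ij")
        p_target = probs[ii, yi, hh, ww]
        loss = float((weight_map * -np.log(np.maximum(p_target, 1e-12))).sum() / wsum)

        if len(self.heads) == 1:
            onehot = np.zeros_like(probs)
            onehot[ii, yi, hh, ww] = 1.0
            dlogits = (probs - onehot) * weight_map[:, None] / wsum
            self._backward_from_heads([self.heads[0].backward(dlogits)])
        else:
            q, r = self._cache["q"], self._cache["r"]
            wm = weight_map / wsum
            # d loss / d (q, r) for p = (q0, q1*r0, q1*r1), target one-hot
            dq = np.zeros_like(q)
            dr = np.zeros_like(r)
            is0, is1, is2 = (yi == 0), (yi == 1), (yi == 2)
            eps = 1e-12
            dq[:, 0] = -wm * is0 / np.maximum(q[:, 0], eps)
            dq[:, 1] = -wm * (is1 | is2) / np.maximum(q[:, 1], eps)
            dr[:, 0] = -wm * is1 / np.maximum(r[:, 0], eps)
            dr[:, 1] = -wm * is2 / np.maximum(r[:, 1], eps)
            dlog_q = q * (dq - (dq * q).sum(axis=1, keepdims=True))
            dlog_r = r * (dr - (dr * r).sum(axis=1, keepdims=True))
            self._backward_from_heads([self.heads[0].backward(dlog_q),
                                       self.heads[1].backward(dlog_r)])
        return loss


def build_model(config: TrainConfig) -> SegModel:
    """Construct a model for the configured architecture (seeded init)."""
    model = SegModel(config)
    if model.n_parameters > 2_000_000:
        raise ValueError("model exceeds the 2M-parameter desk-scale budget")
    return model


# ---------------------------------------------------------------------------
# training utilities
# ---------------------------------------------------------------------------

def class_weights(label_code_volumes: list[np.ndarray],
                  prostate_masks: list[np.ndarray],
                  cap: float = 100.0,
                  normalize: bool = True) -> np.ndarray:
    """Inverse-class-frequency weights over prostate voxels of a training set.

    Weights are proportional to 1/frequency per class (normal, indolent,
    aggressive), capped at ``cap`` (an absent class gets exactly the cap),
    and normalized to mean 1 unless ``normalize=False``.
    """
    if not label_code_volumes:
        raise ValueError("empty training set")
    counts = np.zeros(N_CLASSES)
    for codes, mask in zip(label_code_volumes, prostate_masks):
        inside = np.asarray(codes)[np.asarray(mask).astype(bool)]
        for cls in range(N_CLASSES):
            counts[cls] += np.count_nonzero(inside == cls + 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("training set has no prostate voxels")
    weights = np.empty(N_CLASSES)
    for cls in range(N_CLASSES):
        if counts[cls] == 0:
            import warnings

            warnings.warn(f"class {cls + 1} absent from training set; weight capped")
            weights[cls] = cap
        else:
            weights[cls] = min(total / counts[cls], cap)
    if normalize:
        weights = weights / weights.mean()
    return weights


def make_folds(case_ids: list[str], n_folds: int, seed: int) -> dict[str, int]:
    """Case-level cross-validation folds; sizes differ by at most one."""
    if n_folds > len(case_ids):
        raise ValueError("more folds than cases")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    order = list(case_ids)
    rng.shuffle(order)
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        for cid in chunk:
            assignment[str(cid)] = fold
    return assignment


def assemble_inputs(t2w: ImageVolume, adc: ImageVolume,
                    input_mode: str) -> np.ndarray:
    """Per-slice network inputs: (n_slices, C, H, W).

    ``stack3`` concatenates three consecutive slices of T2w then ADC (6
    channels); ``single_slice`` concatenates the current slice of each
    modality (2 channels).
    """
    k = 1 if input_mode == "single_slice" else 3
    return np.concatenate(
        [stack_adjacent_slices(t2w, k), stack_adjacent_slices(adc, k)], axis=1)


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)


def train(model: SegModel, X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
          config: TrainConfig, weights: np.ndarray | None = None) -> TrainHistory:
    """Adam optimization of masked class-balanced cross-entropy.

    ``X``: (M, C, H, W) slice samples; ``Y``: (M, H, W) integer label codes
    (0 outside, 1..3 classes); ``mask``: (M, H, W) prostate mask.  Only
    prostate voxels contribute to the loss and gradients.
    """
    cfg = config.resolved()
    if weights is None:
        if cfg.class_weight_mode == "dataset":
            weights = class_weights([Y], [mask], cap=cfg.weight_cap)
        else:
            weights = np.ones(N_CLASSES)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31337]))
    y_cls = Y.astype(np.int64) - 1           # codes 1..3 -> classes 0..2
    m = np.asarray(mask).astype(bool) & (y_cls >= 0)
    wmap_full = np.where(m, weights[np.clip(y_cls, 0, N_CLASSES - 1)], 0.0)

    history = TrainHistory()
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            loss = model.loss_and_backward(X[idx], y_cls[idx], wmap_full[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {start // cfg.batch_size}; "
                    f"lr={cfg.lr}, arch={cfg.arch}")
            t += 1
            for p in model.params():
                p.m = beta1 * p.m + (1 - beta1) * p.grad
                p.v = beta2 * p.v + (1 - beta2) * p.grad ** 2
                mhat = p.m / (1 - beta1 ** t)
                vhat = p.v / (1 - beta2 ** t)
                p.value -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))
    return history


def predict(model: SegModel, t2w: ImageVolume, adc: ImageVolume,
            prostate_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slice-wise inference assembled into a 3D probability volume.

    Returns ``(prob, hard)`` where ``prob`` has shape (3, z, y, x) with
    voxelwise softmax probabilities and ``hard`` holds argmax codes 1..3
    inside the prostate, 0 outside.  No morphological post-processing.
    """
    if t2w.shape != adc.shape or t2w.shape != np.asarray(prostate_mask).shape:
        raise ValueError("input grids differ")
    X = assemble_inputs(t2w, adc, model.config.input_mode)
    probs = model.forward(X)                      # (nz, 3, H, W)
    prob = np.transpose(probs, (1, 0, 2, 3))
    mask = np.asarray(prostate_mask).astype(bool)
    hard = np.where(mask, np.argmax(prob, axis=0) + 1, 0).astype(np.int16)
    return prob, hard
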