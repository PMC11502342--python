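"""Trainable encoder-decoder segmentation backend.

A small U-Net: a contracting path of 3x3 convolutions and 2x2 max-pooling, a
bottleneck, and an expanding path of nearest-neighbour upsampling with skip
connections from the matching encoder level, ending in a 1x1 convolution to
two-class logits.  Optimized with Adam on pixel-wise cross-entropy.

The network is implemented directly on numpy arrays (forward and backward
passes are written out explicitly), which keeps the backend dependency-free
and fully deterministic under a seed.  The encoder depth and channel widths
are configurable; the default is a reduced encoder sized so that training on
a few hundred small B-scans is a desk-scale CPU job.  Deeper/wider variants
replicate the same topology.

Predicted masks are post-processed to the same per-column contiguity
guarantee as the classical backend, so downstream stages are
backend-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .types import SegmentationMask

__all__ = ["TrainConfig", "UNet", "train_neural", "predict_mask", "split_pairs"]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror a standard biomedical-segmentation recipe: Adam at
    learning rate 1e-4, batch size 8, 100 epochs, 9:1 train/test split.
    """

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    split_ratio: float = 0.9
    optimizer: str = "adam"
    seed: int = 0
    input_size: int = 128
    base_channels: int = 8
    depth: int = 2  # number of pooling levels in the encoder

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


# --------------------------------------------------------------------------
# primitive layers (explicit forward/backward on (N, C, H, W) arrays)
# --------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution; w is (C_out, C_in, 3, 3)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, w.shape[0], h, wd), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            # (N, C_in, H, W) x (C_out, C_in) -> (N, H, W, C_out)
            out += np.tensordot(xp[:, :, di:di + h, dj:dj + wd], w[:, :, di, dj],
                                axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None]


def _conv3x3_backward(x, w, dy):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di:di + h, dj:dj + wd]
            dw[:, :, di, dj] = np.tensordot(dy, patch, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, di:di + h, dj:dj + wd] += np.tensordot(
                dy, w[:, :, di, dj], axes=([1], [0])).transpose(0, 3, 1, 2)
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _maxpool2(x):
    n, c, h, w = x.shape
    v = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = v.max(axis=(3, 5))
    mask = v == y[:, :, :, None, :, None]
    # distribute ties evenly so the gradient check stays exact
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return y, mask


def _maxpool2_backward(dy, mask):
    g = mask * dy[:, :, :, None, :, None]
    n, c, h2, _, w2, _ = g.shape
    return g.reshape(n, c, h2 * 2, w2 * 2)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class UNet:
    """Minimal U-Net for two-class B-scan segmentation.

    ``depth`` pooling levels; encoder level i has ``base_channels * 2**i``
    channels; the decoder mirrors the encoder with skip concatenation.
    """

    def __init__(self, base_channels: int = 8, depth: int = 2, seed: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def conv(name, c_in, c_out):
            # He initialization for ReLU nonlinearities
            self.params[f"{name}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / (c_in * 9)), (c_out, c_in, 3, 3)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

        c = base_channels
        conv("enc0", 1, c)
        for i in range(1, depth):
            conv(f"enc{i}", c * 2 ** (i - 1), c * 2 ** i)
        conv("bott", c * 2 ** (depth - 1), c * 2 ** depth)
        for i in reversed(range(depth)):
            c_skip = c * 2 ** i
            c_up = c * 2 ** (i + 1)
            conv(f"dec{i}", c_skip + c_up, c_skip)
        self.params["out_w"] = rng.normal(0.0, np.sqrt(2.0 / c), (2, c, 1, 1)).astype(np.float32)
        self.params["out_b"] = np.zeros(2, dtype=np.float32)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits (N, 2, H, W) for images (N, 1, H, W) scaled to [0, 1]."""
        p = self.params
        skips, pools = [], []
        h = x
        for i in range(self.depth):
            if cache is not None:
                cache[f"enc{i}_in"] = h
            a = _conv3x3(h, p[f"enc{i}_w"], p[f"enc{i}_b"])
            r = np.maximum(a, 0.0)
            h, m = _maxpool2(r)
            skips.append(r)
            pools.append(m)
            if cache is not None:
                cache[f"enc{i}_a"] = a
        if cache is not None:
            cache["bott_in"] = h
        a = _conv3x3(h, p["bott_w"], p["bott_b"])
        if cache is not None:
            cache["bott_a"] = a
        h = np.maximum(a, 0.0)
        for i in reversed(range(self.depth)):
            up = _upsample2(h)
            cat = np.concatenate([skips[i], up], axis=1)
            a = _conv3x3(cat, p[f"dec{i}_w"], p[f"dec{i}_b"])
            if cache is not None:
                cache[f"dec{i}_in"], cache[f"dec{i}_a"] = cat, a
            h = np.maximum(a, 0.0)
        # 1x1 output convolution
        logits = (np.tensordot(h, p["out_w"][:, :, 0, 0], axes=([1], [1]))
                  .transpose(0, 3, 1, 2) + p["out_b"][None, :, None, None])
        if cache is not None:
            cache["out_in"] = h
            cache["skips"], cache["pools"] = skips, pools
        return logits

    # -- loss and backward -------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean pixel cross-entropy and parameter gradients.

        ``y`` is an integer mask (N, H, W) with values {0, 1}.
        """
        p = self.params
        cache: dict = {}
        logits = self.forward(x, cache)
        n, _, hh, ww = logits.shape
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        prob = e / e.sum(axis=1, keepdims=True)
        idx = (np.arange(2)[None, :, None, None] == y[:, None]).astype(np.float64)
        npix = n * hh * ww
        loss = float(-(idx * np.log(prob + 1e-12)).sum() / npix)
        dlogits = (prob - idx) / npix

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        h = cache["out_in"]
        grads["out_w"][:, :, 0, 0] = np.tensordot(dlogits, h, axes=([0, 2, 3], [0, 2, 3]))
        grads["out_b"] = dlogits.sum(axis=(0, 2, 3))
        dh = np.tensordot(dlogits, p["out_w"][:, :, 0, 0], axes=([1], [0])).transpose(0, 3, 1, 2)

        dskips = [None] * self.depth
        for i in range(self.depth):
            dh = dh * (cache[f"dec{i}_a"] > 0)
            dcat, dw, db = _conv3x3_backward(cache[f"dec{i}_in"], p[f"dec{i}_w"], dh)
            grads[f"dec{i}_w"], grads[f"dec{i}_b"] = dw, db
            c_skip = cache["skips"][i].shape[1]
            dskips[i] = dcat[:, :c_skip]
            dh = _upsample2_backward(dcat[:, c_skip:])

        dh = dh * (cache["bott_a"] > 0)
        dh, dw, db = _conv3x3_backward(cache["bott_in"], p["bott_w"], dh)
        grads["bott_w"], grads["bott_b"] = dw, db

        for i in reversed(range(self.depth)):
            dr = _maxpool2_backward(dh, cache["pools"][i]) + dskips[i]
            dr = dr * (cache[f"enc{i}_a"] > 0)
            dh, dw, db = _conv3x3_backward(cache[f"enc{i}_in"], p[f"enc{i}_w"], dr)
            grads[f"enc{i}_w"], grads[f"enc{i}_b"] = dw, db
        return loss, grads

    # -- inference ---------------------------------------------------------

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class labels (N, H, W) for images (N, H, W) or (N, 1, H, W)."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        return self.forward(x).argmax(axis=1).astype(np.uint8)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON architecture descriptor."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        desc = {"base_channels": self.base_channels, "depth": self.depth, "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(desc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        desc = json.loads(path.with_suffix(".json").read_text())
        net = cls(**desc)
        with np.load(path.with_suffix(".npz")) as data:
            for k in net.params:
                net.params[k] = data[k]
        return net


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class _AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0


def _adam_step(params, grads, state: _AdamState, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state.t += 1
    for k, g in grads.items():
        if k not in state.m:
            state.m[k] = np.zeros_like(g)
            state.v[k] = np.zeros_like(g)
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        mhat = state.m[k] / (1 - beta1 ** state.t)
        vhat = state.v[k] / (1 - beta2 ** state.t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def split_pairs(pairs: list, ratio: float, seed: int, groups: list | None = None):
    """Seeded train/test split, optionally stratified by group (volume) id.

    Splitting whole volumes rather than individual B-scans prevents leakage
    between nearly identical adjacent slices of one volume.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        idx = rng.permutation(len(pairs))
        cut = int(round(ratio * len(pairs)))
        tr, te = idx[:cut], idx[cut:]
    else:
        uniq = sorted(set(groups))
        perm = rng.permutation(len(uniq))
        cut = max(1, int(round(ratio * len(uniq))))
        train_groups = {uniq[i] for i in perm[:cut]}
        tr = [i for i, g in enumerate(groups) if g in train_groups]
        te = [i for i, g in enumerate(groups) if g not in train_groups]
    if len(te) == 0:
        te = [tr[-1]]
        tr = tr[:-1]
    return [pairs[i] for i in tr], [pairs[i] for i in te]


def train_neural(train_set: list[tuple[np.ndarray, np.ndarray]], config: TrainConfig) -> tuple[UNet, list[float]]:
    """Train the U-Net backend on (image, binary mask) pairs.

    Returns the trained network and the per-epoch mean training loss.
    Deterministic given ``config.seed``.

    Raises
    ------
    ValueError
        On fewer than 2 pairs, non-binary masks, or mismatched shapes.
    """
    if len(train_set) < 2:
        raise ValueError("need at least 2 training pairs")
    shape = np.asarray(train_set[0][0]).shape
    xs, ys = [], []
    for img, msk in train_set:
        img = np.asarray(img, dtype=np.float64)
        msk = np.asarray(msk)
        if img.shape != shape or msk.shape != shape:
            raise ValueError("all images and masks must share one shape")
        uniq = np.unique(msk)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("masks must be binary (values 0/1)")
        xs.append(img)
        ys.append(msk.astype(np.int64))
    x = np.stack(xs)[:, None].astype(np.float32)
    y = np.stack(ys)
    scale = x.max()
    if scale > 0:
        x = x / scale

    net = UNet(config.base_channels, config.depth, seed=config.seed)
    opt = _AdamState()
    rng = np.random.default_rng(config.seed + 1)
    history = []
    n = len(train_set)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            loss, grads = net.loss_and_grads(x[sel], y[sel])
            _adam_step(net.params, grads, opt, config.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def predict_mask(net: UNet, image: np.ndarray, scale: float | None = None) -> SegmentationMask:
    """Segment one B-scan with a trained network, with contiguity clean-up.

    The raw argmax prediction is post-processed to the shared mask invariant:
    each column is filled from its topmost predicted skin pixel downward.
    """
    img = np.asarray(image, dtype=np.float64)
    s = scale if scale is not None else (img.max() or 1.0)
    raw = net.predict((img / s)[None])[0]
    any_skin = raw.any(axis=0)
    top = raw.argmax(axis=0)
    rows = np.arange(raw.shape[0])[:, None]
    mask = np.zeros_like(raw)
    mask[:, any_skin] = (rows >= top[any_skin][None, :]).astype(np.uint8)
    return SegmentationMask(labels=mask, backend="neural",
                            provenance={"base_channels": net.base_channels, "depth": net.depth})
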