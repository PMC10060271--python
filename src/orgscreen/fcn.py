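"""Trainable semantic segmentation: a compact NumPy encoder–decoder.

A two-scale fully convolutional network with a skip connection
(conv–pool–conv–upsample–concat–conv–1×1), per-pixel sigmoid output and
binary cross-entropy loss, trained with Adam. The network is implemented
directly on NumPy (im2col convolutions with explicit backprop), which
keeps it small, dependency-free and bit-deterministic under a fixed seed.

Ground-truth masks for training come from the fluorescence channels via
:func:`orgscreen.segmentation.fluorescence_ground_truth`, so the
brightfield network learns from labels the imaging itself provides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ValidationError
from .segmentation import DEFAULT_PARAMS, LabeledMask, _postprocess

_EPS = 1e-7


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 2-D convolution. x (N,C,H,W), w (Co,Ci,k,k) -> (N,Co,H,W)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, wd = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(n, h, wd, w.shape[0]).transpose(0, 3, 1, 2)


def _conv2d_backward(x, w, grad):
    """Gradients of _conv2d wrt (w, b, x)."""
    k = w.shape[-1]
    p = k // 2
    n, c, h, wd = x.shape
    co = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * k * k)
    g = grad.transpose(0, 2, 3, 1).reshape(n * h * wd, co)
    dw = (g.T @ cols).reshape(co, c, k, k)
    db = g.sum(axis=0)
    # dx: full correlation of grad with spatially flipped kernels
    gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
    gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
    gcols = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, co * k * k)
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, co * k * k)
    dx = (gcols @ wflip.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2)
    return dw, db, dx


def _maxpool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _maxpool2_backward(grad, mask):
    g = grad[:, :, :, None, :, None] * mask
    n, c, h2, _, w2, _ = g.shape
    return g.reshape(n, c, h2 * 2, w2 * 2)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(grad):
    n, c, h, w = grad.shape
    return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


@dataclass
class SegModel:
    """Weights + input contract of the segmentation network.

    ``input_spec`` records the normalization applied to brightfield
    rasters (per-image standardization) and the channel widths;
    ``training_meta`` records epochs, loss curve and seed.
    """

    weights: dict[str, np.ndarray]
    input_spec: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, bf: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability in [0, 1] for one raster."""
        x = _normalize(np.asarray(bf, dtype=np.float32))
        if x.ndim != 2:
            raise ValidationError(f"bf: expected 2-D raster, got {x.ndim}-D")
        h, w = x.shape
        xe = x[: h - h % 2, : w - w % 2][None, None]
        logits = _forward(self.weights, xe)[0]
        prob = 1.0 / (1.0 + np.exp(-logits[0, 0]))
        if prob.shape != (h, w):  # odd input: replicate the last row/col
            out = np.empty((h, w), dtype=prob.dtype)
            out[: prob.shape[0], : prob.shape[1]] = prob
            if h % 2:
                out[-1, : prob.shape[1]] = prob[-1]
            if w % 2:
                out[:, -1] = out[:, prob.shape[1] - 1]
            prob = out
        return prob

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights)
        sidecar = {"input_spec": self.input_spec, "training_meta": self.training_meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(weights={k: data[k] for k in data.files}, **sidecar)


def _normalize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / (x.std() + 1e-8)


def _init_weights(rng: np.random.Generator, c1: int, c2: int) -> dict[str, np.ndarray]:
    def he(co, ci, k):
        return rng.normal(0, np.sqrt(2.0 / (ci * k * k)), (co, ci, k, k)).astype(np.float32)

    return {
        "w1": he(c1, 1, 3), "b1": np.zeros(c1, np.float32),
        "w2": he(c2, c1, 3), "b2": np.zeros(c2, np.float32),
        "w3": he(c1, c1 + c2, 3), "b3": np.zeros(c1, np.float32),
        "w4": he(1, c1, 1), "b4": np.zeros(1, np.float32),
    }


def _forward(wts: dict, x: np.ndarray, need_cache: bool = False):
    e1 = np.maximum(_conv2d(x, wts["w1"], wts["b1"]), 0)
    p1, pmask = _maxpool2(e1)
    e2 = np.maximum(_conv2d(p1, wts["w2"], wts["b2"]), 0)
    up = _upsample2(e2)
    cat = np.concatenate([up, e1], axis=1)
    d1 = np.maximum(_conv2d(cat, wts["w3"], wts["b3"]), 0)
    logits = _conv2d(d1, wts["w4"], wts["b4"])
    if not need_cache:
        return logits, None
    return logits, {"x": x, "e1": e1, "p1": p1, "pmask": pmask, "e2": e2,
                    "cat": cat, "d1": d1}


def _backward(wts: dict, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    grads = {}
    grads["w4"], grads["b4"], dd1 = _conv2d_backward(cache["d1"], wts["w4"], dlogits)
    dd1 *= cache["d1"] > 0
    grads["w3"], grads["b3"], dcat = _conv2d_backward(cache["cat"], wts["w3"], dd1)
    c2 = cache["e2"].shape[1]
    dup, de1_skip = dcat[:, :c2], dcat[:, c2:]
    de2 = _upsample2_backward(dup)
    de2 *= cache["e2"] > 0
    grads["w2"], grads["b2"], dp1 = _conv2d_backward(cache["p1"], wts["w2"], de2)
    de1 = _maxpool2_backward(dp1, cache["pmask"]) + de1_skip
    de1 *= cache["e1"] > 0
    grads["w1"], grads["b1"], _ = _conv2d_backward(cache["x"], wts["w1"], de1)
    return grads


def _bce_with_logits(logits: np.ndarray, target: np.ndarray, pos_weight: float = 1.0):
    """Mean binary cross-entropy (positive class up-weighted) and its gradient.

    Foreground pixels are rare (organoids cover a small fraction of a
    well), so the positive class is up-weighted to keep the optimum away
    from the all-background solution.
    """
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = -np.mean(
        pos_weight * target * np.log(p + _EPS) + (1 - target) * np.log(1 - p + _EPS)
    )
    grad = ((1 - target) * p - pos_weight * target * (1 - p)) / target.size
    return float(loss), grad.astype(np.float32)


def train_seg_model(
    pairs: list[tuple[np.ndarray, LabeledMask | np.ndarray]],
    epochs: int = 10,
    lr: float = 0.01,
    batch_size: int = 8,
    seed: int = 0,
    channels: tuple[int, int] = (8, 16),
) -> SegModel:
    """Train the encoder–decoder on (brightfield, truth-mask) pairs.

    All rasters must share one shape with even height and width.
    Deterministic given ``seed``; the per-epoch training loss is recorded
    in ``training_meta["loss_per_epoch"]``.
    """
    if not pairs:
        raise ValidationError("pairs: at least one (brightfield, mask) pair required")
    shapes = {np.asarray(bf).shape for bf, _ in pairs}
    if len(shapes) != 1:
        raise ValidationError(f"pairs: rasters must share one shape, got {shapes}")
    h, w = shapes.pop()
    if h % 2 or w % 2:
        raise ValidationError("pairs: raster height and width must be even")

    x = np.stack([_normalize(np.asarray(bf, dtype=np.float32)) for bf, _ in pairs])[:, None]
    y = np.stack(
        [
            (m.foreground() if isinstance(m, LabeledMask) else np.asarray(m) > 0)
            for _, m in pairs
        ]
    ).astype(np.float32)[:, None]

    fg_frac = float(y.mean())
    pos_weight = float(np.clip((1 - fg_frac) / max(fg_frac, 1e-4), 1.0, 10.0))

    rng = np.random.default_rng(seed)
    wts = _init_weights(rng, *channels)
    m = {k: np.zeros_like(v) for k, v in wts.items()}
    v = {k: np.zeros_like(val) for k, val in wts.items()}
    b1, b2 = 0.9, 0.999
    step = 0
    loss_per_epoch: list[float] = []

    n = len(pairs)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits, cache = _forward(wts, x[idx], need_cache=True)
            loss, dlogits = _bce_with_logits(logits, y[idx], pos_weight)
            grads = _backward(wts, cache, dlogits)
            step += 1
            for k in wts:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                wts[k] -= (lr * mh / (np.sqrt(vh) + 1e-8)).astype(np.float32)
            epoch_loss += loss * len(idx)
        loss_per_epoch.append(epoch_loss / n)

    return SegModel(
        weights=wts,
        input_spec={"normalization": "per-image standardization",
                    "channels": list(channels), "train_shape": [h, w]},
        training_meta={"epochs": epochs, "lr": lr, "batch_size": batch_size,
                       "seed": seed, "loss": "weighted-bce",
                       "pos_weight": pos_weight, "loss_per_epoch": loss_per_epoch},
    )


def segment_fcn(
    bf: np.ndarray,
    model: SegModel,
    threshold: float = 0.5,
    params: dict | None = None,
    frame: int = 0,
) -> LabeledMask:
    """Segment a brightfield raster with a trained network.

    The probability map is cut at ``threshold`` and passed through the
    same post-processing chain as the classical path (closing, hole fill,
    components, minimum area).
    """
    bf = np.asarray(bf, dtype=float)
    if bf.ndim != 2:
        raise ValidationError(f"bf: expected 2-D raster, got {bf.ndim}-D")
    prob = model.predict_proba(bf)
    p = {**DEFAULT_PARAMS, **(params or {})}
    return _postprocess(prob > threshold, p, "fcn", frame)
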