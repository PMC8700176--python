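"""Training recipe and whole-volume inference for the correction networks.

The loss is the Euclidean (squared L2) distance between the network
output and the gamma-reference label patch, reported as the mean over
the mini-batch of per-patch squared-error sums; the optimizer applies
a per-pixel normalization to that gradient so the stated SGD step size
is stable for either label size (see _optim_loss_and_grad).
Optimization is classical momentum SGD (batch 128, lr 0.01, momentum
0.9 by default).  CNN3 adds the weighted companion losses of its
deep-supervision heads.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import TrainedModel, backward, forward
from .simulate import ImageVolume
from .dataset import PatchPairSet, normalize_volume


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    iterations: int = 2000
    seed: int = 0
    loss: str = "euclidean"

    def __post_init__(self) -> None:
        if min(self.batch_size, self.iterations) < 1:
            raise ValueError("batch_size and iterations must be >= 1")
        if self.learning_rate < 0 or not (0 <= self.momentum < 1):
            raise ValueError("bad learning_rate/momentum")
        if self.loss != "euclidean":
            raise ValueError("only the euclidean loss is supported")


def euclidean_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean over the batch of per-patch squared-error sums."""
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {label.shape}")
    n = pred.shape[0]
    return float(((pred - label) ** 2).reshape(n, -1).sum(axis=1).mean())


def euclidean_loss_grad(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    return (2.0 / pred.shape[0]) * (pred - label)


def _optim_loss_and_grad(pred: np.ndarray, label: np.ndarray):
    """Per-pixel-normalized Euclidean objective used by the optimizer.

    The reported loss is the per-patch squared-error sum; dividing by
    the patch pixel count for optimization makes the stated SGD step
    size (lr 0.01, momentum 0.9) stable regardless of label size — with
    the raw per-patch sum the very first updates already exceed the
    Xavier weight scale and training diverges.
    """
    npix = pred.shape[1] * pred.shape[2]
    return (euclidean_loss(pred, label),
            euclidean_loss_grad(pred, label) / npix)


class _IndexStream:
    """Endless seeded epoch-reshuffled index stream over the dataset."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.perm = rng.permutation(n)
        self.pos = 0

    def take(self, k: int) -> np.ndarray:
        out = []
        while k > 0:
            if self.pos == self.n:
                self.perm = self.rng.permutation(self.n)
                self.pos = 0
            got = min(k, self.n - self.pos)
            out.append(self.perm[self.pos:self.pos + got])
            self.pos += got
            k -= got
        return np.concatenate(out)


def train(model: TrainedModel, data: PatchPairSet,
          cfg: TrainConfig) -> TrainedModel:
    """Momentum-SGD training; returns a new TrainedModel (input untouched).

    Raises RuntimeError with the offending iteration if the loss becomes
    non-finite.
    """
    if data.split != "train":
        raise ValueError("train() expects a PatchPairSet with split='train'")
    if data.label_size != model.spec.output_size:
        raise ValueError(
            f"label size {data.label_size} does not match network output "
            f"size {model.spec.output_size}")
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)
    stream = _IndexStream(len(data), rng)
    head_ws = [w for _s, w in model.spec.supervision_heads]
    vel = {(g, i, n): np.zeros_like(t) for g, i, n, t in model.parameters()}

    for it in range(cfg.iterations):
        idx = stream.take(cfg.batch_size)
        x = data.inputs[idx][..., None]
        y = data.labels[idx][..., None]
        out, heads, cache = forward(model, x, want_cache=True)
        loss, d_main = _optim_loss_and_grad(out, y)
        d_heads = []
        for w, h in zip(head_ws, heads):
            hl, hg = _optim_loss_and_grad(h, y)
            loss += w * hl
            d_heads.append(w * hg)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (loss={loss}) at iteration {it}")
        grads = backward(model, cache, d_main, d_heads)
        for g, i, name, tensor in model.parameters():
            grad = grads[g][i][name]
            v = vel[(g, i, name)]
            v *= cfg.momentum
            v -= cfg.learning_rate * grad
            tensor += v
        model.history.append(loss)
    return model


def apply_correction(model: TrainedModel, img: ImageVolume) -> ImageVolume:
    """Correct a Ga-68 volume slice-by-slice, fully convolutionally.

    Each axial slice is normalized by the volume maximum, reflect-padded
    by the network's total shrinkage so the output matches the input
    shape, forwarded, rescaled to count units and clamped at zero.
    """
    if img.provenance != "ga68":
        raise ValueError("apply_correction expects a ga68 image")
    norm, scale = normalize_volume(img)
    m = model.spec.total_shrink // 2
    H, W, nz = img.data.shape
    out = np.empty_like(img.data, dtype=np.float32)
    for z in range(nz):
        sl = np.pad(norm.data[:, :, z], m, mode="reflect")
        y, _heads, _c = forward(model, sl[None, :, :, None])
        out[:, :, z] = y[0, :, :, 0]
    out = np.maximum(out * np.float32(scale), 0.0)
    return ImageVolume(data=out, voxel_size_mm=img.voxel_size_mm,
                       provenance="prc", source_config_id=img.source_config_id,
                       model_id=model.spec.arch_id,
                       meta={"normalization_scale": scale,
                             "source_meta": img.meta})
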