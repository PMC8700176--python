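"""Convolutional architectures for positron-range deblurring.

Three fully-convolutional networks, all built from valid (no-padding)
convolutions so that border voxels never rely on fabricated context:

``CNN1``
    3 layers, kernels 9-1-5, channels 64-32-1 (SRCNN-style
    super-resolution network); a 32x32 input yields a 20x20 output.
``CNN2``
    4 layers, kernels 7-5-3-3, channels 64-64-32-1; 32x32 -> 18x18.
``CNN3``
    CNN2 backbone with deep supervision: every hidden stage feeds a 1x1
    prediction head whose (center-cropped) output gets its own companion
    loss, and layer inputs densely concatenate all earlier feature maps
    (center-cropped to the current spatial size).

The forward/backward passes are implemented directly in numpy
(channels-last im2col feeding BLAS matmuls); weights use Xavier/Glorot
initialization, var = 2/(fan_in + fan_out), biases start at zero.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ARCH_IDS = ("CNN1", "CNN2", "CNN3")
DEFAULT_HEAD_WEIGHT = 0.3


@dataclass
class LayerSpec:
    kernel_size: int
    out_channels: int
    activation: str          # "relu" or "linear"


@dataclass
class ModelSpec:
    """Architecture definition: ordered valid-conv layers plus options."""

    arch_id: str
    layers: list
    dense_connections: bool = False
    supervision_heads: list = field(default_factory=list)  # (stage, weight)
    input_size: int = 32

    @property
    def total_shrink(self) -> int:
        return sum(l.kernel_size - 1 for l in self.layers)

    @property
    def output_size(self) -> int:
        return self.input_size - self.total_shrink

    def stage_sizes(self, input_size: int | None = None) -> list[int]:
        """Spatial size after the input and after each layer."""
        s = input_size if input_size is not None else self.input_size
        sizes = [s]
        for l in self.layers:
            sizes.append(sizes[-1] - (l.kernel_size - 1))
        return sizes

    def in_channels(self) -> list[int]:
        """Input channel count of each conv layer (dense concat aware)."""
        outs = [1] + [l.out_channels for l in self.layers]
        if not self.dense_connections:
            return outs[:-1]
        return [sum(outs[: i + 1]) for i in range(len(self.layers))]


def build_model(arch_id: str,
                head_weight: float = DEFAULT_HEAD_WEIGHT) -> ModelSpec:
    """Construct the spec for CNN1, CNN2 or CNN3."""
    if arch_id == "CNN1":
        return ModelSpec("CNN1", [
            LayerSpec(9, 64, "relu"),
            LayerSpec(1, 32, "relu"),
            LayerSpec(5, 1, "linear"),
        ])
    if arch_id == "CNN2":
        return ModelSpec("CNN2", [
            LayerSpec(7, 64, "relu"),
            LayerSpec(5, 64, "relu"),
            LayerSpec(3, 32, "relu"),
            LayerSpec(3, 1, "linear"),
        ])
    if arch_id == "CNN3":
        spec = build_model("CNN2")
        return ModelSpec("CNN3", spec.layers, dense_connections=True,
                         supervision_heads=[(1, head_weight),
                                            (2, head_weight),
                                            (3, head_weight)])
    raise ValueError(f"unknown arch_id {arch_id!r}; expected one of {ARCH_IDS}")


@dataclass
class TrainedModel:
    """A ModelSpec plus its (possibly untrained) weights and history."""

    spec: ModelSpec
    weights: dict            # {"conv": [{"W","b"}...], "heads": [{"W","b"}...]}
    history: list = field(default_factory=list)
    seed: int | None = None

    def copy(self) -> "TrainedModel":
        return TrainedModel(spec=self.spec,
                            weights=copy.deepcopy(self.weights),
                            history=list(self.history), seed=self.seed)

    def parameters(self):
        """Yield (group, index, name, tensor) over all parameters."""
        for i, p in enumerate(self.weights["conv"]):
            yield ("conv", i, "W", p["W"])
            yield ("conv", i, "b", p["b"])
        for i, p in enumerate(self.weights["heads"]):
            yield ("heads", i, "W", p["W"])
            yield ("heads", i, "b", p["b"])


def _xavier(rng: np.random.Generator, out_c: int, in_c: int, k: int) -> np.ndarray:
    fan_in = in_c * k * k
    fan_out = out_c * k * k
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(out_c, in_c, k, k)).astype(np.float32)


def init_weights(spec: ModelSpec, seed: int) -> TrainedModel:
    """Xavier-initialized filters, zero biases, fully seeded."""
    rng = np.random.default_rng(seed)
    in_ch = spec.in_channels()
    conv = []
    for l, cin in zip(spec.layers, in_ch):
        conv.append({"W": _xavier(rng, l.out_channels, cin, l.kernel_size),
                     "b": np.zeros(l.out_channels, dtype=np.float32)})
    heads = []
    for stage, _w in spec.supervision_heads:
        cin = spec.layers[stage - 1].out_channels
        heads.append({"W": _xavier(rng, 1, cin, 1),
                      "b": np.zeros(1, dtype=np.float32)})
    return TrainedModel(spec=spec, weights={"conv": conv, "heads": heads},
                        seed=seed)


# -- conv primitives ---------------------------------------------------------
#
# Feature maps are carried channels-last, (N, H, W, C): im2col then copies
# contiguous channel runs and the GEMM writes the output layout directly,
# which is what keeps the pure-numpy training loop fast.  Weights are
# stored canonically as (C_out, C_in, k, k).

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*Ho*Wo, k*k*C) patch matrix.

    Column order is (row-offset, col-offset, channel), matching the
    weight reshape in conv_valid.  1x1 kernels and single-channel inputs
    take cheaper paths (no or contiguous-run copies).
    """
    c = x.shape[3]
    if k == 1:
        return np.ascontiguousarray(x).reshape(-1, c)
    if c == 1:
        win = sliding_window_view(x[..., 0], (k, k), axis=(1, 2))
        return np.ascontiguousarray(win).reshape(-1, k * k)
    win = sliding_window_view(x, (k, k), axis=(1, 2))   # N,Ho,Wo,C,k,k
    n, ho, wo = win.shape[:3]
    return (np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
            .reshape(n * ho * wo, k * k * c))


def conv_valid(x: np.ndarray, W: np.ndarray, b: np.ndarray,
               cols: np.ndarray | None = None) -> np.ndarray:
    """Valid 2D convolution (cross-correlation).

    x: (N,H,W,Ci) channels-last; W: (Co,Ci,k,k); ``cols`` may pass a
    precomputed im2col matrix of x.
    """
    k = W.shape[-1]
    co = W.shape[0]
    n, H, Wd = x.shape[:3]
    ho, wo = H - k + 1, Wd - k + 1
    if cols is None:
        cols = _im2col(x, k)
    W2 = W.transpose(2, 3, 1, 0).reshape(-1, co)        # (k*k*Ci, Co)
    y = cols @ W2 + b
    return y.reshape(n, ho, wo, co)


def conv_backward(x: np.ndarray, W: np.ndarray, dy: np.ndarray,
                  cols: np.ndarray | None = None, need_dx: bool = True):
    """Gradients of conv_valid: returns (dx, dW, db); dW in (Co,Ci,k,k).

    ``need_dx=False`` skips the (expensive) full-correlation for the
    input gradient — used at the first layer, whose input is the image.
    """
    k = W.shape[-1]
    co, ci = W.shape[:2]
    n, H, Wd = x.shape[:3]
    if cols is None:
        cols = _im2col(x, k)
    dy_cols = dy.reshape(-1, co)
    dW = (cols.T @ dy_cols).reshape(k, k, ci, co).transpose(3, 2, 0, 1)
    db = dy_cols.sum(axis=0)
    dx = None
    if need_dx:
        pad = k - 1
        dyp = np.pad(dy, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols_dy = _im2col(dyp, k)
        V = W[:, :, ::-1, ::-1].transpose(2, 3, 0, 1).reshape(-1, ci)
        dx = (cols_dy @ V).reshape(n, H, Wd, ci)
    return dx, np.ascontiguousarray(dW), db


def center_crop(x: np.ndarray, size: int) -> np.ndarray:
    """Symmetric spatial center crop of (N,H,W,C) to H=W=size."""
    H = x.shape[1]
    if H == size:
        return x
    off = (H - size) // 2
    return x[:, off:off + size, off:off + size, :]


def _uncrop(dx: np.ndarray, full: int) -> np.ndarray:
    """Adjoint of center_crop: zero-pad gradient back to (full, full)."""
    size = dx.shape[1]
    if size == full:
        return dx
    off = (full - size) // 2
    out = np.zeros((dx.shape[0], full, full, dx.shape[3]), dtype=dx.dtype)
    out[:, off:off + size, off:off + size, :] = dx
    return out


# -- forward / backward over an architecture ---------------------------------

def forward(model: TrainedModel, x: np.ndarray, want_cache: bool = False):
    """Run the network on x:(N,H,W,1) (channels-last).

    Returns (main_out, head_outs, cache); ``head_outs`` are the deep-
    supervision predictions center-cropped to the main output's size
    (empty for CNN1/CNN2).  ``cache`` supports :func:`backward`.
    """
    spec = model.spec
    x = np.ascontiguousarray(x, dtype=np.float32)
    maps = [x]           # maps[i] = output of layer i (0 = input)
    pres = [None]
    inps = [None]
    colss = [None]
    for i, (layer, p) in enumerate(zip(spec.layers, model.weights["conv"]),
                                   start=1):
        target = maps[-1].shape[1]
        if spec.dense_connections:
            inp = np.concatenate([center_crop(m, target) for m in maps], axis=3)
        else:
            inp = maps[-1]
        cols = _im2col(inp, layer.kernel_size)
        pre = conv_valid(inp, p["W"], p["b"], cols=cols)
        out = np.maximum(pre, 0.0) if layer.activation == "relu" else pre
        maps.append(out)
        pres.append(pre)
        inps.append(inp)
        colss.append(cols if want_cache else None)
    final = maps[-1]
    out_size = final.shape[1]
    head_outs = []
    for (stage, _w), hp in zip(spec.supervision_heads, model.weights["heads"]):
        hmap = conv_valid(maps[stage], hp["W"], hp["b"])
        head_outs.append(center_crop(hmap, out_size))
    cache = ({"maps": maps, "pres": pres, "inps": inps,
              "cols": colss} if want_cache else None)
    return final, head_outs, cache


def backward(model: TrainedModel, cache: dict, d_main: np.ndarray,
             d_heads: list | None = None) -> dict:
    """Backpropagate output gradients; returns grads mirroring the weights."""
    spec = model.spec
    maps, pres, inps = cache["maps"], cache["pres"], cache["inps"]
    colss = cache["cols"]
    nL = len(spec.layers)
    g_maps = [np.zeros_like(m) for m in maps]
    g_maps[nL] += d_main

    grads = {"conv": [None] * nL, "heads": []}
    d_heads = d_heads or []
    for (stage, _w), hp, dh in zip(spec.supervision_heads,
                                   model.weights["heads"], d_heads):
        full = maps[stage].shape[1]
        dh_full = _uncrop(dh, full)
        dxh, dWh, dbh = conv_backward(maps[stage], hp["W"], dh_full)
        grads["heads"].append({"W": dWh, "b": dbh})
        g_maps[stage] += dxh

    for i in range(nL, 0, -1):
        layer = spec.layers[i - 1]
        d_out = g_maps[i]
        if layer.activation == "relu":
            d_pre = d_out * (pres[i] > 0)
        else:
            d_pre = d_out
        p = model.weights["conv"][i - 1]
        d_inp, dW, db = conv_backward(inps[i], p["W"], d_pre,
                                      cols=colss[i], need_dx=(i > 1))
        grads["conv"][i - 1] = {"W": dW, "b": db}
        if i == 1:
            continue
        if spec.dense_connections:
            c0 = 0
            for j, m in enumerate(maps[:i]):
                cj = m.shape[3]
                g_maps[j] += _uncrop(d_inp[..., c0:c0 + cj], m.shape[1])
                c0 += cj
        else:
            g_maps[i - 1] += d_inp
    return grads
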