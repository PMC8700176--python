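"""Patch-pair datasets for training and testing the correction networks.

Training examples are 32x32 axial sub-images of the Ga-68 volume paired
with the center crop (20x20 or 18x18, matching the network's valid-
convolution shrinkage) of the same location in the back-to-back-gamma
volume.  Patches are extracted on a deterministic raster grid — stride
14 for training volumes, 21 for testing volumes — slice by slice, and
all-zero (air) patches are dropped.  Volumes are normalized to [0, 1] by
their global maximum before patching; the scale is recorded so corrected
images can be mapped back to count units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import ImageVolume

PATCH_SIZE = 32
TRAIN_STRIDE = 14
TEST_STRIDE = 21
LABEL_SIZES = (20, 18)

#: rod5 TBRs patched into training vs held out for testing
TRAIN_TBRS = frozenset({0.0, 4.0, 5.0, 8.0})
TEST_TBRS = frozenset({2.0, 10.0, 16.0, 20.0})


@dataclass
class PairedVolumes:
    """One phantom configuration's simulated image pair."""

    config_id: str
    family: str
    tbr: float | None
    ga68: ImageVolume
    gamma: ImageVolume


@dataclass
class PatchPairSet:
    """Aligned (input, center-cropped label) patch arrays.

    ``provenance`` has one row per patch: (volume index, slice, row, col);
    ``config_ids`` maps volume index back to its configuration.
    """

    inputs: np.ndarray          # (N, 32, 32) float32
    labels: np.ndarray          # (N, K, K) float32
    stride: int
    split: str
    label_size: int
    normalization: dict = field(default_factory=dict)  # config_id -> scale
    provenance: np.ndarray | None = None               # (N, 4) int32
    config_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @staticmethod
    def concat(parts: list["PatchPairSet"]) -> "PatchPairSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        norm = {}
        cids = []
        provs = []
        for i, p in enumerate(parts):
            if (p.stride, p.split, p.label_size) != (first.stride, first.split,
                                                     first.label_size):
                raise ValueError("incompatible patch sets")
            norm.update(p.normalization)
            off = len(cids)
            cids.extend(p.config_ids)
            prov = p.provenance.copy()
            prov[:, 0] += off
            provs.append(prov)
        return PatchPairSet(
            inputs=np.concatenate([p.inputs for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            stride=first.stride, split=first.split,
            label_size=first.label_size, normalization=norm,
            provenance=np.concatenate(provs), config_ids=cids)


def normalize_volume(img: ImageVolume) -> tuple[ImageVolume, float]:
    """Divide a volume by its global maximum; an all-zero volume is returned
    unchanged with scale 1."""
    m = float(img.data.max()) if img.data.size else 0.0
    if m <= 0:
        return img, 1.0
    return replace(img, data=(img.data / np.float32(m)).astype(np.float32)), m


def grid_positions(extent: int, patch: int, stride: int) -> np.ndarray:
    """Raster start offsets along one axis: 0, stride, ... <= extent-patch."""
    if extent < patch:
        raise ValueError(f"extent {extent} smaller than patch {patch}")
    n = (extent - patch) // stride + 1
    return np.arange(n) * stride


def extract_patch_grid(input_img: ImageVolume, label_img: ImageVolume,
                       patch: int = PATCH_SIZE, stride: int = TRAIN_STRIDE,
                       label_size: int = 18, split: str = "train",
                       drop_empty: bool = True,
                       volume_index: int = 0) -> PatchPairSet:
    """Strided slice-by-slice patch extraction from an aligned image pair.

    Labels are the center crop of each input footprint, offset
    (patch - label_size)/2 in both in-plane axes.
    """
    if input_img.data.shape != label_img.data.shape:
        raise ValueError("input and label volumes differ in shape")
    if label_size not in LABEL_SIZES:
        raise ValueError(f"label_size must be one of {LABEL_SIZES}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    H, W, nz = input_img.data.shape
    rows = grid_positions(H, patch, stride)
    cols = grid_positions(W, patch, stride)
    off = (patch - label_size) // 2

    inputs, labels, prov = [], [], []
    for z in range(nz):
        sl_in = input_img.data[:, :, z]
        sl_lab = label_img.data[:, :, z]
        for r in rows:
            for c in cols:
                pin = sl_in[r:r + patch, c:c + patch]
                if drop_empty and pin.max() <= 0:
                    continue
                inputs.append(pin)
                labels.append(sl_lab[r + off:r + off + label_size,
                                     c + off:c + off + label_size])
                prov.append((volume_index, z, r, c))
    n = len(inputs)
    shape_in = (n, patch, patch)
    shape_lab = (n, label_size, label_size)
    return PatchPairSet(
        inputs=np.array(inputs, dtype=np.float32).reshape(shape_in),
        labels=np.array(labels, dtype=np.float32).reshape(shape_lab),
        stride=stride, split=split, label_size=label_size,
        provenance=np.array(prov, dtype=np.int32).reshape(n, 4),
        config_ids=[input_img.source_config_id])


def _patch_one(vol: PairedVolumes, stride: int, label_size: int,
               split: str) -> PatchPairSet:
    ga68_n, s = normalize_volume(vol.ga68)
    gamma_n, _ = normalize_volume(vol.gamma)
    pps = extract_patch_grid(ga68_n, gamma_n, stride=stride,
                             label_size=label_size, split=split)
    pps.normalization = {vol.config_id: s}
    return pps


def make_splits(volumes: list[PairedVolumes], label_size: int = 18,
                train_brain_fraction: float = 0.8
                ) -> tuple[PatchPairSet, PatchPairSet]:
    """Phantom-level train/test split with stride-14 / stride-21 patching.

    Brain volumes: the first 80% (16 of 20 in the full plan) train, the
    rest test.  rod5: TBR in {0,4,5,8} trains, {2,10,16,20} tests.
    sphere1 and rod20 are evaluation-only and are never patched.
    """
    brains = [v for v in volumes if v.family == "brain"]
    rod5s = [v for v in volumes if v.family == "rod5"]
    n_train_brain = int(round(train_brain_fraction * len(brains)))
    train_vols = brains[:n_train_brain] + \
        [v for v in rod5s if v.tbr in TRAIN_TBRS]
    test_vols = brains[n_train_brain:] + \
        [v for v in rod5s if v.tbr in TEST_TBRS]

    train_ids = {v.config_id for v in train_vols}
    test_ids = {v.config_id for v in test_vols}
    if train_ids & test_ids:
        raise ValueError(f"train/test overlap: {sorted(train_ids & test_ids)}")

    train = PatchPairSet.concat(
        [_patch_one(v, TRAIN_STRIDE, label_size, "train") for v in train_vols])
    test = PatchPairSet.concat(
        [_patch_one(v, TEST_STRIDE, label_size, "test") for v in test_vols])
    return train, test
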