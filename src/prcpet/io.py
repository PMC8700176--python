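"""On-disk formats: NIfTI volumes with JSON sidecars, HDF5 patch stores,
and single-file model checkpoints (.npz + embedded spec JSON)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .dataset import PatchPairSet
from .models import LayerSpec, ModelSpec, TrainedModel
from .phantoms import VoxelPhantom
from .simulate import ImageVolume


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_phantom(ph: VoxelPhantom, stem: Path) -> None:
    stem = Path(stem)
    nib.save(nib.Nifti1Image(ph.activity.astype(np.float32),
                             _affine(ph.voxel_size_mm)),
             str(stem) + "_activity.nii")
    nib.save(nib.Nifti1Image(ph.labels.astype(np.int16),
                             _affine(ph.voxel_size_mm)),
             str(stem) + "_labels.nii")
    sidecar = {"config_id": ph.config_id, "family": ph.family, "tbr": ph.tbr,
               "voxel_size_mm": ph.voxel_size_mm, "meta": _jsonable(ph.meta)}
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_phantom(stem: Path) -> VoxelPhantom:
    stem = Path(stem)
    side = json.loads(Path(str(stem) + ".json").read_text())
    act = np.asarray(nib.load(str(stem) + "_activity.nii").dataobj,
                     dtype=np.float32)
    lab = np.asarray(nib.load(str(stem) + "_labels.nii").dataobj,
                     dtype=np.int16)
    meta = side["meta"]
    # JSON round-trips dict keys as strings; restore integer rod keys
    for key in ("rod_diameters_mm", "rod_centers_mm", "rods"):
        if key in meta:
            meta[key] = {int(k): v for k, v in meta[key].items()}
    return VoxelPhantom(activity=act, labels=lab,
                        voxel_size_mm=side["voxel_size_mm"],
                        family=side["family"], config_id=side["config_id"],
                        tbr=side["tbr"], meta=meta)


def save_image(img: ImageVolume, stem: Path) -> None:
    stem = Path(stem)
    nib.save(nib.Nifti1Image(img.data.astype(np.float32),
                             _affine(img.voxel_size_mm)), str(stem) + ".nii")
    sidecar = {"provenance": img.provenance,
               "source_config_id": img.source_config_id,
               "model_id": img.model_id,
               "voxel_size_mm": img.voxel_size_mm, "meta": _jsonable(img.meta)}
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_image(stem: Path) -> ImageVolume:
    stem = Path(stem)
    side = json.loads(Path(str(stem) + ".json").read_text())
    data = np.asarray(nib.load(str(stem) + ".nii").dataobj, dtype=np.float32)
    return ImageVolume(data=data, voxel_size_mm=side["voxel_size_mm"],
                       provenance=side["provenance"],
                       source_config_id=side["source_config_id"],
                       model_id=side["model_id"], meta=side["meta"])


def save_patches(pps: PatchPairSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=pps.inputs, compression="gzip")
        f.create_dataset("labels", data=pps.labels, compression="gzip")
        f.create_dataset("provenance", data=pps.provenance)
        f.attrs["stride"] = pps.stride
        f.attrs["split"] = pps.split
        f.attrs["label_size"] = pps.label_size
        f.attrs["config_ids"] = json.dumps(pps.config_ids)
        f.attrs["normalization"] = json.dumps(_jsonable(pps.normalization))


def load_patches(path: Path) -> PatchPairSet:
    with h5py.File(path, "r") as f:
        return PatchPairSet(
            inputs=f["inputs"][...], labels=f["labels"][...],
            provenance=f["provenance"][...],
            stride=int(f.attrs["stride"]), split=str(f.attrs["split"]),
            label_size=int(f.attrs["label_size"]),
            config_ids=json.loads(f.attrs["config_ids"]),
            normalization=json.loads(f.attrs["normalization"]))


def save_checkpoint(model: TrainedModel, path: Path) -> None:
    spec = model.spec
    spec_json = json.dumps({
        "arch_id": spec.arch_id,
        "layers": [[l.kernel_size, l.out_channels, l.activation]
                   for l in spec.layers],
        "dense_connections": spec.dense_connections,
        "supervision_heads": spec.supervision_heads,
        "input_size": spec.input_size,
        "seed": model.seed,
    })
    arrays = {"history": np.asarray(model.history, dtype=np.float64)}
    for g, i, name, t in model.parameters():
        arrays[f"{g}.{i}.{name}"] = t
    np.savez(path, spec=np.bytes_(spec_json.encode()), **arrays)


def load_checkpoint(path: Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["spec"]).decode())
        spec = ModelSpec(
            arch_id=meta["arch_id"],
            layers=[LayerSpec(*l) for l in meta["layers"]],
            dense_connections=meta["dense_connections"],
            supervision_heads=[tuple(h) for h in meta["supervision_heads"]],
            input_size=meta["input_size"])
        conv, heads = [], []
        for i in range(len(spec.layers)):
            conv.append({"W": z[f"conv.{i}.W"], "b": z[f"conv.{i}.b"]})
        for i in range(len(spec.supervision_heads)):
            heads.append({"W": z[f"heads.{i}.W"], "b": z[f"heads.{i}.b"]})
        return TrainedModel(spec=spec, weights={"conv": conv, "heads": heads},
                            history=list(z["history"]), seed=meta["seed"])
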