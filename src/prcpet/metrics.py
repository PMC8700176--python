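"""NEMA NU-4-style image-quality metrics.

* RMSE / PSNR over the whole volume, test image against the gamma
  reference (PSNR uses the reference maximum by default).
* Recovery coefficient RC = AVG_target / AVG_uniform per rod of the
  five-rod phantom: the central 50 mm of slices are averaged, the
  max-intensity pixel of each rod located on that average, and an axial
  line profile at that pixel gives AVG/SD_target; AVG/SD_uniform come
  from a 10-mm disc on the (averaged) uniform cylinder of the sphere
  phantom.  CV_RC adds the two relative SDs in quadrature.
* Spill-over ratio SOR = AVG_cold / AVG_hot with 10-mm discs on the cold
  sphere (at its center slice) and on the hot cylinder in the same
  slice; CV_SOR in quadrature as for RC.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .phantoms import VoxelPhantom
from .simulate import ImageVolume

ROI_DIAMETER_MM = 10.0
PROFILE_LENGTH_MM = 50.0


@dataclass
class ImagePairStats:
    rmse: float
    psnr: float
    v: int


@dataclass
class RodRecoveryStats:
    """Per-rod-diameter RC and CV_RC plus the shared uniform-region stats."""

    per_rod: dict = field(default_factory=dict)  # diameter -> dict
    avg_uniform: float = 0.0
    sd_uniform: float = 0.0

    def rc(self, diameter: float) -> float:
        return self.per_rod[diameter]["rc"]

    def cv_rc(self, diameter: float) -> float:
        return self.per_rod[diameter]["cv_rc"]


@dataclass
class SpilloverStats:
    sor: float
    cv_sor: float | None
    avg_cold: float
    sd_cold: float
    avg_hot: float
    sd_hot: float
    degenerate: bool = False


def compute_pair_stats(reference: ImageVolume, test: ImageVolume,
                       i_max_source: str = "reference") -> ImagePairStats:
    """Whole-volume RMSE and PSNR of ``test`` against the gamma reference."""
    a = reference.data.astype(np.float64)
    b = test.data.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    v = a.size
    rmse = math.sqrt(float(((a - b) ** 2).sum()) / v)
    i_max = float(a.max() if i_max_source == "reference" else b.max())
    psnr = math.inf if rmse == 0 else 20.0 * math.log10(i_max / rmse)
    return ImagePairStats(rmse=rmse, psnr=psnr, v=v)


def _central_slab(nz: int, voxel_mm: float,
                  length_mm: float = PROFILE_LENGTH_MM) -> slice:
    half = length_mm / 2.0 / voxel_mm
    zc = (nz - 1) / 2.0
    lo = int(math.ceil(zc - half))
    hi = int(math.floor(zc + half))
    return slice(max(lo, 0), min(hi, nz - 1) + 1)


def disc_mask(shape2d, center_rc, radius_vox: float) -> np.ndarray:
    """Pixels whose centers lie within ``radius_vox`` of ``center_rc``."""
    rr = np.arange(shape2d[0])[:, None]
    cc = np.arange(shape2d[1])[None, :]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 < radius_vox ** 2


def _mm_to_index(xy_mm, shape2d, h):
    return ((shape2d[0] - 1) / 2.0 + xy_mm[0] / h,
            (shape2d[1] - 1) / 2.0 + xy_mm[1] / h)


def _uniform_region_stats(img_sphere1: ImageVolume,
                          sphere_phantom: VoxelPhantom):
    """Mean/SD in a 10-mm disc on the averaged hot cylinder."""
    h = img_sphere1.voxel_size_mm
    data = img_sphere1.data
    slab = _central_slab(data.shape[2], h)
    avg_img = data[:, :, slab].mean(axis=2, dtype=np.float64)
    center = _mm_to_index(sphere_phantom.meta["hot_roi_center_mm"],
                          avg_img.shape, h)
    roi = disc_mask(avg_img.shape, center, ROI_DIAMETER_MM / 2.0 / h)
    vals = avg_img[roi]
    return float(vals.mean()), float(vals.std())


def compute_rc(img_rod5: ImageVolume, rod5_phantom: VoxelPhantom,
               img_sphere1: ImageVolume,
               sphere_phantom: VoxelPhantom) -> RodRecoveryStats:
    """Recovery coefficients of the five rods (NEMA-style procedure)."""
    if img_rod5.voxel_size_mm != img_sphere1.voxel_size_mm:
        raise ValueError("rod5 and sphere1 images on different grids")
    h = img_rod5.voxel_size_mm
    data = img_rod5.data
    slab = _central_slab(data.shape[2], h)
    avg_img = data[:, :, slab].mean(axis=2, dtype=np.float64)

    avg_u, sd_u = _uniform_region_stats(img_sphere1, sphere_phantom)
    out = RodRecoveryStats(avg_uniform=avg_u, sd_uniform=sd_u)

    labels_mid = rod5_phantom.labels[:, :, rod5_phantom.labels.shape[2] // 2]
    for rod_id in rod5_phantom.meta["rod_labels"]:
        d = rod5_phantom.meta["rod_diameters_mm"][rod_id]
        fp = binary_dilation(labels_mid == rod_id)
        if not fp.any():
            raise ValueError(f"rod {rod_id} ({d} mm) has no voxels on this grid")
        # first (row, col) in C order among maxima -> lexicographic tie-break
        masked = np.where(fp, avg_img, -np.inf)
        r, c = np.unravel_index(int(np.argmax(masked)), masked.shape)
        profile = data[r, c, slab].astype(np.float64)
        avg_t = float(profile.mean())
        sd_t = float(profile.std())
        rc = avg_t / avg_u if avg_u > 0 else math.nan
        if avg_t > 0 and avg_u > 0:
            cv = math.sqrt((sd_t / avg_t) ** 2 + (sd_u / avg_u) ** 2)
        else:
            cv = math.nan
        out.per_rod[d] = {"rc": rc, "cv_rc": cv, "avg_target": avg_t,
                          "sd_target": sd_t, "peak_rc": (int(r), int(c))}
    return out


def compute_sor(img_sphere1: ImageVolume,
                sphere_phantom: VoxelPhantom) -> SpilloverStats:
    """Spill-over ratio of the cold sphere against the hot cylinder."""
    h = img_sphere1.voxel_size_mm
    data = img_sphere1.data
    lab = sphere_phantom.labels
    sph = np.argwhere(lab == sphere_phantom.meta["sphere_label"])
    if sph.size == 0:
        raise ValueError("sphere label empty on this grid")
    zc = int(round(sph[:, 2].mean()))
    sl = data[:, :, zc].astype(np.float64)

    r_vox = ROI_DIAMETER_MM / 2.0 / h
    cold_center = _mm_to_index(sphere_phantom.meta["sphere_center_mm"][:2],
                               sl.shape, h)
    hot_center = _mm_to_index(sphere_phantom.meta["hot_roi_center_mm"],
                              sl.shape, h)
    cold = disc_mask(sl.shape, cold_center, r_vox)
    hot = disc_mask(sl.shape, hot_center, r_vox)
    cyl_or_sph = lab[:, :, zc] > 0
    if np.any(hot & ~cyl_or_sph) or np.any(cold & ~cyl_or_sph):
        raise ValueError("SOR ROI extends beyond the cylinder")

    avg_c, sd_c = float(sl[cold].mean()), float(sl[cold].std())
    avg_h, sd_h = float(sl[hot].mean()), float(sl[hot].std())
    sor = avg_c / avg_h if avg_h > 0 else math.nan
    if avg_c > 0 and avg_h > 0:
        cv = math.sqrt((sd_c / avg_c) ** 2 + (sd_h / avg_h) ** 2)
        degenerate = False
    else:
        cv = None                     # flagged sentinel, not a NaN
        degenerate = True
    return SpilloverStats(sor=sor, cv_sor=cv, avg_cold=avg_c, sd_cold=sd_c,
                          avg_hot=avg_h, sd_hot=sd_h, degenerate=degenerate)


def plot_line_profile(images: dict, row: int, axis: int, z: int,
                      out_png: str) -> None:
    """Save a comparison of in-plane intensity profiles (one per image)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axx = plt.subplots(figsize=(6, 4))
    for name, img in images.items():
        prof = img.data[row, :, z] if axis == 0 else img.data[:, row, z]
        axx.plot(np.arange(prof.size) * img.voxel_size_mm, prof, label=name)
    axx.set_xlabel("position (mm)")
    axx.set_ylabel("intensity (counts)")
    axx.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=110)
    plt.close(fig)
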