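"""Voxelized digital phantoms for preclinical PET studies of positron range.

Four phantom families are provided:

``brain``
    A procedural brain surrogate (cortical shell, white-matter interior,
    deep-structure blobs, ventricle-like cold cavities) standing in for a
    Hoffman-style voxelized brain source.  Translation, rotation and a
    smooth seeded deformation field diversify it into many configurations.
``rod5``
    A 50 mm diameter, 80 mm long cylinder holding five hot rods of
    2/4/6/8/10 mm diameter; the background is filled according to a
    target-to-background ratio (TBR).
``sphere1``
    The same cylinder, uniformly hot, with a single 10 mm cold (water)
    sphere — the spill-over phantom.
``rod20``
    An elliptical cylinder (55 × 50 mm axes) with twenty rods of
    2/3/4/5 mm diameter at two activity levels ("white" and "gray" rods).

All phantoms are activity-concentration maps in Bq/mL on an isotropic
voxel grid (default 0.4 mm), with an integer label grid identifying each
region.  World coordinates sit at voxel centers with the grid centered on
the origin; the third array axis is axial.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# -- geometry and activity constants ----------------------------------------

DEFAULT_VOXEL_MM = 0.4

ROD_ACTIVITY_BQ_PER_ML = 1.69e6     # hot rods / hot cylinder
GRAY_ROD_ACTIVITY_BQ_PER_ML = 8.44e5
BRAIN_TOTAL_ACTIVITY_BQ = 3.7e6

CYLINDER_DIAMETER_MM = 50.0
CYLINDER_LENGTH_MM = 80.0
SPHERE_DIAMETER_MM = 10.0
# sphere sits at half the cylinder radius from the axis; the hot/uniform
# ROI used by the metrics sits diametrically opposite
SPHERE_CENTER_MM = (-12.5, 0.0)
HOT_ROI_CENTER_MM = (12.5, 0.0)

ROD5_DIAMETERS_MM = (2.0, 4.0, 6.0, 8.0, 10.0)
ROD5_RING_RADIUS_MM = 14.0
ROD5_ANGLES_DEG = (90.0, 162.0, 234.0, 306.0, 18.0)

ROD20_MAJOR_AXIS_MM = 55.0   # full major axis -> semi-axis 27.5
ROD20_MINOR_AXIS_MM = 50.0
ROD20_DIAMETERS_MM = (2.0, 3.0, 4.0, 5.0)
ROD20_SECTOR_RADIUS_MM = 14.0
ROD20_SECTOR_ANGLES_DEG = (45.0, 135.0, 225.0, 315.0)

TBR_SERIES = (0, 2, 4, 5, 8, 10, 16, 20)

_FAMILIES = ("brain", "rod5", "sphere1", "rod20")


@dataclass
class VoxelPhantom:
    """A voxelized activity map plus region labels.

    ``activity`` is Bq/mL per voxel (float32); ``labels`` assigns each
    voxel an integer region id (0 = outside everything).  ``meta`` holds
    family-specific geometry (rod centers/diameters, sphere center, ...)
    used downstream by the metrics module.
    """

    activity: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float
    family: str
    config_id: str
    tbr: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity.shape != self.labels.shape:
            raise ValueError("activity and labels shapes differ")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if np.any(self.activity < 0):
            raise ValueError("negative activity")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm ** 3 / 1000.0

    def total_activity_bq(self) -> float:
        """Total activity = sum of concentration x voxel volume."""
        return float(self.activity.sum(dtype=np.float64) * self.voxel_volume_ml)

    def region_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


def _axes_mm(shape: tuple[int, int, int], h: float):
    """Centered voxel-center coordinates along each axis."""
    return tuple((np.arange(n) - (n - 1) / 2.0) * h for n in shape)


def _default_rod_shape(h: float) -> tuple[int, int, int]:
    n = int(round(100.0 / h))
    nz = int(round(CYLINDER_LENGTH_MM / h))
    return (n, n, nz)


def _default_brain_shape(h: float) -> tuple[int, int, int]:
    n = int(round(100.0 / h))
    nz = int(round(116.0 / h))
    return (n, n, nz)


# -- cylinder family ---------------------------------------------------------

def _cylinder_grid(h: float, shape):
    shape = tuple(shape) if shape is not None else _default_rod_shape(h)
    x, y, z = _axes_mm(shape, h)
    X = x[:, None]
    Y = y[None, :]
    return shape, x, y, z, X, Y


def make_rod5_phantom(tbr: float, voxel_size_mm: float = DEFAULT_VOXEL_MM,
                      shape: Sequence[int] | None = None) -> VoxelPhantom:
    """Five-rod contrast phantom at a given target-to-background ratio.

    Rods (2..10 mm) are filled at 1.69e6 Bq/mL; the cylinder background
    gets ``rod_activity / tbr`` for tbr > 0 and is cold for tbr = 0.
    """
    if tbr < 0:
        raise ValueError("tbr must be >= 0")
    h = float(voxel_size_mm)
    shape, x, y, z, X, Y = _cylinder_grid(h, shape)
    r_cyl = CYLINDER_DIAMETER_MM / 2.0
    in_cyl = (X ** 2 + Y ** 2) < r_cyl ** 2

    labels2d = np.zeros(shape[:2], dtype=np.int16)
    rod_centers = {}
    for i, (d, ang) in enumerate(zip(ROD5_DIAMETERS_MM, ROD5_ANGLES_DEG), start=1):
        a = np.deg2rad(ang)
        cx = ROD5_RING_RADIUS_MM * np.cos(a)
        cy = ROD5_RING_RADIUS_MM * np.sin(a)
        in_rod = ((X - cx) ** 2 + (Y - cy) ** 2) < (d / 2.0) ** 2
        labels2d[in_rod] = i
        rod_centers[i] = (float(cx), float(cy))
    bg_id = len(ROD5_DIAMETERS_MM) + 1
    labels2d[in_cyl & (labels2d == 0)] = bg_id

    act2d = np.zeros(shape[:2], dtype=np.float32)
    act2d[(labels2d >= 1) & (labels2d <= 5)] = ROD_ACTIVITY_BQ_PER_ML
    if tbr > 0:
        act2d[labels2d == bg_id] = ROD_ACTIVITY_BQ_PER_ML / tbr

    labels = np.repeat(labels2d[:, :, None], shape[2], axis=2)
    activity = np.repeat(act2d[:, :, None], shape[2], axis=2)
    return VoxelPhantom(
        activity=activity, labels=labels, voxel_size_mm=h, family="rod5",
        config_id=f"rod5_tbr{tbr:g}", tbr=float(tbr),
        meta={
            "rod_labels": list(range(1, 6)),
            "rod_diameters_mm": {i: d for i, d in enumerate(ROD5_DIAMETERS_MM, 1)},
            "rod_centers_mm": rod_centers,
            "background_label": bg_id,
        },
    )


def make_sphere1_phantom(voxel_size_mm: float = DEFAULT_VOXEL_MM,
                         shape: Sequence[int] | None = None) -> VoxelPhantom:
    """Hot cylinder with one 10 mm cold (water-filled) sphere."""
    h = float(voxel_size_mm)
    shape, x, y, z, X, Y = _cylinder_grid(h, shape)
    r_cyl = CYLINDER_DIAMETER_MM / 2.0
    in_cyl = (X ** 2 + Y ** 2) < r_cyl ** 2

    labels = np.zeros(shape, dtype=np.int16)
    labels[in_cyl] = 1
    cx, cy = SPHERE_CENTER_MM
    Z = z[None, None, :]
    in_sph = ((X[..., None] - cx) ** 2 + (Y[..., None] - cy) ** 2 + Z ** 2) \
        < (SPHERE_DIAMETER_MM / 2.0) ** 2
    labels[in_sph] = 2

    activity = np.where(labels == 1, ROD_ACTIVITY_BQ_PER_ML, 0.0).astype(np.float32)
    return VoxelPhantom(
        activity=activity, labels=labels, voxel_size_mm=h, family="sphere1",
        config_id="sphere1",
        meta={
            "cylinder_label": 1, "sphere_label": 2,
            "sphere_center_mm": (cx, cy, 0.0),
            "hot_roi_center_mm": HOT_ROI_CENTER_MM,
            "roi_diameter_mm": 10.0,
        },
    )


def _rod20_layout():
    """Centers, diameters and white/gray flags of the 20-rod phantom.

    Derenzo-style: one quadrant sector per diameter, five rods in a
    triangular 2+3 cluster (pitch 2d) with the apex toward the center;
    within a sector rods alternate white (1.69e6) / gray (8.44e5).
    """
    apex_radius = 8.0
    rods = []
    for d, ang in zip(ROD20_DIAMETERS_MM, ROD20_SECTOR_ANGLES_DEG):
        a = np.deg2rad(ang)
        ca, sa = np.cos(a), np.sin(a)
        row2 = apex_radius + np.sqrt(3.0) * d
        offsets = [(apex_radius, -d), (apex_radius, d),
                   (row2, -2 * d), (row2, 0.0), (row2, 2 * d)]
        for j, (radial, tang) in enumerate(offsets):
            rx = ca * radial - sa * tang
            ry = sa * radial + ca * tang
            rods.append((rx, ry, d, j % 2 == 0))  # True -> white
    return rods


def make_rod20_phantom(voxel_size_mm: float = DEFAULT_VOXEL_MM,
                       shape: Sequence[int] | None = None) -> VoxelPhantom:
    """Twenty-rod resolution phantom in an elliptical cylinder."""
    h = float(voxel_size_mm)
    shape, x, y, z, X, Y = _cylinder_grid(h, shape)
    a_semi = ROD20_MAJOR_AXIS_MM / 2.0
    b_semi = ROD20_MINOR_AXIS_MM / 2.0
    in_ell = (X / a_semi) ** 2 + (Y / b_semi) ** 2 < 1.0

    rods = _rod20_layout()
    # containment and overlap checks
    for rx, ry, d, _ in rods:
        if (rx / a_semi) ** 2 + (ry / b_semi) ** 2 >= 1.0:
            raise ValueError(f"rod center ({rx:.1f},{ry:.1f}) outside ellipse")
    for (x1, y1, d1, _), (x2, y2, d2, _) in itertools.combinations(rods, 2):
        if np.hypot(x1 - x2, y1 - y2) < (d1 + d2) / 2.0:
            raise ValueError("overlapping rods in rod20 layout")

    labels2d = np.zeros(shape[:2], dtype=np.int16)
    act2d = np.zeros(shape[:2], dtype=np.float32)
    meta_rods = {}
    for i, (rx, ry, d, white) in enumerate(rods, start=1):
        in_rod = ((X - rx) ** 2 + (Y - ry) ** 2) < (d / 2.0) ** 2
        labels2d[in_rod] = i
        act2d[in_rod] = ROD_ACTIVITY_BQ_PER_ML if white else GRAY_ROD_ACTIVITY_BQ_PER_ML
        meta_rods[i] = {"center_mm": (float(rx), float(ry)),
                        "diameter_mm": d, "white": bool(white)}
    bg_id = len(rods) + 1
    labels2d[in_ell & (labels2d == 0)] = bg_id

    labels = np.repeat(labels2d[:, :, None], shape[2], axis=2)
    activity = np.repeat(act2d[:, :, None], shape[2], axis=2)
    return VoxelPhantom(
        activity=activity, labels=labels, voxel_size_mm=h, family="rod20",
        config_id="rod20",
        meta={"rods": meta_rods, "background_label": bg_id},
    )


# -- brain surrogate ---------------------------------------------------------

_BRAIN_SEMI_AXES = (30.0, 36.0, 27.0)        # x, y, axial half-extents, mm
_CORTEX_INNER_FRAC = 0.78
_GM_WM_RATIO = 4.0                            # Hoffman-style gray:white


def _deformation_field(seed: int, deformation_index: int, q):
    """Smooth displacement field (mm) evaluated at world coords q=(X,Y,Z).

    Index 0 is the identity; indices 1..4 draw low-frequency sinusoidal
    fields from a seeded stream so each index is a distinct, reproducible
    warp of roughly +/- 2 mm.
    """
    if deformation_index == 0:
        return (0.0, 0.0, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(deformation_index)]))
    amps = rng.uniform(0.6, 1.6, size=(3, 3))
    waven = rng.uniform(0.008, 0.02, size=(3, 3, 3))   # cycles per mm
    phases = rng.uniform(0.0, 2 * np.pi, size=(3, 3))
    X, Y, Z = q
    out = []
    for c in range(3):
        u = 0.0
        for hrm in range(3):
            kx, ky, kz = waven[c, hrm]
            u = u + amps[c, hrm] * np.sin(
                2 * np.pi * (kx * X + ky * Y + kz * Z) + phases[c, hrm])
        out.append(u)
    return tuple(out)


def make_brain_phantom(seed: int, translation: Sequence[float] = (0.0, 0.0),
                       rotation: float = 0.0, deformation_index: int = 0,
                       voxel_size_mm: float = DEFAULT_VOXEL_MM,
                       shape: Sequence[int] | None = None,
                       config_id: str | None = None) -> VoxelPhantom:
    """Procedural brain-surrogate phantom, total activity 3.7e6 Bq.

    ``translation`` (mm, in-plane) and ``rotation`` (degrees about the
    axial axis) move the phantom within the field of view;
    ``deformation_index`` (0..4) selects one of five reproducible smooth
    warps of the anatomy.  Raises if the transform pushes activity onto
    the grid boundary.
    """
    if not (0 <= deformation_index <= 4):
        raise ValueError("deformation_index must be in 0..4")
    h = float(voxel_size_mm)
    shape = tuple(shape) if shape is not None else _default_brain_shape(h)
    x, y, z = _axes_mm(shape, h)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    # inverse transform: world -> phantom-local coordinates
    tx, ty = float(translation[0]), float(translation[1])
    Xl = X - tx
    Yl = Y - ty
    if rotation != 0.0:
        th = np.deg2rad(float(rotation))
        Xr = np.cos(th) * Xl + np.sin(th) * Yl
        Yr = -np.sin(th) * Xl + np.cos(th) * Yl
        Xl, Yl = Xr, Yr
    ux, uy, uz = _deformation_field(seed, deformation_index, (Xl, Yl, Z))
    Xl = Xl + ux
    Yl = Yl + uy
    Zl = Z + uz

    ax, ay, az = _BRAIN_SEMI_AXES
    rho = np.sqrt((Xl / ax) ** 2 + (Yl / ay) ** 2 + (Zl / az) ** 2)

    labels = np.zeros(shape, dtype=np.int16)
    activity = np.zeros(shape, dtype=np.float32)
    inside = rho <= 1.0
    cortex = inside & (rho > _CORTEX_INNER_FRAC)
    white = inside & ~cortex
    labels[white] = 2
    activity[white] = 1.0

    def _ellip(center, semi):
        cx, cy, cz = center
        sx, sy, sz = semi
        return (((Xl - cx) / sx) ** 2 + ((Yl - cy) / sy) ** 2
                + ((Zl - cz) / sz) ** 2) < 1.0

    deep_l = white & _ellip((-9.0, -5.0, 2.0), (6.0, 8.0, 7.0))
    deep_r = white & _ellip((9.0, -5.0, 2.0), (6.0, 8.0, 7.0))
    labels[deep_l] = 3
    labels[deep_r] = 4
    activity[deep_l | deep_r] = _GM_WM_RATIO

    vent = white & (_ellip((-4.0, 6.0, 4.0), (3.0, 10.0, 6.0))
                    | _ellip((4.0, 6.0, 4.0), (3.0, 10.0, 6.0)))
    labels[vent] = 5
    activity[vent] = 0.0

    labels[cortex] = 1
    activity[cortex] = _GM_WM_RATIO

    # boundary check: the transform must not clip activity at the FOV edge
    edges = {
        "x-low": activity[0, :, :], "x-high": activity[-1, :, :],
        "y-low": activity[:, 0, :], "y-high": activity[:, -1, :],
        "z-low": activity[:, :, 0], "z-high": activity[:, :, -1],
    }
    for margin, face in edges.items():
        if np.any(face > 0):
            raise ValueError(
                f"brain phantom transform pushes activity outside the grid "
                f"at the {margin} margin")

    total = activity.sum(dtype=np.float64) * (h ** 3 / 1000.0)
    if total <= 0:
        raise ValueError("brain phantom has no activity on this grid")
    activity *= np.float32(BRAIN_TOTAL_ACTIVITY_BQ / total)

    cid = config_id or (
        f"brain_s{seed}_t{tx:g},{ty:g}_r{rotation:g}_d{deformation_index}")
    return VoxelPhantom(
        activity=activity, labels=labels, voxel_size_mm=h, family="brain",
        config_id=cid,
        meta={"seed": int(seed), "translation_mm": (tx, ty),
              "rotation_deg": float(rotation),
              "deformation_index": int(deformation_index)},
    )


# -- configuration plan ------------------------------------------------------

BRAIN_TRANSLATIONS_MM = ((0.0, 0.0), (2.0, 0.0))
BRAIN_ROTATIONS_DEG = (0.0, 6.0)
BRAIN_DEFORMATIONS = (0, 1, 2, 3, 4)
DEFAULT_BRAIN_SEED = 7


@dataclass
class PlanEntry:
    family: str
    config_id: str
    params: dict
    tbr: float | None = None


@dataclass
class ConfigurationPlan:
    """Ordered list of phantom configurations plus the grid they live on."""

    entries: list
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    rod_shape: tuple | None = None
    brain_shape: tuple | None = None

    @property
    def count(self) -> int:
        return len(self.entries)


def default_plan(voxel_size_mm: float = DEFAULT_VOXEL_MM,
                 rod_shape: Sequence[int] | None = None,
                 brain_shape: Sequence[int] | None = None,
                 n_brain: int = 20,
                 brain_seed: int = DEFAULT_BRAIN_SEED,
                 rod5_tbrs: Sequence[float] = TBR_SERIES) -> ConfigurationPlan:
    """The study plan: n_brain brain + len(rod5_tbrs) rod5 + sphere1 + rod20.

    Defaults give the full 30-configuration plan
    (20 brain = 2 translations x 2 rotations x 5 deformations, 8 TBRs).
    """
    brain_combos = [
        (t, r, d)
        for t in BRAIN_TRANSLATIONS_MM
        for r in BRAIN_ROTATIONS_DEG
        for d in BRAIN_DEFORMATIONS
    ]
    if not (1 <= n_brain <= len(brain_combos)):
        raise ValueError("n_brain out of range")
    entries = []
    for i, (t, r, d) in enumerate(brain_combos[:n_brain]):
        entries.append(PlanEntry(
            family="brain", config_id=f"brain{i:02d}",
            params={"seed": brain_seed, "translation": t, "rotation": r,
                    "deformation_index": d}))
    for tbr in rod5_tbrs:
        entries.append(PlanEntry(family="rod5", config_id=f"rod5_tbr{tbr:g}",
                                 params={}, tbr=float(tbr)))
    entries.append(PlanEntry(family="sphere1", config_id="sphere1", params={}))
    entries.append(PlanEntry(family="rod20", config_id="rod20", params={}))
    return ConfigurationPlan(entries=entries, voxel_size_mm=voxel_size_mm,
                             rod_shape=tuple(rod_shape) if rod_shape else None,
                             brain_shape=tuple(brain_shape) if brain_shape else None)


def build_entry(entry: PlanEntry, plan: ConfigurationPlan) -> VoxelPhantom:
    h = plan.voxel_size_mm
    if entry.family == "brain":
        return make_brain_phantom(voxel_size_mm=h, shape=plan.brain_shape,
                                  config_id=entry.config_id, **entry.params)
    if entry.family == "rod5":
        return make_rod5_phantom(entry.tbr, voxel_size_mm=h, shape=plan.rod_shape)
    if entry.family == "sphere1":
        return make_sphere1_phantom(voxel_size_mm=h, shape=plan.rod_shape)
    if entry.family == "rod20":
        return make_rod20_phantom(voxel_size_mm=h, shape=plan.rod_shape)
    raise ValueError(f"unknown family {entry.family!r}")


def enumerate_configurations(plan: ConfigurationPlan | None = None) -> list[VoxelPhantom]:
    """Materialize every phantom in the plan (default: the 30-config plan)."""
    plan = plan or default_plan()
    ids = [e.config_id for e in plan.entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate config_id(s) in plan: {dupes}")
    return [build_entry(e, plan) for e in plan.entries]
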