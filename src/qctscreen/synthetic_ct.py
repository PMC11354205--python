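"""Synthetic CT volumes, calibration phantoms and screening cohorts.

This module provides ground-truthed stand-ins for the three inputs an
opportunistic QCT screening pipeline consumes:

* **Vertebral column volumes** — elliptic-cylinder vertebral bodies stacked
  along the superior-inferior axis, each with a trabecular core of known
  density (mg/cm3), a high-HU cortical shell, an optional basivertebral-vein
  channel entering the posterior-central body, and optional high-HU
  calcification blobs.  Voxel HU follows an affine model
  ``HU = slope * density + intercept`` plus additive Gaussian noise, mirroring
  the linear family the phantom calibration must recover.
* **Spine-phantom volumes** — a soft-tissue-equivalent body with three
  cylindrical inserts of known density (default 50/100/200 mg/cc), the
  standard layout for HU-to-BMD calibration.
* **Cohorts** — participant tables whose sex- and age-specific volumetric BMD
  trends decline with age, with the female decline accelerating after 50, plus
  configurable counts of exclusion-flagged participants (L1 missing from the
  scan; fracture / surgical implant).

Everything is deterministic for a fixed seed: identical seeds give
bit-identical volumes and cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import PhantomScan
from .errors import OverlappingSpecsError
from .volume import (
    CTVolume,
    DEFAULT_ORIENTATION,
    Orientation,
    anterior_axis,
    superior_axis,
    validate_orientation,
)

# voxel class codes: every voxel belongs to exactly one class
BACKGROUND = 0
SOFT_TISSUE = 1
CORTICAL_SHELL = 2
TRABECULAR_CORE = 3
VEIN_CHANNEL = 4
CALCIFICATION = 5

BACKGROUND_HU = -1000.0
SOFT_TISSUE_HU = 40.0
VEIN_HU = 30.0

# fraction of the body's AP diameter the vein channel penetrates; together
# with the 2 mm channel radius this keeps the whole channel inside the
# posterior third of the body for body radii >= 12 mm.  The channel starts at
# the inner boundary of the cortical shell (the shell ring itself stays
# intact), running anteriorly into the trabecular core.
_VEIN_DEPTH_FRACTION = 0.22

# in-plane aspect ratio of the vertebral body ellipse (AP semi-axis / RL semi-axis)
_BODY_ASPECT = 0.85


@dataclass
class VertebraSpec:
    """Geometry and ground-truth density of one synthetic vertebral body."""

    level: str = "L1"
    trabecular_density: float = 100.0  # mg/cm3
    body_radius_mm: float = 17.0  # lateral (RL) semi-axis; AP semi-axis is 0.85x
    body_height_mm: float = 25.0
    cortical_thickness_mm: float = 2.0
    cortical_hu: float = 500.0
    vein_channel: bool = True
    vein_radius_mm: float = 2.0
    n_calcifications: int = 0
    calcification_hu: float = 800.0
    calcification_radius_mm: float = 1.5
    center_z_mm: float | None = None  # superior-axis position; None = auto-stack

    def __post_init__(self) -> None:
        if self.trabecular_density < 0:
            raise ValueError("trabecular_density must be >= 0")
        if self.body_radius_mm <= 0 or self.body_height_mm <= 0:
            raise ValueError("radii and heights must be positive")
        if self.cortical_thickness_mm < 0:
            raise ValueError("cortical_thickness_mm must be >= 0")


@dataclass
class GroundTruth:
    """Masks and the HU model used to paint a synthetic spine volume."""

    lumbar_mask: np.ndarray  # bool: union of all vertebra voxels
    instance_mask: np.ndarray  # int: 1..k, superior -> inferior
    density_by_instance: dict[int, float]
    hu_model: tuple[float, float, float]  # (slope, intercept, noise_sigma)
    class_map: np.ndarray  # per-voxel class code

    def instance(self, label: int) -> np.ndarray:
        return self.instance_mask == label

    def core_mask(self, label: int | None = None) -> np.ndarray:
        return self._class_mask(TRABECULAR_CORE, label)

    def shell_mask(self, label: int | None = None) -> np.ndarray:
        return self._class_mask(CORTICAL_SHELL, label)

    def vein_mask(self, label: int | None = None) -> np.ndarray:
        return self._class_mask(VEIN_CHANNEL, label)

    def calcification_mask(self, label: int | None = None) -> np.ndarray:
        return self._class_mask(CALCIFICATION, label)

    def _class_mask(self, code: int, label: int | None) -> np.ndarray:
        m = self.class_map == code
        if label is not None:
            m &= self.instance_mask == label
        return m


def _stack_extents(
    specs: list[VertebraSpec], disc_gap_mm: float, margin_mm: float
) -> list[tuple[float, float]]:
    """Superior-axis (z) extent of each body in mm; spec[0] is most superior.

    Returns extents measured from z = 0 at the volume top margin downward, then
    re-expressed as positions from the bottom so index 0 ends up most superior.
    Explicit ``center_z_mm`` values override stacking and are collision-checked.
    """
    auto = [s.center_z_mm is None for s in specs]
    extents: list[tuple[float, float]] = []
    total = sum(s.body_height_mm for s in specs) + disc_gap_mm * (len(specs) - 1)
    top = margin_mm + total  # z of the top of the first (most superior) body
    cursor = top
    for s in specs:
        if s.center_z_mm is None:
            hi = cursor
            lo = hi - s.body_height_mm
            cursor = lo - disc_gap_mm
        else:
            lo = s.center_z_mm - s.body_height_mm / 2
            hi = s.center_z_mm + s.body_height_mm / 2
        extents.append((lo, hi))
    for i in range(len(extents)):
        for j in range(i + 1, len(extents)):
            a, b = extents[i], extents[j]
            if a[0] < b[1] and b[0] < a[1]:
                raise OverlappingSpecsError(
                    f"vertebra specs {i} ({specs[i].level}) and {j} ({specs[j].level}) "
                    f"overlap axially: {a} vs {b}"
                )
    if not all(auto):
        # keep superior->inferior instance ordering meaningful
        order = np.argsort([-(lo + hi) / 2 for lo, hi in extents])
        if not np.array_equal(order, np.arange(len(specs))):
            raise OverlappingSpecsError(
                "explicit center_z_mm positions must be ordered superior -> inferior"
            )
    return extents


def generate_vertebra_volume(
    specs: list[VertebraSpec],
    hu_slope: float = 1.0,
    hu_intercept: float = 0.0,
    noise_sigma: float = 0.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    in_plane_shape: tuple[int, int] = (128, 128),
    disc_gap_mm: float = 4.0,
    margin_mm: float = 8.0,
    protocol: str = "default",
) -> tuple[CTVolume, GroundTruth]:
    """Paint a stacked-vertebrae CT volume and its ground truth.

    Axes are fixed to ``("R", "A", "S")``: axis 0 right, axis 1 anterior,
    axis 2 superior; ``specs[0]`` becomes the most superior body (instance 1).
    Trabecular-core voxels have mean HU ``hu_slope * density + hu_intercept``;
    additive Gaussian noise of ``noise_sigma`` HU is applied to the whole
    volume when positive.
    """
    if not specs:
        raise ValueError("at least one VertebraSpec is required")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    orientation: Orientation = DEFAULT_ORIENTATION
    sx, sy, sz = spacing
    extents = _stack_extents(list(specs), disc_gap_mm, margin_mm)
    z_top_mm = max(hi for _, hi in extents) + margin_mm
    nz = int(np.ceil(z_top_mm / sz))
    nx, ny = in_plane_shape
    shape = (nx, ny, nz)

    rng = np.random.default_rng(seed)
    class_map = np.zeros(shape, dtype=np.uint8)
    hu = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    instance_mask = np.zeros(shape, dtype=np.int16)

    # voxel-center coordinates in mm
    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    zs = (np.arange(nz) + 0.5) * sz
    cx, cy = nx * sx / 2, ny * sy / 2
    X = xs[:, None]
    Y = ys[None, :]

    # soft-tissue column surrounding the spine
    st_a = min(cx - 2 * sx, 55.0)
    st_b = min(cy - 2 * sy, 45.0)
    soft2d = ((X - cx) / st_a) ** 2 + ((Y - cy) / st_b) ** 2 <= 1.0
    class_map[soft2d] = SOFT_TISSUE
    hu[soft2d] = SOFT_TISSUE_HU

    density_by_instance: dict[int, float] = {}
    for idx, (spec, (z_lo, z_hi)) in enumerate(zip(specs, extents)):
        label = idx + 1
        density_by_instance[label] = float(spec.trabecular_density)
        a = spec.body_radius_mm
        b = _BODY_ASPECT * spec.body_radius_mm
        t = spec.cortical_thickness_mm
        body2d = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
        core2d = body2d
        if t > 0:
            core2d = ((X - cx) / max(a - t, 1e-6)) ** 2 + (
                (Y - cy) / max(b - t, 1e-6)
            ) ** 2 <= 1.0
        zsel = (zs > z_lo) & (zs < z_hi)
        core_zsel = (zs > z_lo + t) & (zs < z_hi - t)
        body3d = body2d[:, :, None] & zsel[None, None, :]
        core3d = core2d[:, :, None] & core_zsel[None, None, :]
        shell3d = body3d & ~core3d

        core_hu = hu_slope * spec.trabecular_density + hu_intercept
        class_map[shell3d] = CORTICAL_SHELL
        hu[shell3d] = spec.cortical_hu
        class_map[core3d] = TRABECULAR_CORE
        hu[core3d] = core_hu
        instance_mask[body3d] = label

        if spec.vein_channel:
            # horizontal channel along AP at mid-height, from the inner shell
            # boundary into the posterior-central core; voxel centers strictly
            # inside the open cylinder
            z_mid = (z_lo + z_hi) / 2
            y_post = cy - b  # posterior boundary of the body (anterior = +y)
            y_lo = y_post + t
            y_hi = y_post + _VEIN_DEPTH_FRACTION * 2 * b
            r = spec.vein_radius_mm
            rad2 = (X[:, :, None] - cx) ** 2 + (zs[None, None, :] - z_mid) ** 2
            ysel = (Y[:, :, None] >= y_lo) & (Y[:, :, None] <= y_hi)
            vein3d = (rad2 < r**2) & ysel
            vein3d &= class_map != BACKGROUND  # channel lives in tissue
            class_map[vein3d] = VEIN_CHANNEL
            hu[vein3d] = VEIN_HU
            instance_mask[vein3d & body3d] = label

        for _ in range(spec.n_calcifications):
            # rejection-sample a sphere center comfortably inside the core
            for _attempt in range(200):
                px = rng.uniform(cx - a + t + 2, cx + a - t - 2)
                py = rng.uniform(cy - b + t + 2, cy + b - t - 2)
                pz = rng.uniform(z_lo + t + 2, z_hi - t - 2)
                inside = ((px - cx) / max(a - t - 2, 1e-6)) ** 2 + (
                    (py - cy) / max(b - t - 2, 1e-6)
                ) ** 2 <= 1.0
                if inside:
                    break
            rr = spec.calcification_radius_mm
            blob = (
                (X[:, :, None] - px) ** 2
                + (Y[:, :, None] - py) ** 2
                + (zs[None, None, :] - pz) ** 2
            ) <= rr**2
            blob &= core3d
            class_map[blob] = CALCIFICATION
            hu[blob] = spec.calcification_hu

    if noise_sigma > 0:
        hu = hu + rng.normal(0.0, noise_sigma, size=shape)

    lumbar_mask = instance_mask > 0
    ct = CTVolume(
        voxels=hu.astype(np.float32),
        spacing=spacing,
        orientation=orientation,
        protocol=protocol,
    )
    gt = GroundTruth(
        lumbar_mask=lumbar_mask,
        instance_mask=instance_mask,
        density_by_instance=density_by_instance,
        hu_model=(float(hu_slope), float(hu_intercept), float(noise_sigma)),
        class_map=class_map,
    )
    return ct, gt


def generate_esp_volume(
    insert_densities: tuple[float, float, float] = (50.0, 100.0, 200.0),
    hu_slope: float = 1.0,
    hu_intercept: float = 0.0,
    noise_sigma: float = 0.0,
    n_slices: int = 20,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    insert_radius_mm: float = 9.0,
    protocol: str = "default",
) -> PhantomScan:
    """Simulate a spine-phantom scan with three bone-equivalent inserts.

    The phantom is a soft-tissue-equivalent elliptic cylinder containing three
    disjoint cylindrical inserts (left/middle/right) whose mean HU follows
    ``hu_slope * density + hu_intercept``.
    """
    densities = tuple(float(d) for d in insert_densities)
    if len(densities) != 3 or any(d < 0 for d in densities):
        raise ValueError("insert_densities must be three non-negative values")
    if len(set(densities)) != 3:
        raise ValueError("insert densities must be distinct (regression would be degenerate)")
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    sx, sy, sz = spacing
    nx, ny, nz = int(round(120 / sx)), int(round(80 / sy)), int(n_slices)
    rng = np.random.default_rng(seed)
    hu = np.full((nx, ny, nz), BACKGROUND_HU, dtype=np.float64)
    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    cx, cy = nx * sx / 2, ny * sy / 2
    X, Y = xs[:, None], ys[None, :]

    body2d = ((X - cx) / (cx - 2 * sx)) ** 2 + ((Y - cy) / (cy - 2 * sy)) ** 2 <= 1.0
    hu[body2d] = 35.0  # soft-tissue equivalent

    offsets = (-30.0, 0.0, 30.0)
    insert_masks: list[np.ndarray] = []
    for d, off in zip(densities, offsets):
        in2d = (X - (cx + off)) ** 2 + (Y - cy) ** 2 <= insert_radius_mm**2
        m = np.repeat(in2d[:, :, None], nz, axis=2)
        hu[m] = hu_slope * d + hu_intercept
        insert_masks.append(m)

    if noise_sigma > 0:
        hu = hu + rng.normal(0.0, noise_sigma, size=hu.shape)

    vol = CTVolume(
        voxels=hu.astype(np.float32),
        spacing=spacing,
        orientation=DEFAULT_ORIENTATION,
        protocol=protocol,
    )
    return PhantomScan(
        volume=vol,
        insert_masks=insert_masks,
        insert_densities=densities,
        protocol=protocol,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# Default sex-specific median vBMD anchors (age, mg/cm3) at 5-year-bin
# midpoints.  Both curves decline with age; the female curve holds a higher
# plateau through the forties then drops steeply after 50 (menopausal bone
# loss), crossing below the male curve — the canonical screening-cohort
# pattern.  A running minimum is applied after age 50 so the median curve is
# monotone non-increasing there.
_FEMALE_ANCHORS = [
    (22, 165.0), (27, 157.0), (32, 156.0), (37, 154.0), (42, 155.0), (47, 150.0),
    (52, 120.0), (57, 107.0), (62, 92.0), (67, 82.0), (72, 71.0), (77, 65.0),
    (82, 68.0), (87, 60.0),
]
_MALE_ANCHORS = [
    (22, 151.0), (27, 150.0), (32, 147.0), (37, 145.0), (42, 146.0), (47, 133.0),
    (52, 128.0), (57, 122.0), (62, 105.0), (67, 102.0), (72, 95.0), (77, 84.0),
    (82, 73.0), (87, 86.0),
]


def _monotone_after_50(anchors: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([a for a, _ in anchors], dtype=float)
    vals = np.array([v for _, v in anchors], dtype=float)
    post = ages >= 50
    vals[post] = np.minimum.accumulate(vals[post])
    return ages, vals


@dataclass
class BmdCurveParams:
    """Sex-specific median vBMD-vs-age curves plus Gaussian between-subject spread."""

    female_anchors: list[tuple[float, float]] = field(default_factory=lambda: list(_FEMALE_ANCHORS))
    male_anchors: list[tuple[float, float]] = field(default_factory=lambda: list(_MALE_ANCHORS))
    spread_sigma: float = 20.0  # mg/cm3

    def median(self, sex: str, age) -> np.ndarray:
        anchors = self.female_anchors if sex == "female" else self.male_anchors
        ages, vals = _monotone_after_50(anchors)
        return np.interp(np.asarray(age, dtype=float), ages, vals)


@dataclass
class CohortSpec:
    """A generated participant table plus the seed that produced it."""

    participants: pd.DataFrame  # id, age, sex, true_vbmd, flag_missing_L1, flag_fracture_implant
    seed: int

    def to_csv(self, path) -> None:
        self.participants.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, seed: int = -1) -> "CohortSpec":
        df = pd.read_csv(path)
        for col in ("flag_missing_L1", "flag_fracture_implant"):
            df[col] = df[col].astype(bool)
        return CohortSpec(participants=df, seed=seed)


def sample_cohort(
    n: int,
    age_range: tuple[int, int] = (20, 90),
    bmd_curve_params: BmdCurveParams | None = None,
    exclusion_counts: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> CohortSpec:
    """Draw a synthetic screening cohort.

    Ages are drawn uniformly over 5-year bins spanning ``age_range``; sex is
    balanced Bernoulli(0.5); true vBMD is the sex-specific median curve at the
    participant's age plus Gaussian spread.  Exactly ``exclusion_counts[0]``
    participants carry the missing-L1 flag and ``exclusion_counts[1]`` distinct
    participants the fracture/implant flag.
    """
    params = bmd_curve_params or BmdCurveParams()
    n_missing, n_fracture = exclusion_counts
    if n_missing < 0 or n_fracture < 0 or n_missing + n_fracture >= n:
        raise ValueError(
            f"exclusion_counts {exclusion_counts} must be non-negative and sum below n={n}"
        )
    lo, hi = age_range
    if lo < 20:
        raise ValueError("ages must be >= 20")
    rng = np.random.default_rng(seed)
    bin_edges = np.arange(lo, hi + 5, 5)
    n_bins = len(bin_edges) - 1
    bins = rng.integers(0, n_bins, size=n)
    ages = bin_edges[bins] + rng.integers(0, 5, size=n)
    ages = np.minimum(ages, hi)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    medians = np.where(
        sexes == "female",
        params.median("female", ages),
        params.median("male", ages),
    )
    vbmd = medians + rng.normal(0.0, params.spread_sigma, size=n)
    vbmd = np.clip(vbmd, 5.0, None)

    flagged = rng.choice(n, size=n_missing + n_fracture, replace=False)
    flag_missing = np.zeros(n, dtype=bool)
    flag_fracture = np.zeros(n, dtype=bool)
    flag_missing[flagged[:n_missing]] = True
    flag_fracture[flagged[n_missing:]] = True

    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": ages.astype(int),
            "sex": sexes,
            "true_vbmd": np.round(vbmd, 4),
            "flag_missing_L1": flag_missing,
            "flag_fracture_implant": flag_fracture,
        }
    )
    return CohortSpec(participants=df, seed=seed)
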