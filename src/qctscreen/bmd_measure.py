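"""Trabecular ROI placement and volumetric BMD measurement for L1/L2.

The representative HU of a vertebra is measured in an elliptic-cylinder ROI
confined to the inner trabecular bone: the body cross-section is eroded (so
the ROI can never touch the cortical shell), the posterior third is excluded
(avoiding the basivertebral vein channel), the second-moment ellipse of the
remaining region is shrunk until fully contained, and the ellipse is extruded
over the central slab of the body.  Within the ROI the HU distribution is
trimmed of its extreme 1% (guarding against calcification outliers) and the
median of the remainder is the representative HU, which a protocol-matched
conversion model maps to vBMD in mg/cm3.  The L1-2 value is the unweighted
mean of the per-vertebra values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import ConversionModel, convert_hu_to_bmd
from .errors import (
    MeasurementFailureError,
    ProtocolMismatchError,
    ROIInfeasibleError,
    ROITooSmallError,
)
from .spine_mask import VertebraInstance
from .volume import CTVolume, Orientation, anterior_axis, superior_axis


@dataclass
class RoiConfig:
    erosion_mm: float = 3.0  # must exceed the cortical thickness
    shrink: float = 0.8  # initial scale on the second-moment ellipse
    anterior_fraction: float = 2.0 / 3.0  # keep this much of the eroded AP extent
    min_roi_voxels: int = 50
    containment_step: float = 0.95  # shrink factor while any voxel escapes
    max_containment_iters: int = 200


@dataclass
class EllipticalROI:
    """An elliptic-cylinder trabecular ROI."""

    center_mm: np.ndarray
    semi_axes_mm: tuple[float, float]
    slab: tuple[int, int]  # half-open slice range along the superior axis
    indices: np.ndarray  # (n, 3) voxel indices
    n_voxels: int

    def as_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m


@dataclass
class RepresentativeHU:
    value: float
    n_raw: int
    n_used: int
    trim_fraction: float


@dataclass
class VbmdResult:
    """Per-vertebra and combined L1-2 volumetric BMD."""

    per_vertebra: dict[str, float]  # level -> mg/cm3
    combined_l1_2: float
    representative_hu: dict[str, RepresentativeHU]
    rois: dict[str, EllipticalROI]
    model_method: str
    single_vertebra: bool
    failures: dict[str, str] = field(default_factory=dict)


def window_normalize(volume, level: float = 300.0, width: float = 850.0) -> np.ndarray:
    """Window-level/width normalization to [0, 1].

    Values are clipped to ``[level - width/2, level + width/2]`` and mapped
    affinely to the unit interval — the preprocessing applied before
    segmentation-model inference.  Accepts a :class:`CTVolume` or an array.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    arr = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume, dtype=float)
    lo = level - width / 2.0
    return (np.clip(arr, lo, lo + width) - lo) / width


def trimmed_median(
    values, trim_fraction: float = 0.01, tail: str = "symmetric"
) -> RepresentativeHU:
    """Median after removing the extreme ``trim_fraction`` of values.

    ``tail="symmetric"`` removes ``floor(trim_fraction/2 * n)`` from each end
    of the sorted sample (guarding against both calcification spikes and
    low-HU vein / partial-volume voxels); ``tail="upper"`` removes
    ``floor(trim_fraction * n)`` from the top only.
    """
    arr = np.sort(np.asarray(values, dtype=float).ravel())
    n = arr.size
    if n == 0:
        raise ValueError("cannot take the representative HU of an empty sample")
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if tail == "symmetric":
        k = int(math.floor(trim_fraction / 2.0 * n))
        kept = arr[k : n - k] if k > 0 else arr
    elif tail == "upper":
        k = int(math.floor(trim_fraction * n))
        kept = arr[: n - k] if k > 0 else arr
    else:
        raise ValueError(f"unknown tail mode {tail!r}")
    return RepresentativeHU(
        value=float(np.median(kept)),
        n_raw=int(n),
        n_used=int(kept.size),
        trim_fraction=float(trim_fraction),
    )


def representative_hu(
    ct: CTVolume,
    roi: EllipticalROI,
    trim_fraction: float = 0.01,
    tail: str = "symmetric",
) -> RepresentativeHU:
    """Trimmed-median representative HU of a placed ROI."""
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    values = ct.voxels[tuple(roi.indices.T)]
    return trimmed_median(values, trim_fraction=trim_fraction, tail=tail)


def _elliptical_footprint(r0: int, r1: int) -> np.ndarray:
    ii = np.arange(-r0, r0 + 1)[:, None]
    jj = np.arange(-r1, r1 + 1)[None, :]
    return (ii / max(r0, 1e-9)) ** 2 + (jj / max(r1, 1e-9)) ** 2 <= 1.0


def place_roi(
    instance: VertebraInstance,
    spacing: tuple[float, float, float],
    orientation: Orientation,
    config: RoiConfig | None = None,
) -> EllipticalROI:
    """Place the trabecular elliptic-cylinder ROI inside one vertebral body.

    On the mid-slab cross-section: erode the body mask by ``erosion_mm``
    (converted to per-axis voxel radii, rounded half-up), drop the posterior
    third of the eroded region (basivertebral-vein avoidance), fit the
    second-moment ellipse of the remainder, scale its semi-axes by ``shrink``,
    shrink further until every ellipse voxel lies inside the eroded anterior
    region, and extrude over ``instance.body_slices``.

    Raises :class:`ROIInfeasibleError` when erosion annihilates the
    cross-section (vertebra too small for the erosion radius) and
    :class:`ROITooSmallError` when the final ROI has fewer than
    ``min_roi_voxels`` members.
    """
    config = config or RoiConfig()
    spacing = tuple(float(s) for s in spacing)
    s_ax, _ = superior_axis(orientation)
    a_ax, a_sign = anterior_axis(orientation)
    inplane_axes = [ax for ax in range(3) if ax != s_ax]
    ap_inplane = inplane_axes.index(a_ax)

    lo_slab, hi_slab = instance.body_slices
    if hi_slab <= lo_slab:
        raise ROIInfeasibleError("instance has an empty body slab")
    mid = (lo_slab + hi_slab) // 2
    sl: list = [slice(None)] * 3
    sl[s_ax] = mid
    cross = instance.mask[tuple(sl)]
    if not cross.any():
        raise ROIInfeasibleError("empty cross-section at the mid-slab slice")

    # erosion radius in mm, converted per-axis and rounded half-up
    radii = [int(math.floor(config.erosion_mm / spacing[ax] + 0.5)) for ax in inplane_axes]
    eroded = ndimage.binary_erosion(cross, structure=_elliptical_footprint(*radii))
    if not eroded.any():
        raise ROIInfeasibleError(
            f"erosion by {config.erosion_mm} mm annihilated the vertebral cross-section"
        )

    # exclude the posterior third of the eroded region
    coords = np.argwhere(eroded)
    ap = coords[:, ap_inplane]
    lo_ap, hi_ap = ap.min(), ap.max()
    span = hi_ap - lo_ap + 1
    if a_sign > 0:  # increasing index = anterior; posterior third = low indices
        cut = lo_ap + span * (1.0 - config.anterior_fraction)
        keep = ap >= cut
    else:
        cut = hi_ap - span * (1.0 - config.anterior_fraction)
        keep = ap <= cut
    region = coords[keep]
    if len(region) == 0:
        raise ROIInfeasibleError("anterior restriction removed the whole eroded region")
    allowed = np.zeros_like(eroded)
    allowed[tuple(region.T)] = True

    # second-moment (equivalent) ellipse of the allowed region, in mm
    sp2 = np.array([spacing[ax] for ax in inplane_axes])
    pts = (region + 0.5) * sp2
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T, bias=True)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    semi = 2.0 * np.sqrt(evals) * config.shrink  # uniform-ellipse equivalence

    # candidate voxels within the cross-section bounding box
    bb_lo = region.min(axis=0)
    bb_hi = region.max(axis=0)
    gi = np.arange(bb_lo[0], bb_hi[0] + 1)
    gj = np.arange(bb_lo[1], bb_hi[1] + 1)
    GI, GJ = np.meshgrid(gi, gj, indexing="ij")
    grid = np.stack([GI.ravel(), GJ.ravel()], axis=1)
    grid_mm = (grid + 0.5) * sp2
    local = (grid_mm - center) @ evecs  # principal-axis frame

    ellipse_idx = None
    for _ in range(config.max_containment_iters):
        if min(semi) < min(sp2) / 2:
            raise ROIInfeasibleError("containment shrink collapsed the ROI ellipse")
        inside = (local[:, 0] / semi[0]) ** 2 + (local[:, 1] / semi[1]) ** 2 <= 1.0
        members = grid[inside]
        if len(members) > 0 and allowed[tuple(members.T)].all():
            ellipse_idx = members
            break
        semi = semi * config.containment_step
    if ellipse_idx is None or len(ellipse_idx) == 0:
        raise ROIInfeasibleError("could not contain the ROI ellipse in the eroded region")

    # extrude the in-plane ellipse over the body slab
    n_inplane = len(ellipse_idx)
    slab_slices = np.arange(lo_slab, hi_slab)
    indices = np.empty((n_inplane * len(slab_slices), 3), dtype=np.intp)
    for k, z in enumerate(slab_slices):
        block = indices[k * n_inplane : (k + 1) * n_inplane]
        block[:, inplane_axes[0]] = ellipse_idx[:, 0]
        block[:, inplane_axes[1]] = ellipse_idx[:, 1]
        block[:, s_ax] = z
    n_vox = len(indices)
    if n_vox < config.min_roi_voxels:
        raise ROITooSmallError(f"ROI has {n_vox} voxels (< {config.min_roi_voxels})")

    center_mm = np.empty(3)
    center_mm[inplane_axes[0]] = center[0]
    center_mm[inplane_axes[1]] = center[1]
    center_mm[s_ax] = (lo_slab + hi_slab) / 2.0 * spacing[s_ax]
    return EllipticalROI(
        center_mm=center_mm,
        semi_axes_mm=(float(semi[0]), float(semi[1])),
        slab=(lo_slab, hi_slab),
        indices=indices,
        n_voxels=n_vox,
    )


def measure_vbmd(
    ct: CTVolume,
    instances: list[VertebraInstance],
    model: ConversionModel,
    config: RoiConfig | None = None,
    trim_fraction: float = 0.01,
    levels: tuple[str, ...] = ("L1", "L2"),
) -> VbmdResult:
    """Measure per-vertebra vBMD for L1/L2 and combine.

    For each requested level present among the instances: place the ROI, take
    the trimmed-median representative HU, convert via the protocol-matched
    model.  The combined L1-2 value is the unweighted mean of the available
    per-vertebra values; a flag records when only one vertebra contributed.
    Raises :class:`MeasurementFailureError` when no requested vertebra is
    measurable (the cohort's measurement-not-feasible exclusion category).
    """
    if model.protocol != ct.protocol:
        raise ProtocolMismatchError(
            f"model protocol {model.protocol!r} does not match volume protocol {ct.protocol!r}"
        )
    config = config or RoiConfig()
    by_level = {v.level_name: v for v in instances}
    per_vertebra: dict[str, float] = {}
    rep: dict[str, RepresentativeHU] = {}
    rois: dict[str, EllipticalROI] = {}
    failures: dict[str, str] = {}
    for level in levels:
        inst = by_level.get(level)
        if inst is None:
            failures[level] = "not present in scan"
            continue
        try:
            roi = place_roi(inst, ct.spacing, ct.orientation, config)
            r = representative_hu(ct, roi, trim_fraction=trim_fraction)
        except (ROIInfeasibleError, ROITooSmallError) as exc:
            failures[level] = str(exc)
            continue
        per_vertebra[level] = float(convert_hu_to_bmd(model, r.value))
        rep[level] = r
        rois[level] = roi
    if not per_vertebra:
        raise MeasurementFailureError(
            "neither vertebra measurable: " + "; ".join(f"{k}: {v}" for k, v in failures.items())
        )
    combined = float(np.mean(list(per_vertebra.values())))
    return VbmdResult(
        per_vertebra=per_vertebra,
        combined_l1_2=combined,
        representative_hu=rep,
        rois=rois,
        model_method=model.method,
        single_vertebra=(len(per_vertebra) == 1),
        failures=failures,
    )
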