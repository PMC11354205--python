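"""Lumbar segmentation contract and vertebra instance labeling.

The measurement pipeline only needs a binary lumbar mask and an ordered list
of vertebra instances (the most superior object is L1, the next L2, ...).
Production deployments obtain the mask from a trained segmentation network;
that network is deliberately isolated behind this contract so it can be
dropped in later.  Two reference paths are provided:

* ``oracle`` — pass through a generator ground-truth mask (exact);
* ``rule_based`` — threshold at bone-range HU to pick up the cortical shell,
  seal it with an in-plane morphological closing, fill the trabecular
  interior per axial slice, and keep sufficiently large 3-D components.

Closing and hole-filling are performed per axial slice (an in-plane disk
footprint) rather than with a 3-D ball: an in-plane closing seals the
basivertebral channel where it pierces the shell but cannot bridge adjacent
vertebrae across the disc space along the superior-inferior axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import AmbiguousOrderingError, EmptyMaskError
from .synthetic_ct import GroundTruth
from .volume import CTVolume, Orientation, superior_axis


@dataclass
class SegmentationConfig:
    bone_hu: float = 250.0  # cortical shell threshold
    closing_radius_voxels: int = 2  # in-plane disk radius
    min_component_voxels: int = 200  # drops stray noise/calcification blobs
    lumbar_slice_range: tuple[int, int] | None = None  # half-open, along superior axis


@dataclass
class LumbarMask:
    """Binary lumbar mask congruent with its source volume."""

    mask: np.ndarray
    source: str  # "oracle" | "rule_based"
    orientation: Orientation
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")


@dataclass
class VertebraInstance:
    """One labeled vertebral body, ordered superior -> inferior."""

    level_name: str  # "L1", "L2", ...
    mask: np.ndarray  # bool, full-grid
    centroid_mm: np.ndarray
    axial_extent: tuple[int, int]  # half-open slice range along the superior axis
    body_slices: tuple[int, int]  # central-third slab used for the ROI
    n_voxels: int

    @property
    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.mask)


def _inplane_footprint(radius: int, sup_ax: int) -> np.ndarray:
    d = disk(radius).astype(bool)
    return np.expand_dims(d, axis=sup_ax)


def _inplane_structure(sup_ax: int) -> np.ndarray:
    s = ndimage.generate_binary_structure(2, 1)
    return np.expand_dims(s, axis=sup_ax)


def segment_lumbar(
    ct: CTVolume,
    config: SegmentationConfig | None = None,
    ground_truth: GroundTruth | None = None,
    method: str = "rule_based",
) -> LumbarMask:
    """Produce a binary lumbar mask from a CT volume.

    ``method="oracle"`` passes through ``ground_truth.lumbar_mask`` (for
    synthetic volumes); ``method="rule_based"`` runs the reference
    threshold/close/fill pipeline.  Raises :class:`EmptyMaskError` when no
    voxel reaches the bone threshold — a failure distinct from succeeding with
    an empty region of interest.
    """
    config = config or SegmentationConfig()
    if method == "oracle":
        if ground_truth is None:
            raise ValueError("oracle segmentation requires a GroundTruth")
        if ground_truth.lumbar_mask.shape != ct.shape:
            raise ValueError("ground-truth mask not congruent with volume")
        return LumbarMask(
            mask=ground_truth.lumbar_mask.copy(),
            source="oracle",
            orientation=ct.orientation,
            spacing=ct.spacing,
        )
    if method != "rule_based":
        raise ValueError(f"unknown segmentation method {method!r}")

    bone = ct.voxels >= config.bone_hu
    if not bone.any():
        raise EmptyMaskError(f"no voxel reaches the bone threshold {config.bone_hu} HU")

    s_ax, _ = superior_axis(ct.orientation)
    footprint = _inplane_footprint(config.closing_radius_voxels, s_ax)
    closed = ndimage.binary_closing(bone, structure=footprint)
    filled = ndimage.binary_fill_holes(closed, structure=_inplane_structure(s_ax))

    labels, n = ndimage.label(filled, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise EmptyMaskError("closing/filling removed every bone voxel")
    keep = np.zeros(n + 1, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    for i, size in enumerate(sizes, start=1):
        if size < config.min_component_voxels:
            continue
        if config.lumbar_slice_range is not None:
            lo, hi = config.lumbar_slice_range
            comp_slices = np.unique(np.nonzero(labels == i)[s_ax])
            if not np.any((comp_slices >= lo) & (comp_slices < hi)):
                continue
        keep[i] = True
    mask = keep[labels]
    if not mask.any():
        raise EmptyMaskError("no component survived size/region filtering")
    return LumbarMask(mask=mask, source="rule_based", orientation=ct.orientation, spacing=ct.spacing)


def instance_label(
    mask: LumbarMask,
    orientation: Orientation | None = None,
    max_overlap_fraction: float = 0.5,
) -> list[VertebraInstance]:
    """Split a lumbar mask into vertebra instances ordered superior -> inferior.

    Connected components under 26-connectivity are sorted by centroid position
    along the superior axis, most superior first; the first is named L1, the
    second L2, and so on.  ``body_slices`` is the central third of each
    instance's axial extent.  Components whose axial extents overlap by more
    than half (of the shorter extent) cannot be ordered and raise
    :class:`AmbiguousOrderingError`.  Ties on centroid height break toward
    the larger component, then lexicographic centroid, so labeling is
    independent of component discovery order.
    """
    orientation = orientation or mask.orientation
    arr = mask.mask
    if not arr.any():
        raise EmptyMaskError("cannot label an empty mask")
    s_ax, s_sign = superior_axis(orientation)
    labels, n = ndimage.label(arr, structure=np.ones((3, 3, 3), dtype=bool))

    comps = []
    for i in range(1, n + 1):
        comp = labels == i
        idx = np.nonzero(comp)
        centroid = np.array([c.mean() for c in idx])
        size = len(idx[0])
        lo, hi = int(idx[s_ax].min()), int(idx[s_ax].max()) + 1
        superior_pos = s_sign * centroid[s_ax]
        comps.append(
            {
                "mask": comp,
                "centroid": centroid,
                "size": size,
                "extent": (lo, hi),
                "superior_pos": superior_pos,
            }
        )

    comps.sort(key=lambda c: (-c["superior_pos"], -c["size"], tuple(c["centroid"])))

    for a, b in zip(comps, comps[1:]):
        lo = max(a["extent"][0], b["extent"][0])
        hi = min(a["extent"][1], b["extent"][1])
        overlap = max(0, hi - lo)
        shorter = min(a["extent"][1] - a["extent"][0], b["extent"][1] - b["extent"][0])
        if shorter > 0 and overlap / shorter > max_overlap_fraction:
            raise AmbiguousOrderingError(
                f"components overlap axially by {overlap} slices "
                f"(> {max_overlap_fraction:.0%} of the shorter extent)"
            )

    spacing = np.asarray(mask.spacing)
    instances = []
    for rank, c in enumerate(comps, start=1):
        lo, hi = c["extent"]
        height = hi - lo
        third = height / 3.0
        b_lo = lo + int(np.floor(third))
        b_hi = hi - int(np.floor(third))
        if b_hi <= b_lo:
            b_lo, b_hi = lo, hi
        instances.append(
            VertebraInstance(
                level_name=f"L{rank}",
                mask=c["mask"],
                centroid_mm=(c["centroid"] + 0.5) * spacing,
                axial_extent=(lo, hi),
                body_slices=(b_lo, b_hi),
                n_voxels=int(c["size"]),
            )
        )
    return instances


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def instances_to_table(instances: list[VertebraInstance]):
    """Export instance metadata (level, centroid, extent) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "level": v.level_name,
                "centroid_x_mm": v.centroid_mm[0],
                "centroid_y_mm": v.centroid_mm[1],
                "centroid_z_mm": v.centroid_mm[2],
                "extent_lo": v.axial_extent[0],
                "extent_hi": v.axial_extent[1],
                "body_lo": v.body_slices[0],
                "body_hi": v.body_slices[1],
                "n_voxels": v.n_voxels,
            }
            for v in instances
        ]
    )
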