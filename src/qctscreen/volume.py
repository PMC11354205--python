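"""CT volume container with explicit anatomical orientation, plus NIfTI I/O.

A :class:`CTVolume` is a 3-D grid of Hounsfield units together with the voxel
spacing (mm), an orientation that names the anatomical direction of each array
axis, and an acquisition-protocol key (vendor / kVp / kernel class) used to
match volumes to calibration models.

Orientation is a 3-tuple of single-letter codes, one per array axis, giving
the anatomical direction of *increasing* index along that axis:

    R/L  = right / left
    A/P  = anterior / posterior
    S/I  = superior / inferior

e.g. ``("R", "A", "S")`` means axis 0 runs to the patient's right, axis 1 to
anterior, axis 2 to superior.  Exactly one axis must name each anatomical
dimension.  Orientation is carried through NIfTI headers via the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

_CODE_TO_RAS = {
    "R": np.array([1.0, 0.0, 0.0]),
    "L": np.array([-1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}
_AXIS_GROUP = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}

Orientation = tuple[str, str, str]

DEFAULT_ORIENTATION: Orientation = ("R", "A", "S")


def validate_orientation(orientation) -> Orientation:
    codes = tuple(orientation)
    if len(codes) != 3 or any(c not in _CODE_TO_RAS for c in codes):
        raise ValueError(f"orientation must be 3 codes from RLAPSI, got {orientation!r}")
    if sorted(_AXIS_GROUP[c] for c in codes) != [0, 1, 2]:
        raise ValueError(
            f"orientation must name each anatomical axis exactly once, got {orientation!r}"
        )
    return codes  # type: ignore[return-value]


def axis_for(orientation: Orientation, anatomical: str) -> tuple[int, int]:
    """Return ``(array_axis, direction)`` for an anatomical dimension.

    ``anatomical`` is one of ``"SI"``, ``"AP"``, ``"RL"``; direction is +1 when
    increasing index runs toward the first letter (superior / anterior / right),
    -1 otherwise.
    """
    first = anatomical[0]
    group = _AXIS_GROUP[first]
    for ax, code in enumerate(orientation):
        if _AXIS_GROUP[code] == group:
            return ax, (1 if code == first else -1)
    raise ValueError(f"orientation {orientation!r} lacks axis {anatomical!r}")


def superior_axis(orientation: Orientation) -> tuple[int, int]:
    """Array axis running superior-inferior and the sign of the superior direction."""
    return axis_for(orientation, "SI")


def anterior_axis(orientation: Orientation) -> tuple[int, int]:
    return axis_for(orientation, "AP")


@dataclass
class CTVolume:
    """HU voxel grid with spacing, orientation and protocol metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: Orientation = DEFAULT_ORIENTATION
    protocol: str = "default"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive on all axes: {self.spacing}")
        self.orientation = validate_orientation(self.orientation)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def affine(self) -> np.ndarray:
        """Voxel-index -> RAS mm affine encoding spacing and orientation."""
        aff = np.eye(4)
        for ax, code in enumerate(self.orientation):
            aff[:3, ax] = _CODE_TO_RAS[code] * self.spacing[ax]
        return aff


def _axcodes_from_affine(affine: np.ndarray) -> Orientation:
    # nibabel reports codes in RAS+ terms for each array axis
    codes = nib.orientations.aff2axcodes(affine, labels=(("L", "R"), ("P", "A"), ("I", "S")))
    return validate_orientation(codes)


def save_nifti(path, volume: CTVolume, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=dtype), volume.affine())
    nib.save(img, str(path))


def load_nifti(path, protocol: str = "default") -> CTVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    orientation = _axcodes_from_affine(affine)
    data = np.asarray(img.dataobj, dtype=np.float32)
    return CTVolume(voxels=data, spacing=spacing, orientation=orientation, protocol=protocol)


def save_mask_nifti(path, mask: np.ndarray, like: CTVolume) -> None:
    """Write an integer/boolean mask on the grid of an existing volume."""
    if mask.shape != like.shape:
        raise ValueError("mask shape does not match volume shape")
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), like.affine())
    nib.save(img, str(path))


def load_mask_nifti(path) -> tuple[np.ndarray, Orientation, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    orientation = _axcodes_from_affine(img.affine)
    return np.asarray(img.dataobj).astype(np.int16), orientation, spacing
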