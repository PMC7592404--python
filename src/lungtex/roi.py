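"""Cylindrical volume-of-interest construction and extraction.

The protocol is a 4 cm-diameter circle drawn on 10 consecutive
2.5 mm slices in the lung apex, i.e. a right circular cylinder of
parenchyma roughly 4 cm across and 2.5 cm tall.  Placement (centre and
top slice) is supplied by configuration — for phantoms, by the
generator — because apex localisation on real scans is manual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .volumes import CTVolume

__all__ = ["CylinderSpec", "ROIMask", "make_cylinder_mask", "extract_roi", "write_mask"]


@dataclass
class CylinderSpec:
    """Geometry of the apical cylindrical VOI.

    ``center_xy`` is the in-plane centre in mm, in the coordinate frame
    where the centre of voxel column/row ``i`` sits at ``i * spacing``.
    ``top_slice`` is the index of the most apical slice included; the
    mask covers slices ``[top_slice, top_slice + n_slices)``.
    """

    center_xy: tuple[float, float]
    top_slice: int
    diameter_mm: float = 40.0
    n_slices: int = 10
    expected_slice_thickness_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass
class ROIMask:
    """Boolean mask congruent with a CTVolume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROIMask must be 3-D")
        if not self.mask.any():
            raise ValueError("ROIMask must contain at least one true voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def make_cylinder_mask(volume: CTVolume, spec: CylinderSpec) -> ROIMask:
    """Build the cylinder mask: voxel centres strictly inside the circle,
    over ``n_slices`` consecutive slices.

    A voxel belongs to the VOI iff its in-plane centre lies strictly
    within ``diameter_mm / 2`` of ``center_xy`` and its slice index is in
    ``[top_slice, top_slice + n_slices)``.  The cylinder must fit inside
    the volume; a slice thickness different from the expected 2.5 mm
    triggers a warning but the 10-consecutive-slices semantics is kept.
    """
    dx, dy, dz = volume.spacing
    nz, ny, nx = volume.shape
    cx, cy = (float(v) for v in spec.center_xy)
    r = spec.diameter_mm / 2.0

    if spec.top_slice < 0 or spec.top_slice + spec.n_slices > nz:
        raise ValueError(
            f"cylinder slices [{spec.top_slice}, {spec.top_slice + spec.n_slices}) "
            f"exceed volume with {nz} slices"
        )
    # physical in-plane extent, out to the voxel faces
    if (
        cx - r < -dx / 2
        or cx + r > (nx - 1) * dx + dx / 2
        or cy - r < -dy / 2
        or cy + r > (ny - 1) * dy + dy / 2
    ):
        raise ValueError("cylinder extends outside the volume in-plane extent")
    if abs(dz - spec.expected_slice_thickness_mm) > 1e-6:
        warnings.warn(
            f"slice thickness {dz} mm differs from expected "
            f"{spec.expected_slice_thickness_mm} mm; keeping n_slices={spec.n_slices}",
            stacklevel=2,
        )

    x = np.arange(nx) * dx - cx
    y = np.arange(ny) * dy - cy
    inplane = (x[np.newaxis, :] ** 2 + y[:, np.newaxis] ** 2) < r**2
    mask = np.zeros(volume.shape, dtype=bool)
    mask[spec.top_slice : spec.top_slice + spec.n_slices] = inplane
    if not mask.any():
        raise ValueError("cylinder mask contains no voxels at this resolution")
    return ROIMask(mask, volume.spacing)


def extract_roi(volume: CTVolume, mask: ROIMask) -> tuple[np.ndarray, np.ndarray]:
    """Return the grey levels at true voxels with their integer coordinates.

    Values come back in lexicographic (slice, row, column) order, so the
    extraction is deterministic and its length equals the mask true-count.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    coords = np.argwhere(mask.mask)  # C-order argwhere is lexicographic
    values = volume.voxels[mask.mask]
    return values, coords


def write_mask(mask: ROIMask, path: str) -> None:
    """Write the mask as a 0/1 NIfTI volume."""
    affine = np.diag(list(mask.spacing) + [1.0]).astype(float)
    img = nib.Nifti1Image(mask.mask.T.astype(np.uint8), affine)
    nib.save(img, path)
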