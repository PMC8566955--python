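"""Label volumes: binary occupancy grids in millimeter patient space.

The whole pipeline uses one coordinate convention: a right-handed frame in
millimeters with the tendon's proximo-distal axis along +z.  A voxel with
index ``(i, j, k)`` is the axis-aligned box whose *center* sits at
``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class LabelVolume:
    """Binary occupancy grid with voxel geometry.

    Parameters
    ----------
    data:
        Boolean (or 0/1) array indexed ``[ix, iy, iz]``.
    spacing:
        Voxel edge lengths in mm, one per axis, all strictly positive.
    origin:
        World position (mm) of the *corner* of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3-D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three strictly positive values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * self.spacing

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def occupied_volume_mm3(self) -> float:
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3

    # -- derived fields -----------------------------------------------------

    def signed_distance_mm(self) -> np.ndarray:
        """Signed Euclidean distance to the occupancy boundary.

        Negative inside the solid, positive outside, in millimeters.  An
        occupied voxel always maps to a strictly negative value and a
        background voxel to a strictly positive one, so thresholding the
        result at zero recovers ``data`` exactly.
        """
        occ = self.data.astype(bool)
        if not occ.any():
            return np.full(self.shape, np.inf)
        d_out = ndimage.distance_transform_edt(~occ, sampling=self.spacing)
        d_in = ndimage.distance_transform_edt(occ, sampling=self.spacing)
        return np.asarray(d_out - d_in)

    def dice(self, other: "LabelVolume") -> float:
        """Dice overlap with another volume on the identical grid."""
        if self.shape != other.shape:
            raise ValueError("Dice requires volumes on the same grid")
        a = self.data.astype(bool)
        b = other.data.astype(bool)
        denom = a.sum() + b.sum()
        if denom == 0:
            return 1.0
        return float(2.0 * np.logical_and(a, b).sum() / denom)

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin + 0.5 * self.spacing
        return nib.Nifti1Image(self.data.astype(np.uint8), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3] - 0.5 * spacing
        return cls(np.asarray(img.dataobj).astype(np.uint8), spacing, origin)


def common_grid(
    lo: np.ndarray, hi: np.ndarray, spacing, pad_mm: float = 0.0
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Build (origin, spacing, shape) for a grid covering ``[lo, hi]``."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    lo = np.asarray(lo, dtype=float) - pad_mm
    hi = np.asarray(hi, dtype=float) + pad_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    return lo, spacing, tuple(int(n) for n in shape)
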