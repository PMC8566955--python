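"""Acquisition metadata, voxel geometry, and standard-format I/O.

Voxel in-plane size follows the standard relation

    width (mm) = field of view (mm) / matrix width

and voxel depth is the spacing between slices (slice increment).  A voxel
is isotropic when width, height and depth agree.  STL files carry no
units; this package declares millimeters for every mesh it reads or
writes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import trimesh


class MetadataError(ValueError):
    """Raised when acquisition metadata is missing or inconsistent."""


@dataclass
class AcquisitionMeta:
    """Key acquisition parameters as read from DICOM-style metadata.

    All lengths in mm; ``field_strength_T`` in tesla.  Either
    ``field_of_view_mm`` or ``pixel_spacing_mm`` must be present for
    in-plane voxel size to be computable.
    """

    field_strength_T: float
    slice_thickness_mm: float
    spacing_between_slices_mm: float
    matrix_width: int
    matrix_height: int
    repetition_time: float = 0.0
    echo_time: float = 0.0
    pixel_spacing_mm: tuple[float, float] | None = None
    field_of_view_mm: float | None = None
    sequence: str | None = None  # pass-through (e.g. "PDW", "T1W 3D")

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0 or self.spacing_between_slices_mm <= 0:
            raise MetadataError("slice thickness and spacing must be positive")
        if self.matrix_width < 2 or self.matrix_height < 2:
            raise MetadataError("matrix must be at least 2 in each dimension")
        if self.pixel_spacing_mm is not None and any(
            p <= 0 for p in self.pixel_spacing_mm
        ):
            raise MetadataError("pixel spacing must be positive")

    @classmethod
    def from_dicom(cls, dataset) -> "AcquisitionMeta":
        """Build from a ``pydicom`` dataset (metadata tags only)."""
        ps = getattr(dataset, "PixelSpacing", None)
        return cls(
            field_strength_T=float(getattr(dataset, "MagneticFieldStrength", 0.0)),
            slice_thickness_mm=float(dataset.SliceThickness),
            spacing_between_slices_mm=float(
                getattr(dataset, "SpacingBetweenSlices", dataset.SliceThickness)
            ),
            matrix_width=int(dataset.Columns),
            matrix_height=int(dataset.Rows),
            repetition_time=float(getattr(dataset, "RepetitionTime", 0.0)),
            echo_time=float(getattr(dataset, "EchoTime", 0.0)),
            pixel_spacing_mm=None if ps is None else (float(ps[0]), float(ps[1])),
        )


@dataclass
class VoxelGeometry:
    """Voxel edge lengths in mm with the isotropy flag."""

    width_mm: float
    height_mm: float
    depth_mm: float
    isotropic: bool = field(init=False)

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.depth_mm) <= 0:
            raise ValueError("voxel dimensions must be positive")
        dims = np.array([self.width_mm, self.height_mm, self.depth_mm])
        self.isotropic = bool(np.all(np.abs(dims - dims[0]) <= 1e-9 * dims[0]))

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.width_mm, self.height_mm, self.depth_mm])


def compute_voxel_dimensions(meta: AcquisitionMeta) -> VoxelGeometry:
    """Voxel geometry from acquisition metadata.

    Width/height come from FOV divided by matrix size when the field of
    view is recorded, otherwise directly from pixel spacing; depth is the
    spacing between slices.
    """
    if meta.field_of_view_mm is not None:
        width = meta.field_of_view_mm / meta.matrix_width
        height = meta.field_of_view_mm / meta.matrix_height
    elif meta.pixel_spacing_mm is not None:
        width, height = meta.pixel_spacing_mm
    else:
        raise MetadataError(
            "need either field_of_view_mm or pixel_spacing_mm to size voxels"
        )
    return VoxelGeometry(width, height, meta.spacing_between_slices_mm)


# ---------------------------------------------------------------------------
# STL


class OpenSurfaceWarning(UserWarning):
    """The mesh read from disk is not watertight."""


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL surface (binary or ASCII); warns if not watertight."""
    mesh = trimesh.load(str(path), force="mesh")
    if len(mesh.faces) == 0:
        raise ValueError(f"{path}: empty mesh")
    if not mesh.is_watertight:
        warnings.warn(f"{path}: surface is not watertight", OpenSurfaceWarning)
    return mesh


def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary") -> None:
    """Write an STL surface in the requested dialect."""
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if dialect == "binary":
        mesh.export(str(path), file_type="stl")
    elif dialect == "ascii":
        mesh.export(str(path), file_type="stl_ascii")
    else:
        raise ValueError(f"unknown STL dialect {dialect!r}")


# ---------------------------------------------------------------------------
# acquisition summaries


def median_midpoint(values: Iterable[float]) -> float:
    """Median with the even-count midpoint-mean convention (no interpolation
    beyond the average of the two central order statistics)."""
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("median of an empty sequence")
    mid = v.size // 2
    if v.size % 2 == 1:
        return float(v[mid])
    return float(0.5 * (v[mid - 1] + v[mid]))


def summarize_acquisition(
    records: list[AcquisitionMeta], group_by: str = "field_strength_T"
) -> dict:
    """Median and (min, max) range of each numeric parameter per group.

    Groups are typically field strengths, mirroring how acquisition
    parameters are reported separately for high- and low-field systems.
    """
    if not records:
        raise ValueError("no acquisition records")
    params = [
        "slice_thickness_mm",
        "spacing_between_slices_mm",
        "repetition_time",
        "echo_time",
    ]
    out: dict = {}
    keys = sorted({getattr(r, group_by) for r in records})
    for key in keys:
        grp = [r for r in records if getattr(r, group_by) == key]
        summary = {}
        for p in params:
            vals = [getattr(r, p) for r in grp]
            summary[p] = {
                "median": median_midpoint(vals),
                "range": (float(min(vals)), float(max(vals))),
            }
        out[key] = summary
    return out
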