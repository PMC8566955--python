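"""Fusion and refinement of planar reconstructions into a tendon part.

The three single-plane surfaces are fused by Boolean intersection — only
geometry common to all three acquisitions survives — then cropped to the
standardized proximo-distal extent, wrapped (gap closing 0.5 mm, smallest
detail 1 mm) and smoothed (factor 0.7).  Boolean operations run on a
common voxelization followed by re-meshing, which is robust to the
near-coincident surfaces produced by independently segmented planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from ._mesh import mesh_from_volume, rasterize_mesh, surface_shell_mask
from .grid import LabelVolume, common_grid

DEFAULT_GAP_CLOSING_MM = 0.5
DEFAULT_SMALLEST_DETAIL_MM = 1.0
DEFAULT_SMOOTH_FACTOR = 0.7


@dataclass
class TendonPart:
    """A watertight tendon surface in mm with its build provenance."""

    mesh: trimesh.Trimesh
    provenance: dict = field(default_factory=dict)

    @property
    def volume_mm3(self) -> float:
        return float(abs(self.mesh.volume))


def _as_mesh(obj) -> trimesh.Trimesh:
    return obj.mesh if isinstance(obj, TendonPart) else obj


@dataclass
class CropPlanes:
    """Proximal and distal crop planes (point + unit normal, both distally
    directed); the kept slab is between them."""

    proximal_point: np.ndarray
    proximal_normal: np.ndarray
    distal_point: np.ndarray
    distal_normal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("proximal_normal", "distal_normal"):
            v = np.asarray(getattr(self, name), float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be nonzero")
            setattr(self, name, v / n)
        self.proximal_point = np.asarray(self.proximal_point, float)
        self.distal_point = np.asarray(self.distal_point, float)
        if np.dot(self.proximal_normal, self.distal_point - self.proximal_point) <= 0:
            raise ValueError(
                "proximal plane must lie proximal of the distal plane "
                "(planes swapped?)"
            )


def boolean_intersect(
    meshes, pitch_mm: float = 0.5
) -> trimesh.Trimesh:
    """Boolean intersection of exactly three watertight surfaces.

    The meshes keep their original spatial relationship; the intersection
    is computed on a shared voxelization at ``pitch_mm`` and re-meshed.
    An empty intersection returns an empty mesh (no crash).
    """
    meshes = [_as_mesh(m) for m in meshes]
    if len(meshes) != 3:
        raise ValueError("boolean_intersect expects exactly three meshes")
    for m in meshes:
        if not m.is_watertight:
            raise ValueError("boolean intersection requires watertight inputs")
    lo = np.max([m.bounds[0] for m in meshes], axis=0)
    hi = np.min([m.bounds[1] for m in meshes], axis=0)
    if np.any(hi <= lo):
        return trimesh.Trimesh()
    origin, spacing, shape = common_grid(lo, hi, pitch_mm, pad_mm=2 * pitch_mm)
    occ = np.ones(shape, dtype=bool)
    for m in meshes:
        occ &= rasterize_mesh(m, origin, spacing, shape).data
    if not occ.any():
        return trimesh.Trimesh()
    return mesh_from_volume(LabelVolume(occ, spacing, origin))


def crop_between_planes(
    mesh, planes: CropPlanes, pitch_mm: float = 0.3
) -> trimesh.Trimesh:
    """Clip a watertight mesh to the slab between the two crop planes.

    If the slab contains the whole mesh the input is returned unchanged;
    otherwise the mesh is re-meshed from its voxelization restricted to
    the slab (re-capped to watertightness by construction).  A slab that
    misses the mesh entirely yields an empty mesh.
    """
    mesh = _as_mesh(mesh)
    if not mesh.is_watertight:
        raise ValueError("crop requires a watertight input")
    corners = trimesh.bounds.corners(mesh.bounds)
    side_p = (corners - planes.proximal_point) @ planes.proximal_normal
    side_d = (corners - planes.distal_point) @ planes.distal_normal
    if np.all(side_p >= 0) and np.all(side_d <= 0):
        return mesh.copy()
    origin, spacing, shape = common_grid(
        mesh.bounds[0], mesh.bounds[1], pitch_mm, pad_mm=2 * pitch_mm
    )
    vol = rasterize_mesh(mesh, origin, spacing, shape)
    xs = [vol.axis_centers(a) for a in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    keep = ((pts - planes.proximal_point) @ planes.proximal_normal >= 0) & (
        (pts - planes.distal_point) @ planes.distal_normal <= 0
    )
    occ = vol.data & keep
    if not occ.any():
        return trimesh.Trimesh()
    return mesh_from_volume(LabelVolume(occ, spacing, origin))


def wrap(
    mesh,
    gap_closing_mm: float = DEFAULT_GAP_CLOSING_MM,
    smallest_detail_mm: float = DEFAULT_SMALLEST_DETAIL_MM,
) -> trimesh.Trimesh:
    """Shrink-wrap a (possibly open) surface into a watertight one.

    Realized as: conservative surface voxelization at a pitch derived
    from ``smallest_detail_mm`` → morphological closing with a ball of
    radius ``gap_closing_mm / 2`` → hole filling → surface extraction at
    the mid-shell level (averaging the filled solid with its strict
    interior), which keeps the output surface centered on the input
    surface rather than inflated by the voxel shell.
    """
    mesh = _as_mesh(mesh)
    if len(mesh.faces) == 0 or mesh.area == 0:
        raise ValueError("cannot wrap a degenerate (zero-area) mesh")
    if gap_closing_mm <= 0 or smallest_detail_mm <= 0:
        raise ValueError("wrap parameters must be positive")
    pitch = min(smallest_detail_mm / 2.0, 0.5)
    margin = gap_closing_mm + 4 * pitch
    origin, spacing, shape = common_grid(
        mesh.bounds[0], mesh.bounds[1], pitch, pad_mm=margin
    )
    shell = surface_shell_mask(mesh, origin, spacing, shape)
    r_vox = max(1, int(round(gap_closing_mm / 2.0 / pitch)))
    ball = _ball(r_vox)
    closed = ndimage.binary_closing(shell, structure=ball)
    filled = ndimage.binary_fill_holes(closed)
    interior = filled & ~shell
    if interior.any():
        # signed mid-shell field: zero midway between the strict interior
        # and the outside, which centers the output on the input surface
        # instead of inflating it by the voxel shell
        d_int = ndimage.distance_transform_edt(~interior, sampling=spacing)
        d_out = ndimage.distance_transform_edt(filled, sampling=spacing)
        field = d_out - d_int
    else:  # too thin to have a strict interior at this pitch
        field = filled.astype(float) - 0.5
    padded = np.pad(field, 1, mode="constant", constant_values=field.min())
    # tiny positive level so voxels exactly equidistant from interior and
    # outside (symmetric slabs) do not sit on the isosurface
    verts, faces, _, _ = marching_cubes(padded, level=1e-6, spacing=tuple(spacing))
    # skimage's output is already vertex-merged and manifold; trimesh's
    # processing can pinch degenerate triangles into non-manifold edges
    out = trimesh.Trimesh(verts + origin - 0.5 * spacing, faces, process=False)
    if out.volume < 0:
        out.invert()
    return out


def _ball(r: int) -> np.ndarray:
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return x * x + y * y + z * z <= r * r


def smooth(mesh, factor: float = DEFAULT_SMOOTH_FACTOR) -> trimesh.Trimesh:
    """Volume-compensated (Taubin) smoothing.

    ``factor`` in [0, 1] maps to the Taubin shrink weight ``0.5 * factor``
    (with the matched inflate step) over a fixed 10 iterations; 0 is the
    identity.  This mapping is this package's convention for a single
    smoothing-strength knob.
    """
    mesh = _as_mesh(mesh)
    if not 0.0 <= factor <= 1.0:
        raise ValueError("smoothing factor must lie in [0, 1]")
    out = mesh.copy()
    if factor == 0.0 or len(out.faces) == 0:
        return out
    trimesh.smoothing.filter_taubin(
        out, lamb=0.5 * factor, nu=-0.53 * factor, iterations=10
    )
    return out


def build_part(
    sagittal,
    axial,
    dorsal,
    crop: CropPlanes | None = None,
    gap_closing_mm: float = DEFAULT_GAP_CLOSING_MM,
    smallest_detail_mm: float = DEFAULT_SMALLEST_DETAIL_MM,
    smooth_factor: float = DEFAULT_SMOOTH_FACTOR,
    intersect_pitch_mm: float = 0.5,
    crop_before_intersection: bool = False,
) -> TendonPart:
    """Run intersection → crop → wrap → smooth and record provenance.

    The default order crops *after* the Boolean intersection; set
    ``crop_before_intersection`` to crop each planar surface first.
    """
    meshes = [_as_mesh(m) for m in (sagittal, axial, dorsal)]
    if crop is not None and crop_before_intersection:
        meshes = [crop_between_planes(m, crop) for m in meshes]
    fused = boolean_intersect(meshes, pitch_mm=intersect_pitch_mm)
    if len(fused.faces) == 0:
        raise ValueError("Boolean intersection of the three planes is empty")
    if crop is not None and not crop_before_intersection:
        fused = crop_between_planes(fused, crop)
        if len(fused.faces) == 0:
            raise ValueError("crop slab misses the fused part")
    wrapped = wrap(fused, gap_closing_mm, smallest_detail_mm)
    final = smooth(wrapped, smooth_factor)
    return TendonPart(
        final,
        provenance={
            "source_planes": ["sagittal", "axial", "dorsal"],
            "crop": None
            if crop is None
            else {
                "proximal_point": list(map(float, crop.proximal_point)),
                "proximal_normal": list(map(float, crop.proximal_normal)),
                "distal_point": list(map(float, crop.distal_point)),
                "distal_normal": list(map(float, crop.distal_normal)),
                "before_intersection": crop_before_intersection,
            },
            "gap_closing_mm": gap_closing_mm,
            "smallest_detail_mm": smallest_detail_mm,
            "smooth_factor": smooth_factor,
            "intersect_pitch_mm": intersect_pitch_mm,
        },
    )
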