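"""Internal mesh/voxel geometry kernels.

Everything here is exact or resolution-controlled numerics shared by the
reconstruction, refinement and comparison stages:

* ``mesh_from_volume`` — marching-cubes surface extraction in world mm.
* ``rasterize_mesh`` — parity (even/odd) voxelization of a closed surface.
* ``surface_shell_mask`` — conservative voxelization of an arbitrary
  (possibly open) triangle soup.
* ``SurfaceLocator`` — exact point-to-surface (point-to-triangle) nearest
  queries with a centroid k-d tree plus a guaranteed ball-refinement pass.
* ``ray_first_hit`` — first positive Möller–Trumbore intersection along
  rays, used for wall-thickness chords.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .grid import LabelVolume

# ---------------------------------------------------------------------------
# surface extraction


def mesh_from_volume(vol: LabelVolume, smooth_sigma_vox: float = 0.0) -> trimesh.Trimesh:
    """Extract a watertight surface from a binary volume.

    The volume is zero-padded so the isosurface is closed even when the
    occupancy touches the grid boundary.  ``smooth_sigma_vox`` optionally
    pre-smooths the binary field (in voxel units) to reduce terracing.
    """
    occ = vol.data.astype(float)
    if not occ.any():
        raise ValueError("cannot extract a surface from an empty volume")
    padded = np.pad(occ, 1)
    if smooth_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, smooth_sigma_vox)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(vol.spacing))
    verts = verts + vol.origin - 0.5 * vol.spacing
    # skimage output is vertex-merged and manifold; keep it as is
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# voxelization


def _slice_rings(mesh: trimesh.Trimesh, z: float):
    """Closed cross-section rings of ``mesh`` at height ``z`` (may be [])."""
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z]
    )
    if len(segments) == 0:
        return []
    path = trimesh.load_path(segments[:, :, :2])
    try:
        polys = path.polygons_closed
    except BaseException:
        return []
    return [p for p in polys if p is not None and p.area > 0]


def rasterize_mesh(
    mesh: trimesh.Trimesh,
    origin: np.ndarray,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
) -> LabelVolume:
    """Even/odd rasterization of a closed surface onto a voxel grid.

    Each z-slice of the grid is filled by testing pixel centers against the
    cross-section rings with even/odd parity, so nested surfaces (holes)
    are handled correctly.  Section planes are offset by a tiny epsilon to
    dodge degenerate coplanar facets.
    """
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float)
    occ = np.zeros(shape, dtype=bool)
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    eps = 1e-4 * spacing[2]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    for k in range(shape[2]):
        z = origin[2] + (k + 0.5) * spacing[2] + eps
        rings = _slice_rings(mesh, z)
        if not rings:
            continue
        plane = np.zeros((shape[0], shape[1]), dtype=bool)
        for ring in rings:
            minx, miny, maxx, maxy = ring.bounds
            i0, i1 = np.searchsorted(xs, [minx, maxx])
            j0, j1 = np.searchsorted(ys, [miny, maxy])
            i1 = min(i1 + 1, shape[0])
            j1 = min(j1 + 1, shape[1])
            if i0 >= i1 or j0 >= j1:
                continue
            sub = shapely.contains_xy(
                ring, gx[i0:i1, j0:j1].ravel(), gy[i0:i1, j0:j1].ravel()
            ).reshape(i1 - i0, j1 - j0)
            plane[i0:i1, j0:j1] ^= sub
        occ[:, :, k] = plane
    return LabelVolume(occ, spacing, origin)


def surface_shell_mask(
    mesh: trimesh.Trimesh,
    origin: np.ndarray,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Mark voxels touched by the surface of an arbitrary triangle soup.

    Triangles are subdivided until every edge is shorter than half the
    smallest voxel edge; marking the voxels containing the resulting
    vertices yields a (conservatively thin) one-voxel shell.
    """
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float)
    max_edge = 0.5 * float(np.min(spacing))
    verts, _ = trimesh.remesh.subdivide_to_size(
        mesh.vertices, mesh.faces, max_edge=max_edge
    )
    idx = np.floor((verts - origin) / spacing).astype(int)
    keep = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    idx = idx[keep]
    shell = np.zeros(shape, dtype=bool)
    shell[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return shell


# ---------------------------------------------------------------------------
# exact nearest point on a triangulated surface


class SurfaceLocator:
    """Exact nearest-point queries against a triangle surface.

    A k-d tree over face centroids provides candidates; a second
    ball-query pass with radius ``d_upper + r_max`` guarantees the true
    nearest triangle is among them (any face closer than the current upper
    bound must have its centroid within that radius).
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise ValueError("empty mesh")
        self.mesh = mesh
        self.triangles = mesh.triangles.copy()
        self.centroids = self.triangles.mean(axis=1)
        # max centroid-to-vertex distance over the whole mesh
        self.r_max = float(
            np.sqrt(
                ((self.triangles - self.centroids[:, None, :]) ** 2)
                .sum(axis=2)
                .max()
            )
        )
        self.tree = cKDTree(self.centroids)
        self.face_normals = mesh.face_normals.copy()

    def closest(self, points: np.ndarray):
        """Return (distance, closest_point, face_index) for each query."""
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        _, i0 = self.tree.query(points)
        cp0 = trimesh.triangles.closest_point(self.triangles[i0], points)
        d_upper = np.linalg.norm(points - cp0, axis=1)
        radius = d_upper + self.r_max + 1e-9
        lists = self.tree.query_ball_point(points, radius)
        counts = np.fromiter((len(c) for c in lists), dtype=int, count=n)
        if counts.sum() == 0:
            return d_upper, cp0, i0
        flat = np.concatenate([np.asarray(c, dtype=int) for c in lists])
        seg = np.repeat(np.arange(n), counts)
        cps = trimesh.triangles.closest_point(self.triangles[flat], points[seg])
        d = np.linalg.norm(points[seg] - cps, axis=1)
        best_d = d_upper.copy()
        best_cp = cp0.copy()
        best_f = i0.copy()
        # per-segment argmin: sort by (segment, distance), take first of each
        order = np.lexsort((d, seg))
        seg_sorted = seg[order]
        first = np.searchsorted(seg_sorted, np.arange(n))
        has = first < len(seg_sorted)
        safe = np.minimum(first, len(seg_sorted) - 1)
        has &= seg_sorted[safe] == np.arange(n)
        take = order[safe]
        upd = has & (d[take] <= best_d + 1e-15)
        best_cp[upd] = cps[take[upd]]
        best_f[upd] = flat[take[upd]]
        best_d[upd] = d[take[upd]]
        return best_d, best_cp, best_f

    def signed(self, points: np.ndarray):
        """Signed distance: positive outside the surface, negative inside.

        The sign comes from the nearest face's outward normal; when the
        nearest point falls on an edge or vertex the nearest-face normal is
        still a consistent classifier for the smooth, watertight meshes the
        pipeline produces.
        """
        d, cp, f = self.closest(points)
        points = np.atleast_2d(np.asarray(points, float))
        dots = np.einsum("ij,ij->i", points - cp, self.face_normals[f])
        sign = np.where(dots >= 0, 1.0, -1.0)
        return sign * d, cp, f


# ---------------------------------------------------------------------------
# ray casting


def ray_first_hit(
    mesh: trimesh.Trimesh,
    origins: np.ndarray,
    directions: np.ndarray,
    t_min: float = 1e-6,
    t_max: float = np.inf,
) -> np.ndarray:
    """Distance to the first surface crossing along each ray (inf if none).

    Chunked pairwise Möller–Trumbore over rays x triangles; memory is
    bounded by the chunk size, runtime is O(n_rays * n_triangles) which
    is predictable and fully vectorized.
    """
    origins = np.atleast_2d(np.asarray(origins, float))
    directions = np.atleast_2d(np.asarray(directions, float))
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    tri = mesh.triangles
    nt = len(tri)
    n_rays = len(origins)
    out = np.full(n_rays, np.inf)
    chunk = max(1, int(4e6 / max(nt, 1)))
    tri_rep_cache: dict[int, np.ndarray] = {}
    for s in range(0, n_rays, chunk):
        e = min(s + chunk, n_rays)
        m = e - s
        if m not in tri_rep_cache:
            tri_rep_cache[m] = np.tile(tri, (m, 1, 1))
        o = np.repeat(origins[s:e], nt, axis=0)
        d = np.repeat(directions[s:e], nt, axis=0)
        t = _moller_trumbore(tri_rep_cache[m], o, d, t_min, t_max)
        out[s:e] = t.reshape(m, nt).min(axis=1)
    return out


def _moller_trumbore(tri, o, d, t_min, t_max):
    """Pairwise ray/triangle intersection parameter t (inf when missing)."""
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = o - v0
    u = np.einsum("ij,ij->i", tvec, p) * inv
    q = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    tol = 1e-9
    good = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > t_min) & (t <= t_max)
    return np.where(good, t, np.inf)
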