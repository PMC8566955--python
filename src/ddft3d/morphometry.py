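"""Per-part morphometry: enclosed volume and wall-thickness maps.

Thickness follows the wall-thickness convention: at each vertex the
solid is probed along the inward surface normal and the thickness is the
chord length to the first exit through the opposite wall.  Tendons are
thin curved solids, so this matches the dorso-palmar thickness a
clinician would read off an axial slice.  Rays that graze the surface
(no interior chord found within the bounding diameter) are flagged and
inherit the nearest valid neighbor's value instead of polluting the
minimum statistic with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import ray_first_hit
from .imaging_io import median_midpoint

#: inward offset (mm) applied to ray origins so the chord does not
#: immediately re-hit the faces incident to the starting vertex
_RAY_OFFSET_MM = 1e-3


@dataclass
class ThicknessMap:
    """Per-vertex solid thickness (mm) with the min/median/max summary."""

    values_mm: np.ndarray
    flagged: np.ndarray  # True where the chord was grazing / not found

    def summary(self) -> tuple[float, float, float]:
        return thickness_summary(self)

    def __len__(self) -> int:
        return len(self.values_mm)


def _as_mesh(part) -> trimesh.Trimesh:
    mesh = getattr(part, "mesh", part)
    if not isinstance(mesh, trimesh.Trimesh):
        raise TypeError("expected a TendonPart or trimesh.Trimesh")
    return mesh


def mesh_volume(part) -> float:
    """Enclosed volume (mm^3) by the divergence theorem, reported positive.

    Orientation is auto-corrected if the total signed volume is negative;
    an open (non-watertight) mesh is an error.
    """
    mesh = _as_mesh(part)
    if not mesh.is_watertight:
        raise ValueError("volume requires a watertight mesh")
    return float(abs(mesh.volume))


def thickness_map(part, vertex_mask: np.ndarray | None = None) -> ThicknessMap:
    """Wall thickness at every vertex by inward-normal ray casting.

    ``vertex_mask`` optionally restricts the computation to a subset of
    vertices (the rest are flagged), which keeps very dense meshes cheap.
    Vertex normals are the area-weighted average of incident triangle
    normals (trimesh's convention).
    """
    mesh = _as_mesh(part)
    if not mesh.is_watertight:
        raise ValueError("thickness requires a watertight mesh")
    verts = mesh.vertices
    normals = mesh.vertex_normals
    n = len(verts)
    sel = np.ones(n, dtype=bool) if vertex_mask is None else np.asarray(vertex_mask)
    max_chord = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    origins = verts[sel] - _RAY_OFFSET_MM * normals[sel]
    t = ray_first_hit(
        mesh, origins, -normals[sel], t_min=1e-6, t_max=max_chord
    )
    values = np.full(n, np.nan)
    flagged = np.ones(n, dtype=bool)
    hit = np.isfinite(t)
    idx = np.flatnonzero(sel)
    values[idx[hit]] = t[hit] + _RAY_OFFSET_MM
    flagged[idx[hit]] = False
    if flagged.any() and not flagged.all():
        values = _fill_from_neighbors(mesh, values, flagged)
    return ThicknessMap(values, flagged)


def _fill_from_neighbors(mesh, values, flagged):
    """Propagate nearest valid neighbor values across mesh edges (BFS)."""
    edges = mesh.edges_unique
    out = values.copy()
    todo = flagged.copy()
    for _ in range(len(out)):
        if not todo.any():
            break
        known = ~np.isnan(out)
        a, b = edges[:, 0], edges[:, 1]
        fill_a = todo[a] & known[b]
        fill_b = todo[b] & known[a]
        if not (fill_a.any() or fill_b.any()):
            break  # isolated component with no valid values
        out[a[fill_a]] = out[b[fill_a]]
        out[b[fill_b]] = out[a[fill_b]]
        todo[a[fill_a]] = False
        todo[b[fill_b]] = False
    return out


def thickness_summary(tmap: ThicknessMap) -> tuple[float, float, float]:
    """(min, median, max) over unflagged vertices; midpoint-mean median."""
    good = tmap.values_mm[~tmap.flagged]
    good = good[np.isfinite(good)]
    if good.size == 0:
        raise ValueError("no unflagged thickness values")
    return (
        float(good.min()),
        median_midpoint(good),
        float(good.max()),
    )


def thickness_to_csv(part, tmap: ThicknessMap, path) -> None:
    """Export per-vertex thickness as vertex_id,x,y,z,thickness_mm CSV."""
    import pandas as pd

    mesh = _as_mesh(part)
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(mesh.vertices)),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2],
            "thickness_mm": tmap.values_mm,
            "flagged": tmap.flagged.astype(int),
        }
    ).to_csv(path, index=False)
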