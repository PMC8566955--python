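"""Longitudinal comparison of two tendon parts.

Two scans of the same tendon are first aligned with rigid iterative
closest point (ICP) registration — rigid because the two parts are the
same physical structure, and any scaling would corrupt the thickness-
change semantics — and then compared point-by-point: for every vertex of
the follow-up part, the signed distance to the baseline surface.
Positive values mean the follow-up surface lies outside the baseline
(thickening), negative values inside (thinning).  The maximum unsigned
value is the directed Hausdorff distance from the follow-up vertices to
the baseline surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._mesh import SurfaceLocator
from .imaging_io import median_midpoint

DEFAULT_DISTANCE_THRESHOLD_MM = 5.0
DEFAULT_ITERATIONS = 100
DEFAULT_SUBSAMPLE_FRACTION = 0.90
DEFAULT_CHANGE_THRESHOLD_MM = 1.5


class RegistrationError(RuntimeError):
    """Registration failed; carries diagnostics in ``.diagnostics``."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class RigidTransform:
    """Proper rigid transform: rotation (det = +1) plus translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_history_mm: list[float]
    n_pairs: int
    converged: bool
    seed: int | None = None


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (SVD, proper)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, mu_d - r @ mu_s)


def _mesh_of(part) -> trimesh.Trimesh:
    return getattr(part, "mesh", part)


def global_register(
    moving,
    fixed,
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
    iterations: int = DEFAULT_ITERATIONS,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
    rms_tol_mm: float = 1e-6,
) -> RegistrationResult:
    """Rigid ICP alignment of ``moving`` onto ``fixed``.

    Each iteration matches a seeded random subsample of the moving
    vertices (drawn once per call) to their nearest points on the fixed
    surface, rejects pairs beyond ``distance_threshold_mm``, solves the
    least-squares rigid transform, and composes it.  Stops at the
    iteration cap or when the RMS residual changes by less than
    ``rms_tol_mm``.
    """
    moving_mesh = _mesh_of(moving)
    fixed_mesh = _mesh_of(fixed)
    if len(moving_mesh.vertices) == 0 or len(fixed_mesh.vertices) == 0:
        raise RegistrationError("empty part")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    verts = moving_mesh.vertices
    k = max(3, int(round(subsample_fraction * len(verts))))
    sub = rng.choice(len(verts), size=k, replace=False)
    pts0 = verts[sub]
    locator = SurfaceLocator(fixed_mesh)
    transform = RigidTransform.identity()
    rms_history: list[float] = []
    n_pairs = 0
    converged = False
    for _ in range(iterations):
        pts = transform.apply(pts0)
        d, cp, _ = locator.closest(pts)
        accept = d <= distance_threshold_mm
        n_pairs = int(accept.sum())
        if n_pairs == 0:
            raise RegistrationError(
                "no point pairs within the distance threshold",
                diagnostics={
                    "min_distance_mm": float(d.min()),
                    "threshold_mm": distance_threshold_mm,
                    "rms_history_mm": rms_history,
                },
            )
        rms = float(np.sqrt(np.mean(d[accept] ** 2)))
        if rms_history and abs(rms_history[-1] - rms) < rms_tol_mm:
            rms_history.append(rms)
            converged = True
            break
        rms_history.append(rms)
        step = _kabsch(pts[accept], cp[accept])
        transform = step.compose(transform)
    return RegistrationResult(transform, rms_history, n_pairs, converged, seed)


# ---------------------------------------------------------------------------
# part comparison


@dataclass
class PartComparison:
    """Signed per-vertex distances from follow-up vertices to baseline."""

    signed_mm: np.ndarray
    vertices: np.ndarray
    symmetric: bool = False
    directions: dict = field(default_factory=dict)

    @property
    def summary(self) -> tuple[float, float, float]:
        s = self.signed_mm
        return (float(s.min()), median_midpoint(s), float(s.max()))

    @property
    def directed_hausdorff_mm(self) -> float:
        return float(np.abs(self.signed_mm).max())


def part_compare(follow_up, baseline, symmetric: bool = False) -> PartComparison:
    """Signed surface deviation of the follow-up part from baseline.

    Distances are exact point-to-triangle (not point-to-vertex); the sign
    comes from the baseline's inside/outside classification at each
    follow-up vertex.  Parts must already be registered.  With
    ``symmetric=True`` the reverse direction (baseline vertices against
    the follow-up surface, signs negated to keep the same convention) is
    merged in.
    """
    fu = _mesh_of(follow_up)
    base = _mesh_of(baseline)
    if len(fu.vertices) == 0 or len(base.vertices) == 0:
        raise ValueError("cannot compare an empty part")
    signed, _, _ = SurfaceLocator(base).signed(fu.vertices)
    if not symmetric:
        return PartComparison(signed, fu.vertices.copy())
    rev, _, _ = SurfaceLocator(fu).signed(base.vertices)
    merged = np.concatenate([signed, -rev])
    return PartComparison(
        merged,
        np.vstack([fu.vertices, base.vertices]),
        symmetric=True,
        directions={"forward_n": len(fu.vertices), "reverse_n": len(base.vertices)},
    )


def change_exceeds(
    cmp: PartComparison, threshold_mm: float = DEFAULT_CHANGE_THRESHOLD_MM
) -> tuple[bool, dict]:
    """Whether thickness anywhere changed by at least ±threshold (inclusive)."""
    lo, med, hi = cmp.summary
    fired = bool(hi >= threshold_mm or lo <= -threshold_mm)
    return fired, {"min_mm": lo, "median_mm": med, "max_mm": hi,
                   "threshold_mm": threshold_mm}


def export_colormap(
    cmp: PartComparison,
    palette_range: tuple[float, float],
    mesh_path=None,
    csv_path=None,
    follow_up=None,
):
    """Diverging color map of the comparison, centered at zero.

    Values map onto a blue–white–red palette with zero at mid-palette;
    out-of-range values clamp to the end colors.  Writes a color-annotated
    mesh (PLY) when ``mesh_path`` and ``follow_up`` are given, and the
    per-vertex table as CSV when ``csv_path`` is given.  Returns the RGBA
    array (uint8).
    """
    lo, hi = palette_range
    if lo >= hi:
        raise ValueError("palette range must satisfy lo < hi")
    import matplotlib

    d = cmp.signed_mm
    t = np.empty_like(d)
    pos = d >= 0
    # piecewise-linear so that 0 -> mid palette, hi -> end, lo -> other end
    t[pos] = 0.5 + 0.5 * np.clip(d[pos] / hi, 0.0, 1.0) if hi > 0 else 1.0
    t[~pos] = 0.5 - 0.5 * np.clip(d[~pos] / lo, 0.0, 1.0) if lo < 0 else 0.0
    rgba = (matplotlib.colormaps["RdBu_r"](t) * 255).astype(np.uint8)
    if mesh_path is not None:
        if follow_up is None:
            raise ValueError("mesh export needs the follow-up part")
        mesh = _mesh_of(follow_up).copy()
        n = len(mesh.vertices)
        mesh.visual.vertex_colors = rgba[:n]
        mesh.export(str(mesh_path))
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "vertex_id": np.arange(len(d)),
                "x": cmp.vertices[:, 0],
                "y": cmp.vertices[:, 1],
                "z": cmp.vertices[:, 2],
                "signed_distance_mm": d,
                "r": rgba[:, 0],
                "g": rgba[:, 1],
                "b": rgba[:, 2],
            }
        ).to_csv(csv_path, index=False)
    return rgba
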