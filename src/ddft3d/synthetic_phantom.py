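"""Synthetic tendon phantoms with known geometry, lesions and change.

The phantom emulates the deep digital flexor tendon segment analyzed in
the pipeline: bilobed proximally (two overlapping lobes side by side),
thinning to a flat sheet distally, with a gentle sagittal bend emulating
the course around the navicular region.  The solid is defined by an
analytic signed-distance field, so ground-truth surfaces, volumes and
thicknesses are known independently of any reconstruction step.

Coordinate frame: millimeters, right-handed, proximal → distal along +z,
medial–lateral along x (the lobes), dorso-palmar along y (the thin
direction of the distal sheet).

Intensity is two-level: occupied tendon voxels are *hypointense* (label
1); lesions mark voxels *hyperintense* (label 2).  Background is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .grid import LabelVolume, common_grid

BACKGROUND, HYPOINTENSE, HYPERINTENSE = 0, 1, 2


# ---------------------------------------------------------------------------
# parameters and the analytic solid


@dataclass
class PhantomParams:
    """Geometry of the synthetic tendon segment.

    Defaults are sized to the equine digit: a ~60 mm proximo-distal
    segment whose enclosed volume falls in the 5,000–17,000 mm^3 span of
    real tendons, lobe diameter ~12 mm proximally and a ~3 mm sheet
    distally.
    """

    length_mm: float = 60.0
    proximal_lobe_radius_mm: float = 6.0
    lobe_separation_mm: float = 7.0
    distal_sheet_thickness_mm: float = 3.0
    distal_sheet_width_mm: float = 28.0
    curvature_radius_mm: float = 80.0
    roughness_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "length_mm",
            "proximal_lobe_radius_mm",
            "distal_sheet_thickness_mm",
            "distal_sheet_width_mm",
            "curvature_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lobe_separation_mm < 0:
            raise ValueError("lobe_separation_mm must be nonnegative")
        if self.distal_sheet_thickness_mm >= 2 * self.proximal_lobe_radius_mm:
            raise ValueError(
                "distal sheet must be thinner than the proximal lobe diameter"
            )
        if self.roughness_mm < 0:
            raise ValueError("roughness_mm must be nonnegative")


def _phantom_sdf(params: PhantomParams) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized signed-distance-like field of the phantom (negative inside)."""
    L = params.length_mm
    r = params.proximal_lobe_radius_mm
    cx = params.lobe_separation_mm / 2.0
    t2 = params.distal_sheet_thickness_mm / 2.0
    w2 = params.distal_sheet_width_mm / 2.0
    R = params.curvature_radius_mm

    if params.roughness_mm > 0:
        rng = np.random.default_rng(params.rng_seed)
        n_waves = 6
        k = rng.uniform(0.05, 0.25, size=(n_waves, 3))  # cycles/mm
        phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        amp = params.roughness_mm * rng.dirichlet(np.ones(n_waves))
    else:
        k = phase = amp = None

    def sdf(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        # sagittal bend: shift the cross-section center in y along z
        yb = y - (z - L / 2.0) ** 2 / (2.0 * R)
        s = np.clip(z / L, 0.0, 1.0)
        s = s * s * (3.0 - 2.0 * s)  # smoothstep
        # bilobed cross-section: union of two discs
        d_bilobe = np.minimum(np.hypot(x - cx, yb), np.hypot(x + cx, yb)) - r
        # sheet cross-section: rounded rectangle, half-thickness t2
        qx = np.abs(x) - (w2 - t2)
        qy = np.abs(yb)
        outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
        inside = np.minimum(np.maximum(qx, qy), 0.0)
        d_sheet = outside + inside - t2
        d = (1.0 - s) * d_bilobe + s * d_sheet
        # proximal/distal end caps
        d = np.maximum(d, np.abs(z - L / 2.0) - L / 2.0)
        if amp is not None:
            wave = np.zeros_like(d)
            for i in range(len(amp)):
                wave += amp[i] * np.sin(
                    2 * np.pi * (k[i, 0] * x + k[i, 1] * y + k[i, 2] * z) + phase[i]
                )
            d = d + wave
        return d

    return sdf


@dataclass
class TendonPhantom:
    """Ground truth bundle: label grid, truth surface, and the SDF."""

    labels: LabelVolume
    surface: trimesh.Trimesh
    sdf: Callable[[np.ndarray], np.ndarray] | None = None
    params: PhantomParams | None = None

    @property
    def occupancy(self) -> LabelVolume:
        """Binary view (any tendon tissue, hypo- or hyperintense)."""
        return LabelVolume(
            self.labels.data > BACKGROUND, self.labels.spacing, self.labels.origin
        )


def generate_tendon_phantom(
    params: PhantomParams | None = None, spacing_mm: float = 0.3
) -> TendonPhantom:
    """Rasterize the analytic phantom and extract its ground-truth surface.

    The occupancy grid marks voxels whose centers are inside the solid;
    the surface is the zero level set of the same field, so the two agree
    to within one voxel by construction.
    """
    params = params or PhantomParams()
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    sdf = _phantom_sdf(params)
    half_w = max(
        params.distal_sheet_width_mm / 2.0,
        params.lobe_separation_mm / 2.0 + params.proximal_lobe_radius_mm,
    )
    y_hi = params.proximal_lobe_radius_mm + params.length_mm**2 / (
        8.0 * params.curvature_radius_mm
    )
    lo = np.array([-half_w, -params.proximal_lobe_radius_mm, 0.0])
    hi = np.array([half_w, y_hi, params.length_mm])
    origin, spacing, shape = common_grid(lo, hi, spacing_mm, pad_mm=2.0)
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * spacing[2]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    field = sdf(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])).reshape(shape)
    occ = field < 0.0
    if not occ.any():
        raise ValueError("phantom parameters produce an empty solid")
    labels = LabelVolume(
        np.where(occ, HYPOINTENSE, BACKGROUND).astype(np.uint8), spacing, origin
    )
    verts, faces, _, _ = marching_cubes(field, level=0.0, spacing=tuple(spacing))
    surface = trimesh.Trimesh(verts + origin + 0.5 * spacing, faces, process=True)
    surface.fix_normals()
    return TendonPhantom(labels, surface, sdf, params)


# ---------------------------------------------------------------------------
# lesions


@dataclass
class LesionSpec:
    """An ellipsoidal hyperintense lesion.

    ``core`` lesions are internal (a rim of intact tendon must separate
    them from the surface); ``surface_split`` lesions contact the surface,
    like a parasagittal split.
    """

    kind: Literal["core", "surface_split"]
    center_mm: tuple[float, float, float]
    extent_mm: tuple[float, float, float]  # ellipsoid semi-axes

    def __post_init__(self) -> None:
        if self.kind not in ("core", "surface_split"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if any(e < 0 for e in self.extent_mm):
            raise ValueError("lesion extent must be nonnegative")


def apply_lesion(phantom: TendonPhantom, lesion: LesionSpec) -> TendonPhantom:
    """Mark an ellipsoidal region of the phantom hyperintense.

    A ``core`` lesion whose ellipsoid reaches the surface (i.e. any lesion
    voxel is 6-adjacent to background, leaving no intact rim) is a
    specification error.  A ``surface_split`` lesion must contact the
    surface.  Zero-extent lesions are no-ops.
    """
    if all(e == 0 for e in lesion.extent_mm):
        return phantom
    if any(e == 0 for e in lesion.extent_mm):
        raise ValueError("lesion extent must be zero or positive in all axes")
    vol = phantom.labels
    lo = vol.origin
    hi = vol.origin + vol.extent_mm
    c = np.asarray(lesion.center_mm, float)
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError("lesion center lies outside the phantom bounding box")
    xs = [vol.axis_centers(a) for a in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    e = np.asarray(lesion.extent_mm, float)
    inside = (
        ((gx - c[0]) / e[0]) ** 2 + ((gy - c[1]) / e[1]) ** 2 + ((gz - c[2]) / e[2]) ** 2
    ) <= 1.0
    occupied = vol.data > BACKGROUND
    lesion_mask = inside & occupied
    if not lesion_mask.any():
        raise ValueError("lesion does not overlap the tendon")
    background = ~occupied
    touches = lesion_mask & ndimage.binary_dilation(
        background, structure=ndimage.generate_binary_structure(3, 1)
    )
    if lesion.kind == "core" and touches.any():
        raise ValueError("core lesion reaches the surface: no intact rim")
    if lesion.kind == "surface_split" and not touches.any():
        raise ValueError("surface_split lesion does not contact the surface")
    data = vol.data.copy()
    data[lesion_mask] = HYPERINTENSE
    return TendonPhantom(
        LabelVolume(data, vol.spacing, vol.origin),
        phantom.surface,
        phantom.sdf,
        phantom.params,
    )


# ---------------------------------------------------------------------------
# longitudinal change


@dataclass
class ChangeField:
    """Signed normal displacement of the surface, in mm.

    ``patches`` are Gaussian bumps ``(center, amplitude_mm, sigma_mm)``:
    positive amplitude thickens (outward displacement), negative thins.
    ``uniform_mm`` displaces the whole surface.  The zero field leaves the
    geometry bitwise identical at the sampled resolution.
    """

    patches: list[tuple[tuple[float, float, float], float, float]] = dc_field(
        default_factory=list
    )
    uniform_mm: float = 0.0
    global_scale: float = 1.0

    def amplitude(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        a = np.full(len(p), float(self.uniform_mm))
        for center, amp, sigma in self.patches:
            r2 = ((p - np.asarray(center, float)) ** 2).sum(axis=1)
            a += amp * np.exp(-r2 / (2.0 * sigma**2))
        return self.global_scale * a

    @property
    def is_zero(self) -> bool:
        if self.global_scale == 0.0:
            return True
        return self.uniform_mm == 0.0 and all(a == 0.0 for _, a, _ in self.patches)


def simulate_followup(
    phantom: TendonPhantom, change: ChangeField, seed: int | None = None
) -> TendonPhantom:
    """Displace the phantom surface along its outward normals.

    Implemented on the signed-distance representation: the new solid is
    ``{x : sdf(x) < a(x)}`` where ``a`` is the (smooth) normal displacement
    amplitude, which avoids mesh self-intersection bookkeeping.  Erosion
    deeper than the local interior radius (which would invert the solid)
    is rejected.
    """
    del seed  # the change field is deterministic; kept for interface stability
    vol = phantom.occupancy
    if change.is_zero:
        return TendonPhantom(
            LabelVolume(phantom.labels.data.copy(), vol.spacing, vol.origin),
            phantom.surface,
            phantom.sdf,
            phantom.params,
        )
    sdf = vol.signed_distance_mm()
    xs = [vol.axis_centers(a) for a in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    a = change.amplitude(pts).reshape(vol.shape)
    affected = np.abs(a) > 0.05
    if affected.any():
        eroding = affected & (a < 0) & vol.data.astype(bool)
        if eroding.any():
            local_depth = float((-sdf[eroding]).max())
            if float((-a[eroding]).max()) >= local_depth:
                raise ValueError(
                    "displacement amplitude exceeds the local interior radius"
                )
    new_occ = sdf < a
    if not new_occ.any():
        raise ValueError("change field removed the entire solid")
    from ._mesh import mesh_from_volume

    new_labels = LabelVolume(
        np.where(new_occ, HYPOINTENSE, BACKGROUND).astype(np.uint8),
        vol.spacing,
        vol.origin,
    )
    surface = mesh_from_volume(LabelVolume(new_occ, vol.spacing, vol.origin))
    return TendonPhantom(new_labels, surface, None, phantom.params)


# ---------------------------------------------------------------------------
# tri-planar sampling


def _fraction_resample(vol: LabelVolume, coarse_spacing: np.ndarray) -> np.ndarray:
    """Occupancy fraction of coarse cells tiling the volume's extent.

    Separable exact overlap: per axis, a matrix of overlap lengths between
    coarse and fine cells; the fraction is the normalized triple product.
    """
    occ = vol.data.astype(float)
    mats = []
    for ax in range(3):
        n_fine = vol.shape[ax]
        fs = vol.spacing[ax]
        cs = coarse_spacing[ax]
        n_coarse = int(np.ceil(n_fine * fs / cs))
        fine_lo = np.arange(n_fine) * fs
        coarse_lo = np.arange(n_coarse) * cs
        ov = np.minimum(fine_lo[None, :] + fs, coarse_lo[:, None] + cs) - np.maximum(
            fine_lo[None, :], coarse_lo[:, None]
        )
        mats.append(np.maximum(ov, 0.0))
    frac = np.einsum("Ii,Jj,Kk,ijk->IJK", mats[0], mats[1], mats[2], occ, optimize=True)
    return frac / np.prod(coarse_spacing)


def sample_planar_stacks(
    truth: LabelVolume,
    plane_geometries: dict,
    misalignment_mm: dict | None = None,
):
    """Sample anisotropic per-plane mask stacks from a ground-truth volume.

    ``plane_geometries`` maps plane name (sagittal/axial/dorsal) to a
    :class:`~ddft3d.imaging_io.VoxelGeometry` whose depth is the spacing
    between slices.  A pixel is foreground iff the solid occupies at least
    half of its voxel (partial-volume binarization at 0.5, symmetric and
    unbiased for convex shapes).  ``misalignment_mm`` optionally translates
    individual planes to emulate imperfect inter-acquisition registration.
    """
    from .planar_segmentation import PLANE_AXES, PlanarStack

    if not np.asarray(truth.data).any():
        raise ValueError("cannot sample an all-background volume")
    stacks = {}
    for plane, geom in plane_geometries.items():
        if plane not in PLANE_AXES:
            raise ValueError(f"unknown plane {plane!r}")
        slice_ax, row_ax, col_ax = PLANE_AXES[plane]
        world_spacing = np.empty(3)
        world_spacing[slice_ax] = geom.depth_mm
        world_spacing[row_ax] = geom.height_mm
        world_spacing[col_ax] = geom.width_mm
        if max(geom.width_mm, geom.height_mm) > geom.depth_mm + 1e-12:
            raise ValueError("in-plane spacing must not exceed slice spacing")
        vol = truth
        if misalignment_mm and plane in misalignment_mm:
            # the acquisition is shifted but the stack still *believes* it
            # sits at the nominal origin, emulating inter-plane misregistration
            shift = np.asarray(misalignment_mm[plane], float)
            vol = LabelVolume(truth.data, truth.spacing, truth.origin - shift)
        frac = _fraction_resample(vol, world_spacing)
        masks = np.moveaxis(frac >= 0.5, (slice_ax, row_ax, col_ax), (0, 1, 2))
        if masks.shape[0] == 0:
            raise ValueError(f"{plane}: zero slices produced")
        stacks[plane] = PlanarStack(
            plane=plane,
            masks=masks,
            in_plane_spacing_mm=(geom.height_mm, geom.width_mm),
            slice_spacing_mm=geom.depth_mm,
            origin_mm=truth.origin.copy(),
        )
    return stacks


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass
class CohortConfig:
    """Synthetic longitudinal cohort layout and effect sizes.

    ``timepoints_per_tendon`` lists (horse, limb, n_timepoints).  Scores
    are drawn from ``score_marginals`` — integer counts (assigned exactly
    by a seeded permutation) or probabilities.  The imposed relation is a
    monotone effect of the combined score on the change in median
    thickness (``effect_mm`` per score unit, +1 = improvement modeled as
    thickening toward normal) plus Gaussian noise.
    """

    timepoints_per_tendon: list[tuple[int, str, int]] = dc_field(
        default_factory=lambda: [
            (1, "LF", 3),
            (2, "LF", 3),
            (2, "RF", 3),
            (3, "LF", 2),
            (3, "RF", 2),
            (4, "LF", 2),
            (4, "RF", 2),
            (5, "LF", 2),
            (5, "RF", 2),
            (6, "RF", 2),
        ]
    )
    score_marginals: dict | None = None  # e.g. {1: 3, 0: 4, -1: 2} or probs
    effect_mm: float = 0.8
    noise_mm: float = 0.35
    volume_effect_pct: float = 8.0
    volume_noise_pct: float = 4.0
    clinical_discordance: float = 0.15
    baseline_thickness_mm: tuple[float, float] = (3.5, 0.9)  # mean, sd
    baseline_volume_mm3: tuple[float, float] = (10576.0, 3698.0)
    high_field_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not self.timepoints_per_tendon:
            raise ValueError("cohort must contain at least one tendon")
        if max(n for _, _, n in self.timepoints_per_tendon) < 2:
            raise ValueError("at least one tendon needs >= 2 time points")


def generate_cohort(config: CohortConfig, seed: int):
    """Generate a longitudinal cohort table (one row per tendon per scan).

    Deterministic under a fixed seed.  Baseline rows carry empty scores;
    every later row carries the MRI and clinical change scores versus the
    previous scan, coded +1 (improved) / 0 (no change) / -1 (worse).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_trans = sum(n - 1 for _, _, n in config.timepoints_per_tendon)
    marg = config.score_marginals
    if marg is not None and all(
        float(v).is_integer() for v in marg.values()
    ) and sum(marg.values()) == n_trans:
        scores = np.concatenate(
            [np.full(int(c), s, dtype=int) for s, c in sorted(marg.items())]
        )
        rng.shuffle(scores)
    else:
        if marg is None:
            marg = {1: 1 / 3, 0: 1 / 3, -1: 1 / 3}
        keys = sorted(marg)
        p = np.asarray([marg[k] for k in keys], float)
        scores = rng.choice(keys, size=n_trans, p=p / p.sum())
    rows = []
    ti = 0
    for horse, limb, n_tp in config.timepoints_per_tendon:
        mu_t, sd_t = config.baseline_thickness_mm
        mu_v, sd_v = config.baseline_volume_mm3
        thickness = max(0.8, rng.normal(mu_t, sd_t))
        volume = max(1500.0, rng.normal(mu_v, sd_v))
        field = 1.5 if rng.random() < config.high_field_fraction else 0.27
        months = 0.0
        for tp in range(n_tp):
            if tp == 0:
                mri = clin = ""
            else:
                s = int(scores[ti])
                ti += 1
                mri = s
                clin = (
                    int(rng.choice([x for x in (-1, 0, 1) if x != s]))
                    if rng.random() < config.clinical_discordance
                    else s
                )
                thickness = max(
                    0.5,
                    thickness
                    + config.effect_mm * s
                    + rng.normal(0.0, config.noise_mm),
                )
                volume = max(
                    1000.0,
                    volume
                    * (
                        1.0
                        + (
                            config.volume_effect_pct * s
                            + rng.normal(0.0, config.volume_noise_pct)
                        )
                        / 100.0
                    ),
                )
                months += float(rng.integers(2, 11))
            rows.append(
                {
                    "horse": horse,
                    "limb": limb,
                    "time": "0" if tp == 0 else f"{months:g} M",
                    "median_thickness_mm": round(float(thickness), 2),
                    "volume_mm3": round(float(volume), 2),
                    "field_T": field,
                    "mri_score": mri,
                    "clinical_score": clin,
                }
            )
    return pd.DataFrame(rows)
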