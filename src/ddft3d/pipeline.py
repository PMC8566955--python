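"""End-to-end orchestration: phantom pair → parts → comparison → report.

The pipeline is deterministic: every stochastic stage takes an explicit
seed from the configuration (omitting the seed is a configuration error,
not silent nondeterminism), and a rerun with an identical configuration
reproduces an identical numeric report.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_stats import (
    build_transitions,
    concordance_counts,
    correlate_scores,
    summarize_outcome_groups,
)
from .imaging_io import VoxelGeometry, write_stl
from .longitudinal import change_exceeds, export_colormap, global_register, part_compare
from .morphometry import mesh_volume, thickness_map, thickness_summary
from .part_builder import CropPlanes, build_part
from .planar_segmentation import apply_signal_inclusion, extract_surface, interpolate_stack
from .synthetic_phantom import (
    ChangeField,
    CohortConfig,
    LesionSpec,
    PhantomParams,
    apply_lesion,
    generate_cohort,
    generate_tendon_phantom,
    sample_planar_stacks,
    simulate_followup,
)

log = logging.getLogger("ddft3d")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Full parameterization of a synthetic end-to-end run.

    Defaults mirror the pipeline's standard settings: wrap gap closing
    0.5 mm / smallest detail 1 mm, smoothing factor 0.7, registration
    threshold 5 mm with 100 iterations and a 90% subsample, and the
    ±1.5 mm change threshold.  The seed is mandatory.
    """

    seed: int = None  # type: ignore[assignment]
    phantom: dict = field(default_factory=dict)
    phantom_spacing_mm: float = 0.3
    lesions: list = field(default_factory=list)
    change: dict = field(
        default_factory=lambda: {
            "patches": [[[0.0, 2.0, 30.0], -2.0, 6.0]],
        }
    )
    in_plane_mm: float = 0.31
    slice_spacing_mm: float = 3.6
    reconstruct_spacing_mm: float = 0.31
    fusion_margin_mm: float | None = None  # default: slice spacing / 4
    gap_closing_mm: float = 0.5
    smallest_detail_mm: float = 1.0
    smooth_factor: float = 0.7
    intersect_pitch_mm: float = 0.31
    crop: dict | None = None
    registration_threshold_mm: float = 5.0
    registration_iterations: int = 100
    registration_subsample: float = 0.90
    change_threshold_mm: float = 1.5
    thickness_max_vertices: int = 6000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("pipeline config requires an explicit seed")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name):
    """Log a stage banner with timing; re-raise failures stage-named."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def reconstruct_part(truth_binary, config: PipelineConfig, crop: CropPlanes | None):
    """Tri-planar sampling → per-plane reconstruction → fused refined part."""
    geoms = {
        p: VoxelGeometry(config.in_plane_mm, config.in_plane_mm, config.slice_spacing_mm)
        for p in ("sagittal", "axial", "dorsal")
    }
    stacks = sample_planar_stacks(truth_binary, geoms)
    margin = config.fusion_margin_mm
    if margin is None:
        margin = config.slice_spacing_mm / 4.0
    meshes = {}
    for plane, stack in stacks.items():
        vol = interpolate_stack(
            stack, config.reconstruct_spacing_mm, slice_axis_margin_mm=margin
        )
        meshes[plane] = extract_surface(vol)
    part = build_part(
        meshes["sagittal"],
        meshes["axial"],
        meshes["dorsal"],
        crop=crop,
        gap_closing_mm=config.gap_closing_mm,
        smallest_detail_mm=config.smallest_detail_mm,
        smooth_factor=config.smooth_factor,
        intersect_pitch_mm=config.intersect_pitch_mm,
    )
    return part, meshes


def _measure(part, config: PipelineConfig, rng: np.random.Generator) -> dict:
    n = len(part.mesh.vertices)
    mask = None
    if n > config.thickness_max_vertices:
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=config.thickness_max_vertices, replace=False)] = True
    tmap = thickness_map(part, vertex_mask=mask)
    tmin, tmed, tmax = thickness_summary(tmap)
    return {
        "volume_mm3": round(mesh_volume(part), 2),
        "thickness_min_mm": round(tmin, 3),
        "thickness_median_mm": round(tmed, 3),
        "thickness_max_mm": round(tmax, 3),
        "n_vertices": n,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic study and write the artifact bundle.

    Outputs (STL parts, PLY color map, CSV tables, JSON report and run
    manifest) land in ``outdir``; the returned dict is the stats report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    report: dict = {"version": __version__, "seed": config.seed}
    rng = np.random.default_rng(config.seed)

    with _stage("simulate"):
        params = PhantomParams(**config.phantom)
        baseline = generate_tendon_phantom(params, config.phantom_spacing_mm)
        for spec in config.lesions:
            baseline = apply_lesion(baseline, LesionSpec(**spec))
        change = ChangeField(
            patches=[(tuple(c), a, s) for c, a, s in config.change.get("patches", [])],
            uniform_mm=config.change.get("uniform_mm", 0.0),
        )
        followup = simulate_followup(baseline, change, seed=config.seed)

    with _stage("reconstruct"):
        crop = None
        if config.crop is not None:
            crop = CropPlanes(**{k: np.asarray(v, float) for k, v in config.crop.items()})
        truth0 = apply_signal_inclusion(baseline.labels)
        truth1 = apply_signal_inclusion(followup.labels)
        part0, _ = reconstruct_part(truth0, config, crop)
        part1, _ = reconstruct_part(truth1, config, crop)
        write_stl(part0.mesh, outdir / "baseline_part.stl")
        write_stl(part1.mesh, outdir / "followup_part.stl")
        report["dice_baseline_vs_truth"] = _dice_vs_truth(part0, truth0, config)

    with _stage("measure"):
        report["baseline"] = _measure(part0, config, rng)
        report["followup"] = _measure(part1, config, rng)
        report["delta_volume_pct"] = round(
            100.0
            * (report["followup"]["volume_mm3"] - report["baseline"]["volume_mm3"])
            / report["baseline"]["volume_mm3"],
            2,
        )

    with _stage("compare"):
        reg = global_register(
            part1,
            part0,
            distance_threshold_mm=config.registration_threshold_mm,
            iterations=config.registration_iterations,
            subsample_fraction=config.registration_subsample,
            seed=config.seed,
        )
        aligned = part1.mesh.copy()
        aligned.apply_transform(reg.transform.matrix)
        cmp_ = part_compare(aligned, part0)
        fired, extrema = change_exceeds(cmp_, config.change_threshold_mm)
        lo, med, hi = cmp_.summary
        report["comparison"] = {
            "min_mm": round(lo, 3),
            "median_mm": round(med, 3),
            "max_mm": round(hi, 3),
            "exceeds_threshold": fired,
            "threshold_mm": config.change_threshold_mm,
            "registration_rms_mm": round(reg.rms_history_mm[-1], 4),
            "registration_iterations": len(reg.rms_history_mm),
        }
        export_colormap(
            cmp_,
            (-config.change_threshold_mm, config.change_threshold_mm),
            mesh_path=outdir / "comparison.ply",
            csv_path=outdir / "comparison.csv",
            follow_up=aligned,
        )

    with _stage("report"):
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "outputs": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _dice_vs_truth(part, truth, config: PipelineConfig) -> float:
    from ._mesh import rasterize_mesh
    from .grid import LabelVolume

    recon = rasterize_mesh(part.mesh, truth.origin, truth.spacing, truth.data.shape)
    return round(LabelVolume(truth.data, truth.spacing, truth.origin).dice(recon), 4)


def run_cohort_stats(cohort_df, correlate: str = "delta_median_thickness_mm",
                     policy: str = "mri") -> dict:
    """Transition accounting and headline statistics for a cohort table."""
    transitions = build_transitions(cohort_df)
    out = {
        "n_transitions": len(transitions),
        "concordance": concordance_counts(transitions),
        "groups": summarize_outcome_groups(transitions, policy=policy),
    }
    try:
        corr = correlate_scores(transitions, column=correlate)
        out["correlation"] = {"column": correlate, "r": round(corr.r, 4),
                              "p": round(corr.p, 4), "n": corr.n}
    except ValueError as exc:
        out["correlation"] = {"column": correlate, "error": str(exc)}
    return out


def demo_cohort(seed: int):
    """Synthetic cohort mirroring the example-study layout."""
    return generate_cohort(CohortConfig(), seed=seed)
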