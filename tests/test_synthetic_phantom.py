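import numpy as np
import pytest

from ddft3d import (
    ChangeField,
    CohortConfig,
    LesionSpec,
    PhantomParams,
    VoxelGeometry,
    apply_lesion,
    generate_cohort,
    generate_tendon_phantom,
    sample_planar_stacks,
    simulate_followup,
)
from ddft3d.grid import LabelVolume
from ddft3d.synthetic_phantom import HYPERINTENSE, TendonPhantom

from conftest import make_cylinder_volume


class TestPhantomGeneration:
    def test_default_volume_in_equine_range(self, default_phantom):
        """Default phantom volume falls in the observed tendon-volume span."""
        v = default_phantom.occupancy.occupied_volume_mm3()
        assert 5000 <= v <= 17000
        assert abs(default_phantom.surface.volume - v) / v < 0.02

    def test_surface_is_watertight(self, default_phantom):
        assert default_phantom.surface.is_watertight

    def test_degenerate_length_raises(self):
        with pytest.raises(ValueError):
            PhantomParams(length_mm=0)

    def test_sheet_thinner_than_lobes_enforced(self):
        with pytest.raises(ValueError):
            PhantomParams(distal_sheet_thickness_mm=12.1, proximal_lobe_radius_mm=6.0)

    def test_same_seed_identical_grids(self):
        a = generate_tendon_phantom(PhantomParams(roughness_mm=0.2, rng_seed=5), 0.6)
        b = generate_tendon_phantom(PhantomParams(roughness_mm=0.2, rng_seed=5), 0.6)
        assert np.array_equal(a.labels.data, b.labels.data)

    def test_different_seed_differs_with_roughness(self):
        a = generate_tendon_phantom(PhantomParams(roughness_mm=0.3, rng_seed=1), 0.6)
        b = generate_tendon_phantom(PhantomParams(roughness_mm=0.3, rng_seed=2), 0.6)
        assert not np.array_equal(a.labels.data, b.labels.data)


class TestLesions:
    def test_core_lesion_voxel_count_matches_brute_force(self, coarse_phantom):
        """Ellipsoid rasterization equals a voxel-by-voxel oracle count."""
        lesion = LesionSpec("core", (0.0, 0.75, 14.0), (2.0, 2.0, 3.0))
        out = apply_lesion(coarse_phantom, lesion)
        count = int((out.labels.data == HYPERINTENSE).sum())
        # independent brute-force rasterization over the same grid
        vol = coarse_phantom.labels
        expected = 0
        for i in range(vol.shape[0]):
            x = vol.origin[0] + (i + 0.5) * vol.spacing[0]
            if abs(x) > 2.0:
                continue
            for j in range(vol.shape[1]):
                y = vol.origin[1] + (j + 0.5) * vol.spacing[1]
                for k in range(vol.shape[2]):
                    z = vol.origin[2] + (k + 0.5) * vol.spacing[2]
                    if (x / 2) ** 2 + ((y - 0.75) / 2) ** 2 + (
                        (z - 14) / 3
                    ) ** 2 <= 1 and vol.data[i, j, k]:
                        expected += 1
        assert count == expected
        assert expected > 0

    def test_zero_extent_lesion_is_noop(self, coarse_phantom):
        out = apply_lesion(coarse_phantom, LesionSpec("core", (0, 1, 14), (0, 0, 0)))
        assert np.array_equal(out.labels.data, coarse_phantom.labels.data)

    def test_core_lesion_reaching_surface_rejected(self, coarse_phantom):
        with pytest.raises(ValueError, match="rim"):
            apply_lesion(
                coarse_phantom, LesionSpec("core", (0.0, 0.0, 10.0), (9.0, 9.0, 9.0))
            )

    def test_surface_split_touches_background(self, coarse_phantom):
        from scipy import ndimage

        out = apply_lesion(
            coarse_phantom, LesionSpec("surface_split", (3.5, 8.0, 10.0), (1.5, 3.0, 3.0))
        )
        hyper = out.labels.data == HYPERINTENSE
        bg = out.labels.data == 0
        near = ndimage.binary_dilation(bg, ndimage.generate_binary_structure(3, 1))
        assert (hyper & near).any()


class TestFollowup:
    def test_zero_field_identical(self, coarse_phantom):
        out = simulate_followup(coarse_phantom, ChangeField(), seed=0)
        assert np.array_equal(out.labels.data, coarse_phantom.labels.data)

    def test_uniform_outward_growth_of_cylinder(self):
        """+1 mm uniform displacement turns a r=5 cylinder into r=6."""
        vol = make_cylinder_volume(5.0, 30.0, 0.25)
        phantom = TendonPhantom(
            LabelVolume((vol.data > 0).astype(np.uint8), vol.spacing, vol.origin),
            None,
        )
        out = simulate_followup(phantom, ChangeField(uniform_mm=1.0), seed=0)
        idx = np.argwhere(out.labels.data > 0)
        xy = np.hypot(
            vol.origin[0] + (idx[:, 0] + 0.5) * vol.spacing[0],
            vol.origin[1] + (idx[:, 1] + 0.5) * vol.spacing[1],
        )
        # mid-length slab to avoid the end caps
        z = vol.origin[2] + (idx[:, 2] + 0.5) * vol.spacing[2]
        mid = (z > 10) & (z < 20)
        assert np.abs(xy[mid].max() - 6.0) <= vol.spacing[0] + 1e-9

    def test_inverting_erosion_rejected(self):
        vol = make_cylinder_volume(5.0, 30.0, 0.4)
        phantom = TendonPhantom(
            LabelVolume((vol.data > 0).astype(np.uint8), vol.spacing, vol.origin),
            None,
        )
        with pytest.raises(ValueError, match="exceeds"):
            simulate_followup(phantom, ChangeField(uniform_mm=-10.0), seed=0)


class TestPlanarSampling:
    def test_slice_count_is_ceiling_of_extent_over_spacing(self):
        # 60 mm of extent at 3.6 mm between slices -> 17 slices
        occ = np.ones((40, 40, 200), dtype=bool)
        vol = LabelVolume(occ, (0.5, 0.5, 0.3), (0, 0, 0))
        geom = VoxelGeometry(0.5, 0.5, 3.6)
        stack = sample_planar_stacks(vol, {"axial": geom})["axial"]
        assert stack.n_slices == 17

    def test_isotropic_sphere_disk_areas(self):
        """Near-isotropic sampling of a sphere reproduces circle areas."""
        sp = 0.1
        r = 8.0
        shape = (180, 180, 180)
        origin = np.array([-9.0, -9.0, -9.0])
        xs = origin[0] + (np.arange(180) + 0.5) * sp
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        occ = gx**2 + gy**2 + gz**2 <= r**2
        vol = LabelVolume(occ, np.full(3, sp), origin)
        geom = VoxelGeometry(0.31, 0.31, 0.31)
        stack = sample_planar_stacks(vol, {"axial": geom})["axial"]
        for s in range(stack.n_slices):
            z = origin[2] + (s + 0.5) * 0.31
            if abs(z) > 0.8 * r:
                continue
            analytic = np.pi * (r**2 - z**2)
            measured = stack.masks[s].sum() * 0.31**2
            assert measured == pytest.approx(analytic, rel=0.05)

    def test_all_background_volume_rejected(self):
        vol = LabelVolume(np.zeros((10, 10, 10), bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            sample_planar_stacks(vol, {"axial": VoxelGeometry(1, 1, 3)})

    def test_in_plane_spacing_must_not_exceed_slice_spacing(self):
        vol = LabelVolume(np.ones((10, 10, 10), bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            sample_planar_stacks(vol, {"axial": VoxelGeometry(4.0, 4.0, 3.0)})


class TestCohortGeneration:
    def test_row_count_matches_timepoints(self):
        cfg = CohortConfig()
        df = generate_cohort(cfg, seed=1)
        assert len(df) == sum(n for _, _, n in cfg.timepoints_per_tendon)

    def test_same_seed_identical_csv_bytes(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_cohort(CohortConfig(), seed=9).to_csv(a, index=False)
        generate_cohort(CohortConfig(), seed=9).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_exact_score_marginals_honored(self):
        cfg = CohortConfig(score_marginals={1: 3, 0: 4, -1: 2},
                           clinical_discordance=0.0)
        # default layout has 13 transitions; use a 9-transition layout
        cfg.timepoints_per_tendon = [(i, "LF", 2) for i in range(1, 10)]
        df = generate_cohort(cfg, seed=4)
        scored = df["mri_score"][df["mri_score"] != ""]
        counts = scored.value_counts().to_dict()
        assert counts == {1: 3, 0: 4, -1: 2}

    def test_baseline_rows_unscored(self):
        df = generate_cohort(CohortConfig(), seed=2)
        firsts = df.groupby(["horse", "limb"]).head(1)
        assert (firsts["mri_score"] == "").all()

    def test_single_timepoint_everywhere_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(timepoints_per_tendon=[(1, "LF", 1)])
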