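import numpy as np
import pytest
import trimesh

from ddft3d import PhantomParams, generate_tendon_phantom
from ddft3d.grid import LabelVolume


@pytest.fixture(scope="session")
def default_phantom():
    """Default tendon phantom at the generator's standard grid."""
    return generate_tendon_phantom(PhantomParams(), spacing_mm=0.3)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Coarser phantom for mesh-heavy tests (registration, thickness)."""
    return generate_tendon_phantom(PhantomParams(), spacing_mm=0.6)


@pytest.fixture(scope="session")
def light_mesh():
    """Low-resolution phantom surface for registration tests."""
    return generate_tendon_phantom(PhantomParams(), spacing_mm=1.0).surface


def make_cylinder_volume(radius_mm, length_mm, spacing_mm, pad_mm=2.0):
    """Axis-aligned solid cylinder along z as a LabelVolume."""
    lo = np.array([-radius_mm - pad_mm, -radius_mm - pad_mm, -pad_mm])
    n = np.ceil(
        (2 * (radius_mm + pad_mm), 2 * (radius_mm + pad_mm), length_mm + 2 * pad_mm)
    ) / spacing_mm
    shape = tuple(int(v) for v in np.ceil(n))
    xs = lo[0] + (np.arange(shape[0]) + 0.5) * spacing_mm
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * spacing_mm
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * spacing_mm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    disk = gx**2 + gy**2 <= radius_mm**2
    inz = (zs >= 0) & (zs <= length_mm)
    occ = disk[:, :, None] & inz[None, None, :]
    return LabelVolume(occ, np.full(3, float(spacing_mm)), lo)


def sphere_with_hole(radius_mm=10.0, hole_radius_mm=0.2, subdivisions=5):
    """Icosphere with a small polar hole (diameter ~2x hole_radius)."""
    s = trimesh.creation.icosphere(subdivisions, radius_mm)
    d = np.linalg.norm(s.vertices - [0, 0, radius_mm], axis=1)
    drop = (d[s.faces] < hole_radius_mm).any(axis=1)
    assert drop.any(), "hole construction removed no faces"
    return trimesh.Trimesh(s.vertices, s.faces[~drop], process=False)
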