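import numpy as np
import pytest

import somascope as sc


@pytest.fixture(scope="session")
def sphere_phantom():
    """One centred sphere, r = 5 μm, anisotropic 1×1×2 μm voxels, noise-free."""
    spec = sc.PhantomSpec(
        shape_um=(40.0, 40.0, 40.0),
        voxel_size_um=(1.0, 1.0, 2.0),
        centres_um=[(20.0, 20.0, 20.0)],
        n_somas=None,
        radius_dist=((5.0, 5.0, 5.0), 0.0),
        noise_sigma=0.0,
        soma_intensity=200.0,
        background_intensity=10.0,
        seed=0,
    )
    return sc.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """15 well-separated jittered ellipsoids with mild noise."""
    spec = sc.PhantomSpec(
        shape_um=(100.0, 100.0, 100.0),
        n_somas=15,
        min_separation_um=16.0,
        noise_sigma=5.0,
        seed=42,
    )
    return sc.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_detections(small_phantom):
    stack, _ = small_phantom
    return sc.locate_somas(stack)


def binary_ball_stack(
    radius_um=5.0,
    voxel_size_um=(1.0, 1.0, 1.0),
    extent_um=24.0,
    intensity=200.0,
    background=0.0,
):
    """Hard-thresholded ball (no partial volume): exact uniform intensity."""
    from somascope.stack import ImageStack3D, grid_shape_for_extent

    shape = grid_shape_for_extent((extent_um,) * 3, voxel_size_um)
    nz, ny, nx = shape
    vx, vy, vz = voxel_size_um
    c = extent_um / 2
    zz = (np.arange(nz) * vz - c) ** 2
    yy = (np.arange(ny) * vy - c) ** 2
    xx = (np.arange(nx) * vx - c) ** 2
    d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    img = np.where(d2 <= radius_um**2, intensity, background).astype(np.float64)
    return ImageStack3D(img, voxel_size_um), (c, c, c)
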