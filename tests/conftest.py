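import numpy as np
import pytest

from scarmap.boundaries import classify_boundaries
from scarmap.laplace import solve_laplace
from scarmap.phantom import PhantomSpec, make_phantom, make_slab_phantom

COARSE = (1.5, 1.5, 1.5)  # fast unit-test resolution; wall still 6+ voxels thick


@pytest.fixture(scope="session")
def annulus():
    """Coarse annulus phantom with a half-transmural scar sector."""
    spec = PhantomSpec(shape="annulus", spacing=COARSE, noise_sigma=0.02, seed=1)
    seg, img, truth = make_phantom(spec)
    return spec, seg, img, truth


@pytest.fixture(scope="session")
def annulus_field(annulus):
    _, seg, _, _ = annulus
    bc = classify_boundaries(seg)
    return bc, solve_laplace(seg, bc)


@pytest.fixture(scope="session")
def annulus_radii(annulus):
    """Voxel-centre radius grid of the annulus phantom."""
    _, seg, _, _ = annulus
    xs, ys = seg.axis_coords(0), seg.axis_coords(1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return np.hypot(X, Y)[:, :, None] * np.ones(seg.shape[2])


@pytest.fixture(scope="session")
def slab():
    """Flat 10 mm wall slab (no scar), linear wall coordinate."""
    return make_slab_phantom(wall_thickness=10.0, spacing=0.5)


@pytest.fixture(scope="session")
def slab_full_scar():
    return make_slab_phantom(wall_thickness=10.0, spacing=0.25, ny=8, nz=8, full_scar=True)
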