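import numpy as np
import pytest

from shapeasym import TriangleMesh, make_sphere_mesh

# derandomized hypothesis runs so the suite is reproducible
try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def unit_cube_mesh() -> TriangleMesh:
    """Axis-aligned unit cube, 12 triangles, outward-wound."""
    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    # faces per cube side, outward orientation
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0 (normal -x)
            [4, 6, 7], [4, 7, 5],  # x = 1 (+x)
            [0, 4, 5], [0, 5, 1],  # y = 0 (-y)
            [2, 3, 7], [2, 7, 6],  # y = 1 (+y)
            [0, 2, 6], [0, 6, 4],  # z = 0 (-z)
            [1, 5, 7], [1, 7, 3],  # z = 1 (+z)
        ]
    )
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def cube():
    return unit_cube_mesh()


@pytest.fixture(scope="session")
def icosahedron():
    return make_sphere_mesh(radius=1.0, subdivisions=0)


@pytest.fixture(scope="session")
def icosphere3():
    return make_sphere_mesh(radius=1.0, subdivisions=3)


@pytest.fixture(scope="session")
def icosphere4():
    return make_sphere_mesh(radius=1.0, subdivisions=4)


def random_blob_mask(grid: int, seed: int) -> np.ndarray:
    """Random smooth solid blob mask with a 3-voxel clear border, 6-connected."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = rng.standard_normal((grid, grid, grid))
    field = ndimage.gaussian_filter(field, sigma=grid / 6.0)
    # bias toward the centre so the blob is one compact component
    ax = np.arange(grid) - (grid - 1) / 2.0
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    dist2 = (ii**2 + jj**2 + kk**2) / (grid / 3.0) ** 2
    score = field * 0.4 + (1.0 - dist2)
    mask = score > 0.35
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, lab, range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(mask, iterations=2)
    mask = ndimage.binary_fill_holes(mask)  # no interior cavities
    mask[:3] = mask[-3:] = False
    mask[:, :3] = mask[:, -3:] = False
    mask[:, :, :3] = mask[:, :, -3:] = False
    return mask
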