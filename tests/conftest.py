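import numpy as np
import pytest

from efdangio import build_icosphere


@pytest.fixture(scope="session")
def mesh0():
    return build_icosphere(0)


@pytest.fixture(scope="session")
def mesh2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh5():
    return build_icosphere(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def voronoi_props(mesh) -> np.ndarray:
    """Exact solid-angle fraction of each facet's nearest-centroid assignment
    region (the spherical Voronoi cell of its centroid)."""
    from scipy.spatial import SphericalVoronoi

    sv = SphericalVoronoi(np.asarray(mesh.facet_centroids))
    areas = sv.calculate_areas()
    return areas / areas.sum()


def random_rotation(gen) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(gen.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
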