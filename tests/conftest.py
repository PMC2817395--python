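import numpy as np
import pytest

from osafrec import build_basis, make_phantom, octahedral_rotations


@pytest.fixture(scope="session")
def basis16():
    return build_basis(16)


@pytest.fixture(scope="session")
def basis24():
    return build_basis(24)


@pytest.fixture(scope="session")
def rotations():
    return octahedral_rotations()


@pytest.fixture(scope="session")
def phantom32():
    """Small octahedral phantom for fast pipeline tests."""
    return make_phantom(n=32, voxel=2.0, n_blobs=2, blob_sigma=3.0, seed=1)


@pytest.fixture()
def unit_sphere_points():
    rng = np.random.default_rng(1234)
    v = rng.normal(size=(100, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def angles_of(v):
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    return theta, phi
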