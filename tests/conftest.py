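import numpy as np
import pytest

from radionet import FeatureVolume, VoxelTable, build_voxel_table
from radionet.phantom import (
    Background,
    Ellipsoid,
    PhantomSpec,
    TissueClass,
    default_spec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down two-tissue phantom that runs in a couple of seconds."""
    n = 12
    j = np.arange(n, dtype=float)
    baseline = 50.0 + 10.0 * np.sin(j)
    contrast = 12.0 * np.where(j % 2 == 0, 1.0, -1.0)
    axis = 15.0 * np.sin(2.1 * j + 0.5)
    sds = np.full(n, 2.0)
    healthy = TissueClass(
        "healthy", Background(), baseline, sds, gradient=axis - 0.3 * contrast
    )
    tumor = TissueClass(
        "tumor",
        Ellipsoid(center=(11.5, 11.5, 2.5), radii=(8.0, 7.0, 8.0)),
        baseline + contrast,
        sds,
        gradient=-0.9 * axis - 0.8 * contrast,
        make_interface=True,
    )
    return PhantomSpec(
        grid_shape=(24, 24, 6),
        voxel_spacing=(1.0, 1.0, 2.0),
        n_features=n,
        tissue_classes=[healthy, tumor],
        interface_width=1,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_table(small_phantom):
    volume, _ = small_phantom
    return build_voxel_table(volume)


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical 64x64x8 / 21-feature phantom at seed 42 (slow-ish)."""
    return generate_phantom(default_spec(seed=42))


@pytest.fixture
def tiny_volume():
    """4x4x2 volume with 3 deterministic features."""
    rng = np.random.default_rng(0)
    data = rng.normal(size=(4, 4, 2, 3))
    return FeatureVolume(
        data=data, spacing=(1.0, 1.0, 1.0), feature_names=["a", "b", "c"]
    )


def two_blob_table(n_per_blob=60, n_features=5, separation=12.0, seed=0):
    """Two well-separated Gaussian blobs as a VoxelTable; membership is the
    first-half / second-half split."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_blob, n_features))
    b = rng.normal(separation, 1.0, size=(n_per_blob, n_features))
    features = np.vstack([a, b])
    n = features.shape[0]
    coords = np.column_stack(
        [np.arange(n), np.zeros(n, dtype=int), np.zeros(n, dtype=int)]
    )
    return VoxelTable(
        coords=coords,
        features=features,
        feature_names=[f"f{i}" for i in range(n_features)],
        grid_shape=(n, 1, 1),
        spacing=(1.0, 1.0, 1.0),
        affine=np.eye(4),
    )


@pytest.fixture
def blob_table():
    return two_blob_table()
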