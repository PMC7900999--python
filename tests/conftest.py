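import numpy as np
import pytest

from tracermc.geometry import (
    GeometrySpec,
    SimplicialMesh,
    build_embedding_box,
    build_surrogate_hierarchy,
)


@pytest.fixture(scope="session")
def hier2d():
    """Default-resolution 3-level 2D surrogate hierarchy."""
    return build_surrogate_hierarchy(GeometrySpec(dimension=2, n_levels=3))


@pytest.fixture(scope="session")
def box2d(hier2d):
    return build_embedding_box(hier2d)


@pytest.fixture(scope="session")
def hier3d():
    """Coarse 2-level 3D surrogate (kept small: used for geometry checks)."""
    return build_surrogate_hierarchy(
        GeometrySpec(dimension=3, n_levels=2, base_resolution=0.02)
    )


@pytest.fixture
def two_triangle_mesh():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    cells = np.array([[0, 1, 2], [1, 3, 2]])
    return SimplicialMesh(
        pts,
        cells,
        np.zeros(2, dtype=np.int64),
        np.empty((0, 2), dtype=np.int64),
        np.empty(0, dtype=np.int64),
    )
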