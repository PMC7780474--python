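import numpy as np
import pandas as pd
import pytest

from morphopatch import Configuration, TriMesh
from morphopatch.fixtures import PyramidSpec, make_pyramid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def box_mesh():
    """Unit cube centered at the origin, 12 triangles."""
    import trimesh

    b = trimesh.creation.box()
    return TriMesh(np.asarray(b.vertices, float), np.asarray(b.faces))


@pytest.fixture(scope="session")
def pyramid():
    """Small plain pyramid fixture: (mesh, config, curves)."""
    return make_pyramid(PyramidSpec(mesh_resolution=600))


@pytest.fixture(scope="session")
def fossa_pyramid():
    spec = PyramidSpec(base_depth=1.2, height=1.3,
                       fossa=(0, (0.5, 0.27), 0.1), mesh_resolution=1500)
    return make_pyramid(spec)


@pytest.fixture(scope="session")
def hemisphere_atlas():
    from morphopatch.fixtures import make_hemisphere_template

    return make_hemisphere_template(radius=1.0, target_faces=800,
                                    surface_grid=(3, 6), n_curve_points=5)


def make_landmark_config(specimen_id: str, coords: np.ndarray) -> Configuration:
    coords = np.asarray(coords, float)
    df = pd.DataFrame({
        "label": [f"p{i}" for i in range(len(coords))],
        "class": "landmark",
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    })
    return Configuration(specimen_id, df)


@pytest.fixture()
def landmark_config_factory():
    return make_landmark_config
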