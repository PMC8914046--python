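import numpy as np
import pytest
import trimesh

from rvstrain import Mesh
from rvstrain.synthetic import MeshCycleParams, generate_mesh_cycle


@pytest.fixture(scope="session")
def cube_mesh() -> Mesh:
    """Axis-aligned cube, side 10 mm (area 600 mm^2, volume 1 mL)."""
    box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
    return Mesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def icosphere4() -> Mesh:
    """Icosphere, 4 subdivisions, radius 10 mm."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return Mesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def default_cycle():
    """Default synthetic RV cycle (circ scale 0.90, long scale 0.85) + ground truth."""
    return generate_mesh_cycle(MeshCycleParams())


@pytest.fixture(scope="session")
def uniform_cycle():
    """Uniform end-systolic scaling 0.9 of the RV-like shape + ground truth."""
    params = MeshCycleParams(circumferential_scale_es=0.9, longitudinal_scale_es=0.9)
    return generate_mesh_cycle(params)


def random_rotation(seed: int) -> np.ndarray:
    """A deterministic proper rotation matrix."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
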