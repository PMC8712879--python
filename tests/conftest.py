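"""Shared fixtures: meshes and torso built once per session."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from crtpredict import anatomy as an


@pytest.fixture(scope="session")
def ventricle_mesh():
    """Default biventricular anatomy at the standard 4 mm resolution."""
    return an.build_ventricles(edge_length=4.0)


@pytest.fixture(scope="session")
def lesioned_mesh():
    """Anatomy with the septal mid-wall fibrosis example plus an apical scar."""
    mesh = an.build_ventricles(edge_length=4.0)
    spec = an.LesionSpec({(s, 1): "fibrosis" for s in (2, 3, 8, 9)}
                         | {(13, 0): "scar", (13, 1): "scar"})
    return an.apply_lesions(mesh, spec)


@pytest.fixture(scope="session")
def torso():
    return an.default_torso()


def _random_tet_mesh(n_nodes: int, seed: int) -> an.VentricularMesh:
    """Small irregular tetrahedral mesh with random (unit-norm) fibers."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 30, size=(n_nodes, 3))
    tri = Delaunay(pts, qhull_options="QJ Pp")
    tets = tri.simplices
    p = pts[tets]
    vols = np.abs(np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                            np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))) / 6
    keep = vols > 1e-6
    tets, vols = tets[keep], vols[keep]
    m = len(tets)
    fiber = rng.normal(size=(m, 3))
    fiber /= np.linalg.norm(fiber, axis=1, keepdims=True)
    return an.VentricularMesh(
        nodes=pts, tets=tets, element_volume=vols,
        wall_label=rng.integers(0, 3, m).astype(np.int32),
        wall_label_node=rng.integers(0, 3, n_nodes).astype(np.int32),
        layer_label=rng.integers(0, 3, m).astype(np.int32),
        aha_segment=rng.integers(1, 18, m).astype(np.int32),
        tissue_class=np.zeros(m, dtype=np.int32),
        fiber=fiber, depth=np.full(m, 0.5),
        endo_surface_LV=np.array([], dtype=np.int64),
        endo_surface_RV=np.array([], dtype=np.int64),
        edge_length=5.0, shape=None)


@pytest.fixture(scope="session")
def random_mesh_200():
    return _random_tet_mesh(200, seed=7)


@pytest.fixture(scope="session")
def slab_2mm():
    """Homogeneous anisotropic slab, fibers along x, 2 mm edges."""
    return an.build_slab(size=(40.0, 40.0, 20.0), edge_length=2.0,
                         fiber_dir=(1, 0, 0))
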