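import numpy as np
import pytest

from kneereg import _raster
from kneereg.geometry import Mesh, make_biplanar_rig
from kneereg.synthetic import make_phantom_mesh, make_scene


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba kernels once so timings inside tests are stable."""
    _raster.warmup()


@pytest.fixture(scope="session")
def rig():
    return make_biplanar_rig()


@pytest.fixture(scope="session")
def femoral_mesh():
    return make_phantom_mesh("femoral_like", seed=1)


@pytest.fixture(scope="session")
def tibial_mesh():
    return make_phantom_mesh("tibial_like", seed=1)


@pytest.fixture(scope="session")
def unit_tetrahedron():
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return Mesh(vertices=v, faces=f)


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, clutter-free femoral scene: silhouette on flat background."""
    return make_scene("femoral_like", seed=11, noise_sigma=0.0, n_clutter=0)


@pytest.fixture(scope="session")
def cluttered_scene():
    """Default study conditions: clutter and noise on."""
    return make_scene("femoral_like", seed=12)


def random_rigid(rng, rot=20.0, trans=20.0):
    from kneereg.geometry import RigidTransform

    p = np.concatenate(
        [rng.uniform(-rot, rot, 3), rng.uniform(-trans, trans, 3)]
    )
    return RigidTransform.from_array(p)
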