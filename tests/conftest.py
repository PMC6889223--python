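import numpy as np
import pytest

from morphowarp import semilandmarks, synthetic_faces


@pytest.fixture(scope="session")
def base_face():
    """A small neutral synthetic face shared across the suite."""
    spec = synthetic_faces.SynthSpec(seed=11, mesh_resolution=900)
    return synthetic_faces.make_base_face(spec)


@pytest.fixture(scope="session")
def small_template(base_face):
    """A reduced template (16 anchors + 40 semi-landmarks) for fast tests."""
    mesh, anchors = base_face
    return semilandmarks.build_template(mesh, anchors, n_semi=40, min_spacing=1.5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """A uniform-ish proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
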