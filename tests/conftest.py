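import numpy as np
import pytest

from skullmorph.datatypes import LandmarkConfiguration, LandmarkDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle_pair():
    """Two distinct 2-D triangles, centred, unit centroid size."""
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.9]])
    b = np.array([[0.0, 0.1], [1.1, 0.0], [0.5, 1.2]])

    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt(np.sum(x**2))

    return norm(a), norm(b)


def make_dataset(shapes, ids=None, species=None, sex=None, part="cranium"):
    """Stack a list/array of complete k x d coordinate arrays into a dataset."""
    n = len(shapes)
    ids = ids or [f"s{i}" for i in range(n)]
    species = species or ["unknown"] * n
    sex = sex or ["unknown"] * n
    return LandmarkDataset(
        [
            LandmarkConfiguration(
                specimen_id=ids[i],
                coords=np.asarray(shapes[i], dtype=float),
                species=species[i],
                sex=sex[i],
                part=part,
            )
            for i in range(n)
        ]
    )


def random_rotation(d, rng):
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
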