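import numpy as np
import pytest

from dwifov.core_io import DWIStudy, GradientTable
from dwifov.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One 32³ noisy phantom case: (study, structural, brain, tensors)."""
    spec = PhantomSpec(shape=(32, 32, 32), n_weighted=4, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless 32³ phantom for analytic signal checks."""
    spec = PhantomSpec(shape=(32, 32, 32), n_weighted=4, seed=7,
                       sigma=0.0, structural_sigma=0.0)
    return generate_phantom(spec)


def random_study(rng, shape=(8, 8, 8), n_b0=1, n_weighted=3,
                 bval=1300.0) -> DWIStudy:
    """A geometry-valid study with uniform-random intensities."""
    v = n_b0 + n_weighted
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_weighted, bval)])
    vecs = rng.normal(size=(n_weighted, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    bvecs = np.concatenate([np.zeros((n_b0, 3)), vecs])
    data = rng.uniform(0, 1, size=shape + (v,)).astype(np.float32)
    return DWIStudy(data, GradientTable(bvals, bvecs),
                    (1.0, 1.0, 1.0), np.eye(4))
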