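import numpy as np
import pytest

from octquant.mpp import MPPParams
from octquant.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One 256x256x12 phantom with 15 CSR-placed particles at default speckle."""
    return generate_phantom(PhantomParams(seed=42))


@pytest.fixture(scope="session")
def clean_phantom():
    """Nearly noise-free phantom (very high gamma shape) for exact-geometry checks."""
    return generate_phantom(PhantomParams(seed=7, speckle_shape=1e6))


@pytest.fixture()
def mpp_params():
    return MPPParams(seed=0)


def vitreous_roi(phantom, z, clearance=2):
    """Boolean ROI strictly above the ground-truth surface of slice z."""
    H = phantom.params.height_px
    return np.arange(H)[:, None] < (phantom.gt_surface[z][None, :] - clearance)


@pytest.fixture(scope="session")
def small_instance_factory():
    """Seeded 64x64 images with a handful of planted bright blobs, plus a
    deterministic <=12-candidate pool — the brute-force oracle regime."""
    from octquant.mpp import candidate_data_terms

    def make(seed, params=None):
        params = params or MPPParams(seed=seed, grid_stride=4)
        rng = np.random.default_rng(seed)
        img = rng.gamma(30, 1 / 30, (64, 64)) * 0.1
        for _ in range(int(rng.integers(4, 7))):
            r, c = rng.integers(8, 56, 2)
            h, w = rng.integers(3, 7, 2)
            img[r : r + h, c : c + w] = 0.9 * rng.gamma(30, 1 / 30, (h, w))
        rects, energies = candidate_data_terms(img, params)
        order = np.argsort(energies, kind="stable")[:12]
        cands = [rects[i] for i in sorted(order)]
        return img, cands, params

    return make
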