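import numpy as np
import pytest

import freqness as fn
from freqness.datamodel import FrequencyGrid, NarrowbandDataset, VoxelDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 voxels, 10 s at 100 Hz of mildly correlated noise."""
    mixing = rng.standard_normal((20, 6))
    latents = rng.standard_normal((6, 1000))
    data = mixing @ latents + 0.5 * rng.standard_normal((20, 1000))
    return VoxelDataset(data=data, sampling_rate=100.0)


@pytest.fixture
def small_grid():
    centers = np.array([4.0, 8.0, 12.0, 16.0, 20.0])
    fwhms = np.array([fn.fwhm_schedule(c) for c in centers])
    return FrequencyGrid(centers=centers, fwhms=fwhms, stimulation_frequency=4.0)


def make_narrow(dataset, center=10.0, fwhm=1.0):
    kernel = fn.design_gaussian_kernel(center, fwhm, dataset.n_samples, dataset.sampling_rate)
    return fn.narrowband_filter(dataset, kernel)


@pytest.fixture(scope="session")
def _recovery_cache():
    return {}


@pytest.fixture
def recovery(request, _recovery_cache):
    if "result" not in _recovery_cache:
        spec = fn.default_two_network_spec(seed=7)
        dataset, truth = fn.simulate_dataset(spec)
        grid = fn.build_frequency_grid(nyquist=dataset.nyquist)
        landscape = fn.scan_frequencies(dataset, grid, n_keep=10)
        _recovery_cache["result"] = (spec, dataset, truth, grid, landscape)
    return _recovery_cache["result"]
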