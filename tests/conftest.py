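import numpy as np
import pytest

from rrnclust import imaging, synth


@pytest.fixture
def config():
    return imaging.ImagingConfig()


@pytest.fixture
def small_mu_sim():
    """One small Mu experiment reused across binning/normalization tests."""
    params = synth.MuSimParams(n_insertions=20_000, n_replicates=3,
                               reads_per_replicate=500_000, seed=7)
    sim, truth = synth.simulate_mu_insertions(params)
    return params, sim, truth


def gaussian_spot(shape, center, amplitude=100.0, sigma=2.0):
    """Render a single Gaussian spot; the unique-maximum test image."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center
    return amplitude * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2)
                              / (2 * sigma**2))
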