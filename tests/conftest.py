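import pytest

from crowdspot import SynthConfig, WorkerModel, simulate_crowd, simulate_image
from crowdspot.records import spot_coords


@pytest.fixture(scope="session")
def snr15_image():
    """256x256 image with 30 well-separated SNR-15 spots and its truth."""
    cfg = SynthConfig(n_spots=30, snr_mean=15.0, sigma=1.5, min_nnd=15.0, seed=42)
    image, truth = simulate_image(cfg, 256, 256)
    return image, truth


@pytest.fixture(scope="session")
def noiseless_spots_image():
    """Spots rendered on a flat zero-noise background (for exact fits)."""
    cfg = SynthConfig(
        n_spots=6, snr_mean=100.0, sigma=2.0, min_nnd=30.0, noise_std=0.0, seed=5
    )
    return simulate_image(cfg, 192, 192)


@pytest.fixture(scope="session")
def small_crowd(snr15_image):
    """25 default-model workers annotating the SNR-15 fixture."""
    image, truth = snr15_image
    model = WorkerModel(seed=7)
    return simulate_crowd(truth, image.shape[1], image.shape[0], model, 25), truth


def truth_xy(truth):
    return spot_coords(truth)
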