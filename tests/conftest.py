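import numpy as np
import pytest

from sheeprr import SyntheticSpec, generate_breathing_video


@pytest.fixture(scope="session")
def rgb_scene():
    """Reference RGB-stage scene: 27 bpm, 20 fps, 30 s, default noise."""
    spec = SyntheticSpec(rr_bpm=27.0, fps=20.0, duration_s=30.0, seed=1, modality="rgb")
    frames, mask, truth = generate_breathing_video(spec)
    return spec, frames, mask, truth


@pytest.fixture(scope="session")
def nir_scene():
    """NIR-stage scene: 24 bpm, 10 fps, 25 s, default (higher) noise."""
    spec = SyntheticSpec(rr_bpm=24.0, fps=10.0, duration_s=25.0, seed=7, modality="nir")
    frames, mask, truth = generate_breathing_video(spec)
    return spec, frames, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(40, 60), n_seeds=4):
    """A random connected-ish blob mask for partition/IoU property tests."""
    from scipy.ndimage import gaussian_filter

    field = rng.normal(size=shape)
    field = gaussian_filter(field, sigma=5)
    mask = field > np.quantile(field, 0.7)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask
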