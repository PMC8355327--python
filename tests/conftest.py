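import numpy as np
import pytest

from tubulekit.contour import ContourTimeSeries
from tubulekit.simulate import RenderConfig, render_video


@pytest.fixture(scope="session")
def straight_tubule_frame():
    """One noiseless 48x48 frame of a horizontal tubule at y = 20.3 px,
    x from 8 to 40, PSF sigma 1.5 px, peak 100 over background 10."""
    pix = 0.104
    coords = np.array([[[8.0, 20.3], [40.0, 20.3]]]) * pix
    series = ContourTimeSeries.from_coordinates(coords, times=[0.0])
    cfg = RenderConfig(pixel_size=pix, psf_sigma=1.5, image_shape=(48, 48), seed=0)
    video, truth = render_video(series, cfg)
    return video[0], 20.3, cfg


@pytest.fixture(scope="session")
def noisy_tubule_video():
    """30-frame noisy video of the same static tubule (Gaussian noise SD 3)."""
    pix = 0.104
    coords = np.repeat(np.array([[[8.0, 20.3], [40.0, 20.3]]]), 30, axis=0) * pix
    series = ContourTimeSeries.from_coordinates(coords, times=np.arange(30) * 0.03)
    cfg = RenderConfig(
        pixel_size=pix, psf_sigma=1.5, image_shape=(48, 48), gaussian_noise=3.0, seed=1
    )
    video, truth = render_video(series, cfg)
    return video, 20.3, cfg
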