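import numpy as np
import pytest

import cometkit as ck
from cometkit.synthetic import CometParams


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy synthetic dataset (fast; shared across tests)."""
    return ck.generate_dataset(n_images=2, comets_per_image=(6, 10), seed=42)


@pytest.fixture(scope="session")
def noiseless_truth():
    """One noiseless small image with ground truth."""
    return ck.generate_dataset(n_images=1, comets_per_image=(8, 12),
                               noise={"gaussian_sd": 0.0}, seed=5)[0]


@pytest.fixture
def single_comet():
    """An isolated comet (tail fraction 0.5) as an analysis-ready image."""
    params = CometParams(center=(0.0, 0.0), head_radius=12, head_peak=180,
                         tail_length=60, tail_fraction=0.5, orientation=0.5)
    patch, comet_m, head_m = ck.render_comet(params, amplitude_cap=240)
    pixels = np.clip(np.rint(patch + 12), 0, 255).astype(np.uint8)
    image = ck.IntensityImage(pixels, stain_mode="fluorescent", bit_depth=8)
    return params, image, comet_m, head_m


def roi_around(mask, pad=6.0):
    """Circle ROI covering a boolean mask (as a user would draw it)."""
    rr, cc = np.nonzero(mask)
    ctr = (rr.mean(), cc.mean())
    radius = float(np.hypot(rr - ctr[0], cc - ctr[1]).max() + pad)
    return ck.Roi("circle", center=ctr, radius=radius)
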