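"""Shared fixtures: rendered synthetic images reused across test modules."""

import numpy as np
import pytest

import nucmech as nm

SEED = 0


@pytest.fixture(scope="session")
def ellipsoid_nucleus():
    """Noise-free rendered ellipsoidal nucleus (a=8, b=5, c=3 µm, 30°)."""
    spec = nm.SyntheticNucleusSpec(
        semi_axis_a=8.0, semi_axis_b=5.0, semi_axis_c=3.0,
        orientation_deg=30.0, intensity_per_um=100.0, seed=SEED)
    image, truth = nm.render_nucleus_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def segmented_nucleus(ellipsoid_nucleus):
    _, image, _ = ellipsoid_nucleus
    return nm.segment_nucleus(image)


@pytest.fixture(scope="session")
def uniform_disc():
    """Flat disc of intensity 100 on zero background, radius 60 px."""
    shape = (161, 161)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (rows - 80) ** 2 + (cols - 80) ** 2 <= 60 ** 2
    image = nm.CalibratedImage(np.where(mask, 100.0, 0.0), 0.32)
    return image, mask
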