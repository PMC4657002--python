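import numpy as np
import pytest

from fascicle3d import position_lines as pl
from fascicle3d.synthetic_histology import (
    StackConfig,
    generate_stack,
    generate_template_windows,
)


@pytest.fixture(scope="session")
def template_set():
    """Clean template windows for detector training."""
    return generate_template_windows(150, 150, seed=3)


@pytest.fixture(scope="session")
def detector(template_set):
    windows, labels = template_set
    return pl.train_detector(windows, labels)


@pytest.fixture(scope="session")
def small_stack():
    """6 sections, 3 fascicles, no events, mild misalignment."""
    cfg = StackConfig(
        n_sections=6, image_size=(480, 640), n_fascicles_initial=3,
        rng_seed=9, misalignment_scale=3.0,
    )
    return generate_stack(cfg)


@pytest.fixture(scope="session")
def flat_stack():
    """Single perfectly aligned section used for typing tests."""
    cfg = StackConfig(
        n_sections=1, image_size=(480, 640), n_fascicles_initial=3,
        rng_seed=5, misalignment_scale=0.0,
    )
    return generate_stack(cfg)


def make_granular_disk(density=0.09, seed=0, radius=60, size=200, intensity=60.0):
    """Granular-texture disk on a light background, with the true circle known."""
    rng = np.random.default_rng(seed)
    center = size / 2.0
    img = np.full((size, size), 236.0)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    d = np.hypot(yy - center, xx - center)
    mask = d <= radius
    candidates = np.argwhere(d <= radius + 2)
    idx = rng.integers(0, len(candidates), size=int(density * mask.sum()))
    for i in idx:
        r, c = candidates[i]
        rad = rng.uniform(1, 2.1)
        sel = ((yy - r) ** 2 + (xx - c) ** 2 <= rad * rad) & mask
        img[sel] = intensity + rng.normal(0, 8)
    return img, (center, center), radius


def make_clean_disk(radius=60, size=200, intensity=60.0):
    center = size / 2.0
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    d = np.hypot(yy - center, xx - center)
    return np.where(d <= radius, intensity, 236.0), (center, center), radius


@pytest.fixture(scope="session")
def granular_disk():
    return make_granular_disk()


@pytest.fixture(scope="session")
def clean_disk():
    return make_clean_disk()
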