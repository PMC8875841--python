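"""Shared fixtures: small phantoms and geometries, generated at test time."""

import numpy as np
import pytest

from limitedct import (ImageSlice, PhantomSpec, Sinogram, ViewMask,
                       generate_volume, radon_forward, uniform_angles)


def antialiased_disk(n: int, radius: float, value: float = 1.0,
                     ss: int = 8) -> np.ndarray:
    """A centered uniform disk rasterized with ss x ss supersampling, so its
    projections are close to the analytic chord-length profile."""
    m = n * ss
    c = (m - 1) / 2.0
    yy, xx = np.ogrid[:m, :m]
    d = ((xx - c) ** 2 + (yy - c) ** 2) <= (radius * ss) ** 2
    return value * d.reshape(n, ss, n, ss).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def disk64():
    return antialiased_disk(64, 20.0, value=0.8)


@pytest.fixture(scope="session")
def disk_sinogram(disk64):
    return radon_forward(ImageSlice(disk64), uniform_angles(180))


@pytest.fixture(scope="session")
def phantom64():
    """One slice of a randomized ellipse phantom."""
    return generate_volume(PhantomSpec(image_size=64, n_slices=1, seed=42))[0]


@pytest.fixture(scope="session")
def phantom_sinogram(phantom64):
    return radon_forward(ImageSlice(phantom64), uniform_angles(180))


@pytest.fixture(scope="session")
def cut_post_60():
    return ViewMask("cut_post", 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
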