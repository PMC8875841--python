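"""Synthetic spatially-coherent slice stacks and their simulated sinograms.

Volumes are randomized ellipse phantoms (Shepp-Logan-like): a soft-tissue
body ellipse plus a handful of internal ellipses with random centers, axes,
orientations and intensities, rasterized with supersampling so projections
match analytic line integrals closely. Along the slice axis every ellipse
parameter performs a smooth bounded random walk scaled by ``z_drift``, which
makes adjacent slices strongly correlated — the structural assumption the
spatial restoration stage exploits — with the correlation strength
controllable and measurable.

``generate_dataset`` mirrors a parallel-beam acquisition: forward-project
each slice on the full angle grid, drop the masked views, complete by FBP
reprojection, and keep every intermediate needed to train and evaluate the
three stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (ImageSlice, Sinogram, ViewMask, apply_view_mask,
                       fbp_reconstruct, radon_forward, uniform_angles)
from .preprocess import merge_radon

__all__ = ["PhantomSpec", "generate_volume", "generate_dataset",
           "TINY", "PAPER_GEOMETRY"]


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic volume.

    ``z_drift`` is the per-slice standard deviation of the random walk on
    ellipse centers/axes (in units of the body radius) and orientations
    (radians); 0 makes all slices identical.
    """

    image_size: int = 128
    n_slices: int = 16
    n_views: int = 180
    n_bins: int = None
    n_ellipses: tuple = (3, 6)
    intensity: tuple = (0.15, 0.5)
    z_drift: float = 0.01
    noise_std: float = 0.0
    seed: int = 0
    supersample: int = 4

    def __post_init__(self):
        if self.n_bins is None:
            self.n_bins = self.image_size


# Presets: the desk-scale default and the full acquisition geometry.
TINY = PhantomSpec(image_size=64, n_slices=8)
PAPER_GEOMETRY = PhantomSpec(image_size=512, n_slices=16, n_views=180,
                             n_bins=512)


def _raster_ellipses(n: int, ellipses, ss: int) -> np.ndarray:
    """Rasterize (cx, cy, a, b, phi, value) ellipses with ss x ss
    supersampling; coordinates in [-1, 1] over the image square."""
    m = n * ss
    coords = (np.arange(m) + 0.5) / m * 2.0 - 1.0
    x = coords[None, :]
    y = coords[:, None]
    img = np.zeros((m, m))
    for cx, cy, a, b, phi, val in ellipses:
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - cx) * c + (y - cy) * s
        yr = -(x - cx) * s + (y - cy) * c
        img += val * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return img.reshape(n, ss, n, ss).mean(axis=(1, 3))


def generate_volume(spec: PhantomSpec) -> np.ndarray:
    """A (n_slices, N, N) stack of phantoms in [0, 1], reproducible from
    ``spec.seed``."""
    lo, hi = spec.n_ellipses
    if hi <= 0 and spec.intensity[1] <= 0:
        raise ValueError("degenerate spec: no ellipses and no background")
    rng = np.random.default_rng(spec.seed)
    n_ell = int(rng.integers(lo, hi + 1))
    body = np.array([0.0, 0.0, 0.82, 0.74, rng.uniform(0, np.pi), 0.35])
    parts = [body]
    for _ in range(n_ell):
        r = rng.uniform(0, 0.5)
        ang = rng.uniform(0, 2 * np.pi)
        parts.append(np.array([
            r * np.cos(ang), r * np.sin(ang),
            rng.uniform(0.05, 0.3), rng.uniform(0.05, 0.3),
            rng.uniform(0, np.pi),
            rng.uniform(*spec.intensity),
        ]))
    params = np.stack(parts)                     # (E, 6)
    slices = []
    for _ in range(spec.n_slices):
        ells = [tuple(p) for p in params]
        slices.append(np.clip(_raster_ellipses(spec.image_size, ells,
                                               spec.supersample), 0.0, 1.0))
        if spec.z_drift > 0:
            step = rng.normal(0.0, spec.z_drift, size=params.shape)
            step[:, 5] *= 0.5                     # gentler intensity drift
            step[0, :2] = 0.0                     # body stays centered
            params = params + step
            params[:, 2:4] = np.clip(params[:, 2:4], 0.03, 0.9)
            params[:, 5] = np.clip(params[:, 5], 0.05, 0.9)
        else:
            # consume the same random stream so z_drift only changes
            # geometry, not the ellipse layout of later volumes
            rng.normal(0.0, 1.0, size=params.shape)
    return np.stack(slices)


@dataclass
class SliceRecord:
    """All per-slice arrays the pipeline stages need."""

    ground_truth: np.ndarray
    full_sinogram: np.ndarray
    limited_sinogram: np.ndarray
    merged_sinogram: np.ndarray
    fbp_limited: np.ndarray
    fbp_merged: np.ndarray


@dataclass
class Dataset:
    volumes: list            # list of list[SliceRecord]
    mask: ViewMask
    angles: np.ndarray
    manifest: dict
    split: dict = field(default_factory=dict)


def generate_dataset(spec: PhantomSpec, mask: ViewMask, n_volumes: int = 5,
                     split_ratio: tuple = (1, 1, 3)) -> Dataset:
    """Paired limited-view data for ``n_volumes`` phantom volumes.

    Per slice: ground-truth image, full sinogram, limited sinogram, merged
    (FBP-reprojection-completed) sinogram and the FBP images of the limited
    and merged data. Volumes are split train:val:test by the given ratio
    (default 1:1:3) in volume order.
    """
    if mask.n_full != spec.n_views:
        raise ValueError("mask grid does not match spec.n_views")
    angles = uniform_angles(spec.n_views)
    volumes = []
    seeds = []
    rng = np.random.default_rng(spec.seed)
    for v in range(n_volumes):
        vol_seed = int(rng.integers(2 ** 31))
        seeds.append(vol_seed)
        vspec = PhantomSpec(spec.image_size, spec.n_slices, spec.n_views,
                            spec.n_bins, spec.n_ellipses, spec.intensity,
                            spec.z_drift, spec.noise_std, vol_seed,
                            spec.supersample)
        stack = generate_volume(vspec)
        records = []
        for sl in stack:
            img = ImageSlice(sl)
            full = radon_forward(img, angles, n_bins=spec.n_bins)
            if spec.noise_std > 0:
                noisy = full.values + rng.normal(
                    0.0, spec.noise_std, size=full.values.shape)
                full = Sinogram(noisy, angles)
            limited = apply_view_mask(full, mask)
            merged = merge_radon(limited, mask, spec.image_size)
            fbp_lim = fbp_reconstruct(limited, spec.image_size)
            fbp_mrg = fbp_reconstruct(merged.sinogram, spec.image_size)
            records.append(SliceRecord(
                ground_truth=sl,
                full_sinogram=full.values,
                limited_sinogram=limited.values,
                merged_sinogram=merged.values,
                fbp_limited=np.clip(fbp_lim.pixels, 0.0, 1.0),
                fbp_merged=np.clip(fbp_mrg.pixels, 0.0, 1.0)))
        volumes.append(records)
    total = sum(split_ratio)
    n_train = max(1, round(n_volumes * split_ratio[0] / total)) \
        if n_volumes >= 3 else n_volumes
    n_val = max(1, round(n_volumes * split_ratio[1] / total)) \
        if n_volumes >= 3 else 0
    n_train = min(n_train, n_volumes)
    n_val = min(n_val, n_volumes - n_train)
    split = {"train": list(range(n_train)),
             "val": list(range(n_train, n_train + n_val)),
             "test": list(range(n_train + n_val, n_volumes))}
    manifest = {"seed": spec.seed, "volume_seeds": seeds,
                "image_size": spec.image_size, "n_views": spec.n_views,
                "n_bins": spec.n_bins, "scheme": mask.scheme,
                "n_missing": mask.n_missing, "split_ratio": list(split_ratio)}
    return Dataset(volumes, mask, angles, manifest, split)
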