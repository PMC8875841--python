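"""Parallel-beam projection geometry: Radon transform, FBP, view masking.

The forward projector is pixel-driven: each pixel's value is splatted onto the
two nearest detector bins with linear weights, so the unfiltered back
projector implemented with the same weights is the exact adjoint (transpose)
of the forward operator. Filtered back projection applies the standard
discrete ramp kernel in the frequency domain before back projecting.

Conventions
-----------
* View angles are degrees, uniform on [0, 180); view i sits at
  ``i * 180 / n_views``.
* The detector has ``n_bins`` unit-width bins centered on the image center;
  by default one bin spans one pixel width.
* Sinograms are ``(n_views, n_bins)`` arrays of line integrals in pixel-length
  units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import fft, ifft

__all__ = [
    "Sinogram", "ImageSlice", "ViewMask",
    "uniform_angles", "radon_forward", "back_project", "fbp_reconstruct",
    "apply_view_mask", "insert_views", "fov_mask",
    "save_sinogram", "load_sinogram", "save_volume", "load_volume",
    "read_dicom_slice",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Sinogram:
    """Projection data: one row of line integrals per view angle.

    ``role`` tags where the data sits in the completion workflow:
    ``"full"`` (ground truth), ``"limited"`` (measured subset, Rlv),
    ``"reprojected"`` (Rfv) or ``"merged"`` (Rmerge).
    """

    values: np.ndarray
    angles: np.ndarray
    role: str = "full"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2D (n_views, n_bins)")
        if len(self.angles) != self.values.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} views but {len(self.angles)} angles")
        if len(self.angles) > 1:
            d = np.diff(self.angles)
            if not np.all(d > 0):
                raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class ImageSlice:
    """A single reconstructed or ground-truth slice (H x W, attenuation)."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ViewMask:
    """Which projection views of the full angle grid are measured.

    ``cut_post`` removes the trailing contiguous block of views;
    ``cut_mid`` removes a contiguous block centered at ``n_full // 2``
    (ties resolved toward the lower index).
    """

    scheme: str
    n_missing: int
    n_full: int = 180
    measured_indices: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.scheme not in ("cut_post", "cut_mid"):
            raise ValueError(f"unknown masking scheme {self.scheme!r}")
        if not (0 <= self.n_missing <= self.n_full):
            raise ValueError("n_missing out of range")
        if self.measured_indices is None:
            if self.scheme == "cut_post":
                missing = np.arange(self.n_full - self.n_missing, self.n_full)
            else:
                start = self.n_full // 2 - self.n_missing // 2
                missing = np.arange(start, start + self.n_missing)
            keep = np.setdiff1d(np.arange(self.n_full), missing)
            self.measured_indices = keep
        self.measured_indices = np.asarray(self.measured_indices, dtype=int)
        if len(self.measured_indices) + self.n_missing != self.n_full:
            raise ValueError("measured_indices inconsistent with n_missing")

    @property
    def missing_indices(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_full), self.measured_indices)

    @property
    def measured_bool(self) -> np.ndarray:
        m = np.zeros(self.n_full, dtype=bool)
        m[self.measured_indices] = True
        return m


def uniform_angles(n_views: int = 180) -> np.ndarray:
    """The default full-scan angle grid: ``n_views`` uniform on [0, 180)."""
    return np.arange(n_views) * (180.0 / n_views)


# ---------------------------------------------------------------------------
# Projection operators
# ---------------------------------------------------------------------------

def _splat_geometry(n: int, n_bins: int, angle_deg: float):
    """Linear splat indices/weights of every pixel onto the detector."""
    c = (n - 1) / 2.0
    xs = np.arange(n) - c
    theta = np.deg2rad(angle_deg)
    # t = x cos(theta) + y sin(theta), y axis pointing up (row 0 on top)
    t = (xs[None, :] * np.cos(theta) - xs[:, None] * np.sin(theta)).ravel()
    pos = t + (n_bins - 1) / 2.0
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    valid0 = (i0 >= 0) & (i0 < n_bins)
    valid1 = (i0 + 1 >= 0) & (i0 + 1 < n_bins)
    return i0, frac, valid0, valid1


def radon_forward(img: ImageSlice, angles: Sequence[float],
                  n_bins: int | None = None) -> Sinogram:
    """Forward-project an image into a sinogram (discrete Radon transform).

    Linear in the image; each view's bin-sum equals the image pixel sum
    (times the pixel size) for objects inside the detector's field of view.
    """
    if not isinstance(img, ImageSlice):
        img = ImageSlice(np.asarray(img))
    h, w = img.shape
    if h != w:
        raise ValueError(f"image must be square, got {h}x{w}")
    angles = np.asarray(angles, dtype=float)
    if n_bins is None:
        n_bins = w
    flat = img.pixels.ravel()
    sino = np.zeros((len(angles), n_bins))
    for k, ang in enumerate(angles):
        i0, frac, v0, v1 = _splat_geometry(w, n_bins, ang)
        row = np.bincount(i0[v0], weights=(flat * (1 - frac))[v0],
                          minlength=n_bins)
        row += np.bincount((i0 + 1)[v1], weights=(flat * frac)[v1],
                           minlength=n_bins)
        sino[k] = row
    return Sinogram(sino * img.pixel_size, angles)


def back_project(sino: Sinogram, out_size: int) -> ImageSlice:
    """Unfiltered back projection — the exact adjoint of ``radon_forward``."""
    img = np.zeros(out_size * out_size)
    for k, ang in enumerate(sino.angles):
        i0, frac, v0, v1 = _splat_geometry(out_size, sino.n_bins, ang)
        row = sino.values[k]
        contrib = np.zeros_like(img)
        contrib[v0] += row[i0[v0]] * (1 - frac[v0])
        contrib[v1] += row[(i0 + 1)[v1]] * frac[v1]
        img += contrib
    return ImageSlice(img.reshape(out_size, out_size))


def _ramp_filter(n: int, kind: str = "ramp") -> np.ndarray:
    """Frequency response of the discrete ramp kernel (length n, padded)."""
    # Real-space band-limited ramp (Kak & Slaney): f[0] = 1/4,
    # f[k] = -1 / (pi k)^2 for odd k, 0 for even k.
    f = np.zeros(n)
    f[0] = 0.25
    odd = np.arange(1, n // 2 + 1, 2)
    f[odd] = -1.0 / (np.pi * odd) ** 2
    f[-odd] = -1.0 / (np.pi * odd) ** 2
    resp = 2.0 * np.real(fft(f))
    if kind == "ramp":
        return resp
    freq = np.fft.fftfreq(n)
    if kind == "shepp-logan":
        omega = np.pi * freq
        window = np.ones(n)
        nz = omega != 0
        window[nz] = np.sin(omega[nz]) / omega[nz]
        return resp * window
    if kind == "hann":
        return resp * (0.5 + 0.5 * np.cos(2 * np.pi * freq))
    raise ValueError(f"unknown filter {kind!r}")


def fbp_reconstruct(sino: Sinogram, out_size: int,
                    filter_name: str = "ramp") -> ImageSlice:
    """Filtered back projection.

    With a limited set of views this produces the artifact-laden image the
    restoration stages consume; with the full grid it is an accurate
    analytic reconstruction inside the field of view.
    """
    if sino.n_views == 0:
        raise ValueError("cannot reconstruct from an empty angle set")
    n_bins = sino.n_bins
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n_bins))))
    resp = _ramp_filter(n_pad, filter_name)
    padded = np.zeros((sino.n_views, n_pad))
    padded[:, :n_bins] = sino.values
    filtered = np.real(ifft(fft(padded, axis=1) * resp[None, :], axis=1))
    filtered = filtered[:, :n_bins]
    bp = back_project(Sinogram(filtered, sino.angles, role=sino.role),
                      out_size)
    scale = np.pi / (2.0 * sino.n_views)
    return ImageSlice(bp.pixels * scale)


def fov_mask(n: int) -> np.ndarray:
    """Boolean mask of the inscribed circle (the region parallel-beam data
    with an n-bin detector actually determine)."""
    c = (n - 1) / 2.0
    y, x = np.ogrid[:n, :n]
    return (x - c) ** 2 + (y - c) ** 2 <= (n / 2.0) ** 2


# ---------------------------------------------------------------------------
# Limited-view masking
# ---------------------------------------------------------------------------

def apply_view_mask(full: Sinogram, mask: ViewMask) -> Sinogram:
    """Extract the measured views (Rlv) from a full sinogram.

    Retained rows are bit-identical to the corresponding rows of ``full``.
    """
    if full.n_views != mask.n_full:
        raise ValueError(
            f"mask expects {mask.n_full} views, sinogram has {full.n_views}")
    idx = mask.measured_indices
    return Sinogram(full.values[idx].copy(), full.angles[idx], role="limited")


def insert_views(limited: Sinogram, mask: ViewMask,
                 full_angles: np.ndarray,
                 fill: np.ndarray | float = 0.0) -> Sinogram:
    """Place measured rows back onto the full angle grid.

    Missing rows are taken from ``fill`` (a full-grid array or a constant).
    """
    if limited.n_views != len(mask.measured_indices):
        raise ValueError("limited sinogram inconsistent with mask")
    n_bins = limited.n_bins
    if np.isscalar(fill):
        grid = np.full((mask.n_full, n_bins), float(fill))
    else:
        grid = np.array(fill, dtype=float, copy=True)
        if grid.shape != (mask.n_full, n_bins):
            raise ValueError("fill array has wrong shape")
    grid[mask.measured_indices] = limited.values
    return Sinogram(grid, np.asarray(full_angles, dtype=float), role="merged")


# ---------------------------------------------------------------------------
# File I/O: one array container + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_sinogram(path, sino: Sinogram, mask: ViewMask | None = None):
    meta = {"angles": sino.angles.tolist(), "role": sino.role}
    if mask is not None:
        meta["mask"] = {"scheme": mask.scheme, "n_missing": mask.n_missing,
                        "n_full": mask.n_full}
    np.savez(path, values=sino.values, meta=json.dumps(meta))


def load_sinogram(path) -> tuple[Sinogram, ViewMask | None]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        sino = Sinogram(z["values"], np.array(meta["angles"]),
                        role=meta.get("role", "full"))
    mask = None
    if "mask" in meta:
        m = meta["mask"]
        mask = ViewMask(m["scheme"], m["n_missing"], m["n_full"])
    return sino, mask


def save_volume(path, slices: np.ndarray, meta: dict | None = None):
    np.savez(path, volume=np.asarray(slices, dtype=float),
             meta=json.dumps(meta or {}))


def load_volume(path) -> tuple[np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as z:
        return np.array(z["volume"]), json.loads(str(z["meta"]))


def save_slice_tiff(path, img: ImageSlice):
    """Write a normalized slice as 16-bit TIFF."""
    import tifffile

    arr = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))


def load_slice_tiff(path) -> ImageSlice:
    import tifffile

    arr = tifffile.imread(path).astype(float)
    return ImageSlice(arr / 65535.0)


def read_dicom_slice(path) -> ImageSlice:
    """Import a single DICOM slice (pixel data with rescale applied)."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return ImageSlice(arr * slope + intercept)
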