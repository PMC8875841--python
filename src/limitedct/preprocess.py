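"""Data completion and patch workflows around the restoration networks.

``merge_radon`` implements the limited-view completion step: reconstruct the
measured views with FBP, forward-project the reconstruction on the full angle
grid, and splice the reprojected rows into the missing block while keeping
every measured row bit-identical to the input. The merged sinogram (Rmerge)
is a strictly better starting point for learned completion than zero-filling.

Also here: min-max normalization with recorded inversion parameters, and the
four-patch crop/assemble operators used by the texture-refinement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (ImageSlice, Sinogram, ViewMask, fbp_reconstruct,
                       radon_forward, uniform_angles)

__all__ = [
    "MergedSinogram", "NormParams", "PatchSet",
    "merge_radon", "normalize", "denormalize",
    "crop_patches", "assemble_patches", "pad_views", "unpad_views",
]


@dataclass
class MergedSinogram:
    """A full-grid sinogram with per-view provenance.

    ``provenance_mask[k]`` is True where row k was measured (copied from the
    limited sinogram) and False where it was synthesized by reprojection.
    """

    sinogram: Sinogram
    provenance_mask: np.ndarray

    def __post_init__(self):
        self.provenance_mask = np.asarray(self.provenance_mask, dtype=bool)
        if len(self.provenance_mask) != self.sinogram.n_views:
            raise ValueError("provenance mask length mismatch")

    @property
    def values(self) -> np.ndarray:
        return self.sinogram.values


@dataclass
class NormParams:
    """Recorded affine range of a min-max normalization, for inversion."""

    vmin: float
    vmax: float
    degenerate: bool = False


@dataclass
class PatchSet:
    """Four half-size patches plus the metadata needed for exact reassembly."""

    patches: list
    layout: tuple = ("TL", "TR", "BL", "BR")
    flip_mode: str = "none"
    offsets: list = field(default=None)
    source_shape: tuple = None


# ---------------------------------------------------------------------------
# Sinogram completion
# ---------------------------------------------------------------------------

def merge_radon(rlv: Sinogram, mask: ViewMask, out_size: int,
                filter_name: str = "ramp") -> MergedSinogram:
    """Complete a limited-view sinogram by FBP reprojection.

    Steps: Irecon = FBP(rlv); Rfv = radon(Irecon) on the full grid; the
    output keeps rlv's rows where measured and takes Rfv's rows where
    missing. Deterministic; measured rows are copied verbatim.
    """
    if rlv.n_views != len(mask.measured_indices):
        raise ValueError(
            f"limited sinogram has {rlv.n_views} views, mask measures "
            f"{len(mask.measured_indices)}")
    full_angles = uniform_angles(mask.n_full)
    if not np.allclose(rlv.angles, full_angles[mask.measured_indices]):
        raise ValueError("limited sinogram angles do not match the mask")
    irecon = fbp_reconstruct(rlv, out_size, filter_name=filter_name)
    rfv = radon_forward(irecon, full_angles, n_bins=rlv.n_bins)
    merged = rfv.values.copy()
    merged[mask.measured_indices] = rlv.values
    sino = Sinogram(merged, full_angles, role="merged")
    return MergedSinogram(sino, mask.measured_bool)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(x: np.ndarray, mode: str = "minmax") -> tuple[np.ndarray, NormParams]:
    """Affine min-max map onto [0, 1] with recorded range.

    A constant input maps to all zeros and the range is flagged degenerate.
    Apply per volume (the default in the dataset generator) so consecutive
    slices share one intensity scale.
    """
    if mode != "minmax":
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot normalize non-finite data")
    vmin, vmax = float(x.min()), float(x.max())
    if vmax == vmin:
        return np.zeros_like(x), NormParams(vmin, vmax, degenerate=True)
    return (x - vmin) / (vmax - vmin), NormParams(vmin, vmax)


def denormalize(x: np.ndarray, params: NormParams) -> np.ndarray:
    if params.degenerate:
        return np.full_like(np.asarray(x, dtype=float), params.vmin)
    return np.asarray(x, dtype=float) * (params.vmax - params.vmin) + params.vmin


# ---------------------------------------------------------------------------
# View-axis padding (sinogram heights divisible by the network's pool depth)
# ---------------------------------------------------------------------------

def pad_views(values: np.ndarray, multiple: int = 16) -> tuple[np.ndarray, tuple]:
    """Zero-pad the view axis up to the next multiple, split evenly
    (extra row at the bottom). Returns the padded array and (top, bottom)."""
    n = values.shape[0]
    target = int(np.ceil(n / multiple) * multiple)
    top = (target - n) // 2
    bottom = target - n - top
    return np.pad(values, ((top, bottom), (0, 0))), (top, bottom)


def unpad_views(values: np.ndarray, pad: tuple) -> np.ndarray:
    top, bottom = pad
    stop = values.shape[0] - bottom
    return values[top:stop]


# ---------------------------------------------------------------------------
# Patch operators
# ---------------------------------------------------------------------------

_FLIPS = {"TL": (False, False), "TR": (False, True),
          "BL": (True, False), "BR": (True, True)}


def _flip(a: np.ndarray, fv: bool, fh: bool) -> np.ndarray:
    if fv:
        a = a[::-1, :]
    if fh:
        a = a[:, ::-1]
    return a


def crop_patches(img: ImageSlice, method: str = "corner",
                 seed: int | None = None) -> PatchSet:
    """Split an image into four half-size patches.

    * ``corner``: the four non-overlapping quadrants (TL, TR, BL, BR).
    * ``corner_flip``: quadrants flipped so all share the top-left
      orientation (TR mirrored horizontally, BL vertically, BR both).
    * ``random``: four patches at uniformly random offsets (seeded); not
      reassemblable.
    * ``none``: a single full-size "patch".
    """
    if not isinstance(img, ImageSlice):
        img = ImageSlice(np.asarray(img))
    h, w = img.shape
    if method == "none":
        return PatchSet([img.pixels.copy()], layout=("FULL",),
                        flip_mode="none", source_shape=(h, w))
    if h % 2 or w % 2:
        raise ValueError(f"image dimensions must be even, got {h}x{w}")
    hh, hw = h // 2, w // 2
    quads = {"TL": img.pixels[:hh, :hw], "TR": img.pixels[:hh, hw:],
             "BL": img.pixels[hh:, :hw], "BR": img.pixels[hh:, hw:]}
    if method == "corner":
        return PatchSet([quads[k].copy() for k in ("TL", "TR", "BL", "BR")],
                        flip_mode="none", source_shape=(h, w))
    if method == "corner_flip":
        patches = [_flip(quads[k], *_FLIPS[k]).copy()
                   for k in ("TL", "TR", "BL", "BR")]
        return PatchSet(patches, flip_mode="to_same_pattern",
                        source_shape=(h, w))
    if method == "random":
        rng = np.random.default_rng(seed)
        offs = [(int(rng.integers(0, h - hh + 1)),
                 int(rng.integers(0, w - hw + 1))) for _ in range(4)]
        patches = [img.pixels[r:r + hh, c:c + hw].copy() for r, c in offs]
        return PatchSet(patches, layout=("R0", "R1", "R2", "R3"),
                        flip_mode="none", offsets=offs, source_shape=(h, w))
    raise ValueError(f"unknown patch method {method!r}")


def assemble_patches(ps: PatchSet) -> ImageSlice:
    """Exact inverse of ``crop_patches`` for corner/corner_flip/none modes."""
    if ps.offsets is not None:
        raise ValueError("random-offset patch sets are not reassemblable")
    if ps.layout == ("FULL",):
        return ImageSlice(ps.patches[0].copy())
    h, w = ps.source_shape
    out = np.empty((h, w))
    hh, hw = h // 2, w // 2
    slots = {"TL": (slice(None, hh), slice(None, hw)),
             "TR": (slice(None, hh), slice(hw, None)),
             "BL": (slice(hh, None), slice(None, hw)),
             "BR": (slice(hh, None), slice(hw, None))}
    for key, patch in zip(ps.layout, ps.patches):
        if ps.flip_mode == "to_same_pattern":
            patch = _flip(patch, *_FLIPS[key])
        out[slots[key]] = patch
    return ImageSlice(out)
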