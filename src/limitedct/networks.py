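"""The three restoration architectures and their shared discriminator.

All three stages use the same fully convolutional encoder-decoder ("AE
block"): an encoder of double-conv blocks (each 3x3 conv + batch norm + ReLU
twice) where every 2x2 max pooling halves the spatial size and the next block
doubles the channel count, and a mirrored decoder of 2x2 transposed
convolutions with concatenative skip connections at equal resolution,
finished by a three-convolution head (base -> 12 -> 1 channels, final conv
linear). The default channel schedule is 32-64-128-256-512 over four
poolings, so inputs must have height and width divisible by 16.

* Stage one restores merged sinograms (1 input channel).
* Stage two ("spatial") runs a shared 3-channel AE block over the three
  overlapping triplets of a 5-slice stack and fuses their outputs with a
  second AE block: s_i'' = G2(concat(G1(S1), G1(S2), G1(S3))).
* Stage three ("refine") restores the four corner patches of an image with a
  single shared AE block and reassembles them.

The discriminator reuses the encoder but its deepest block has three conv
layers with output channels 512, 64 and 1; the final map goes through an
element-wise sigmoid and is averaged into one realness score per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor
from .geometry import ImageSlice
from .preprocess import PatchSet, assemble_patches, crop_patches

__all__ = [
    "NetPlan", "SliceStack", "Autoencoder", "Discriminator",
    "build_autoencoder", "build_discriminator",
    "spatial_forward", "refine_forward",
    "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass
class NetPlan:
    """Layer schedule of an AE block (and of the discriminator encoder).

    ``base_channels`` doubles at every pooling: with the defaults the
    encoder widths are 32-64-128-256-512. ``depth`` is the number of
    poolings, so valid inputs have H and W divisible by ``2**depth``.
    """

    in_channels: int = 1
    base_channels: int = 32
    depth: int = 4
    head_channels: int = 12

    @property
    def divisibility(self) -> int:
        return 2 ** self.depth

    def encoder_widths(self) -> list[int]:
        return [self.base_channels * 2 ** k for k in range(self.depth + 1)]

    def layer_table(self, h: int, w: int) -> list[tuple]:
        """Rows of (name, IC, OC, stride, in_size, out_size) for the
        autoencoder at input h x w."""
        rows = []
        widths = self.encoder_widths()
        ic = self.in_channels
        ch, cw = h, w
        for k, oc in enumerate(widths):
            rows.append((f"Block{k + 1}", ic, oc, 1, (ch, cw), (ch, cw)))
            if k < self.depth:
                rows.append((f"Pool{k + 1}", oc, oc, 2,
                             (ch, cw), (ch // 2, cw // 2)))
                ch, cw = ch // 2, cw // 2
            ic = oc
        for k in range(self.depth, 0, -1):
            oc = widths[k - 1]
            name = f"Up_Conv{2 * self.depth + 2 - k}"
            rows.append((name, widths[k], oc, 2, (ch, cw), (ch * 2, cw * 2)))
            ch, cw = ch * 2, cw * 2
            blk = 2 * self.depth + 2 - k
            if k > 1:
                rows.append((f"Block{blk}", 2 * oc, oc, 1, (ch, cw), (ch, cw)))
            else:
                rows.append((f"Conv{blk}_1", 2 * oc, oc, 1,
                             (ch, cw), (ch, cw)))
                rows.append((f"Conv{blk}_2", oc, self.head_channels, 1,
                             (ch, cw), (ch, cw)))
                rows.append((f"Conv{blk}_3", self.head_channels, 1, 1,
                             (ch, cw), (ch, cw)))
        return rows


@dataclass
class SliceStack:
    """Ordered consecutive slices sharing shape and normalization."""

    slices: np.ndarray
    center_index: int = None

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slice stack must be 3D (n_slices, H, W)")
        if self.center_index is None:
            self.center_index = self.slices.shape[0] // 2

    def __len__(self) -> int:
        return self.slices.shape[0]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, rng, ic, oc, k=3):
        fan_in = ic * k * k
        self.w = Parameter(ad.kaiming_uniform(rng, (oc, ic, k, k), fan_in))
        self.b = Parameter(np.zeros(oc))
        self.pad = k // 2

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _UpConv:
    def __init__(self, rng, ic, oc):
        self.w = Parameter(ad.kaiming_uniform(rng, (ic, oc, 2, 2), ic * 4))
        self.b = Parameter(np.zeros(oc))

    def __call__(self, x):
        return ad.conv_transpose2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    def __init__(self, c):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.state = {"running_mean": np.zeros(c), "running_var": np.ones(c)}

    def __call__(self, x, training):
        return ad.batchnorm2d(x, self.gamma, self.beta, self.state, training)

    def params(self):
        return [self.gamma, self.beta]


class _DoubleConv:
    """The building block: (3x3 conv + BN + ReLU) twice."""

    def __init__(self, rng, ic, oc):
        self.c1, self.n1 = _Conv(rng, ic, oc), _BatchNorm(oc)
        self.c2, self.n2 = _Conv(rng, oc, oc), _BatchNorm(oc)

    def __call__(self, x, training):
        x = ad.relu(self.n1(self.c1(x), training))
        return ad.relu(self.n2(self.c2(x), training))

    def params(self):
        return (self.c1.params() + self.n1.params()
                + self.c2.params() + self.n2.params())


class _Module:
    """Shared trainer plumbing: parameter list, mode flag, state dicts."""

    def __init__(self):
        self.training = False
        self._layers = []

    def parameters(self):
        ps = []
        for layer in self._layers:
            ps.extend(layer.params())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def state_arrays(self) -> dict:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        for i, layer in enumerate(self._layers):
            if isinstance(layer, _BatchNorm):
                out[f"bn{i}_mean"] = layer.state["running_mean"]
                out[f"bn{i}_var"] = layer.state["running_var"]
        return out

    def load_state_arrays(self, arrays: dict):
        for i, p in enumerate(self.parameters()):
            p.data = np.array(arrays[f"p{i}"], dtype=float)
        for i, layer in enumerate(self._layers):
            if isinstance(layer, _BatchNorm):
                layer.state["running_mean"] = np.array(arrays[f"bn{i}_mean"])
                layer.state["running_var"] = np.array(arrays[f"bn{i}_var"])


def _check_divisible(x: np.ndarray, div: int):
    h, w = x.shape[-2:]
    if h % div or w % div:
        raise ValueError(
            f"input spatial size {h}x{w} must be divisible by {div}")


class Autoencoder(_Module):
    """U-Net-style AE block built from a NetPlan."""

    def __init__(self, plan: NetPlan, seed: int = 0):
        super().__init__()
        self.plan = plan
        rng = np.random.default_rng(seed)
        widths = plan.encoder_widths()
        self.enc = []
        ic = plan.in_channels
        for oc in widths:
            blk = _DoubleConv(rng, ic, oc)
            self.enc.append(blk)
            ic = oc
        self.ups = []
        self.dec = []
        for k in range(plan.depth, 0, -1):
            oc = widths[k - 1]
            self.ups.append(_UpConv(rng, widths[k], oc))
            if k > 1:
                self.dec.append(_DoubleConv(rng, 2 * oc, oc))
        self.head1 = _Conv(rng, 2 * widths[0], widths[0])
        self.head1_bn = _BatchNorm(widths[0])
        self.head2 = _Conv(rng, widths[0], plan.head_channels)
        self.head2_bn = _BatchNorm(plan.head_channels)
        self.head3 = _Conv(rng, plan.head_channels, 1)
        self._layers = (self.enc + self.ups + self.dec
                        + [self.head1, self.head1_bn,
                           self.head2, self.head2_bn, self.head3])

    def forward(self, x, trace: list | None = None):
        """x: Tensor or array (N, C, H, W) -> Tensor (N, 1, H, W).

        If ``trace`` is a list it receives (name, shape) per activation.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        _check_divisible(x.data, self.plan.divisibility)

        def rec(name, t):
            if trace is not None:
                trace.append((name, t.data.shape))

        skips = []
        for k, blk in enumerate(self.enc):
            x = blk(x, self.training)
            rec(f"Block{k + 1}", x)
            if k < self.plan.depth:
                skips.append(x)
                x = ad.maxpool2d(x)
                rec(f"Pool{k + 1}", x)
        for j, up in enumerate(self.ups):
            x = up(x)
            rec(f"Up_Conv{self.plan.depth + 2 + j}", x)
            x = ad.concat_channels([skips[-1 - j], x])
            if j < len(self.dec):
                x = self.dec[j](x, self.training)
                rec(f"Block{self.plan.depth + 2 + j}", x)
        x = ad.relu(self.head1_bn(self.head1(x), self.training))
        rec(f"Conv{2 * self.plan.depth + 1}_1", x)
        x = ad.relu(self.head2_bn(self.head2(x), self.training))
        rec(f"Conv{2 * self.plan.depth + 1}_2", x)
        x = self.head3(x)
        rec(f"Conv{2 * self.plan.depth + 1}_3", x)
        return x

    __call__ = forward

    def restore(self, image: np.ndarray) -> np.ndarray:
        """Eval-mode convenience: (H, W) array in, (H, W) array out."""
        out = self.forward(image[None, None])
        return out.data[0, 0]


class Discriminator(_Module):
    """Encoder + 3-layer deep block + sigmoid-mean realness score."""

    def __init__(self, plan: NetPlan, seed: int = 0):
        super().__init__()
        self.plan = plan
        rng = np.random.default_rng(seed)
        widths = plan.encoder_widths()
        self.enc = []
        ic = plan.in_channels
        for oc in widths[:-1]:
            self.enc.append(_DoubleConv(rng, ic, oc))
            ic = oc
        deep = widths[-1]
        self.d1 = _Conv(rng, widths[-2], deep)
        self.d1_bn = _BatchNorm(deep)
        self.d2 = _Conv(rng, deep, 64 if deep >= 64 else deep)
        self.d2_bn = _BatchNorm(64 if deep >= 64 else deep)
        self.d3 = _Conv(rng, 64 if deep >= 64 else deep, 1)
        self._layers = (self.enc + [self.d1, self.d1_bn, self.d2,
                                    self.d2_bn, self.d3])

    def forward(self, x):
        """x: Tensor or array (N, C, H, W) -> Tensor (N,) of scores in (0,1)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        _check_divisible(x.data, self.plan.divisibility)
        for blk in self.enc:
            x = blk(x, self.training)
            x = ad.maxpool2d(x)
        x = ad.relu(self.d1_bn(self.d1(x), self.training))
        x = ad.relu(self.d2_bn(self.d2(x), self.training))
        x = self.d3(x)
        return ad.mean(ad.sigmoid(x), axis=(1, 2, 3))

    __call__ = forward


def build_autoencoder(plan: NetPlan, in_channels: int | None = None,
                      seed: int = 0) -> Autoencoder:
    if in_channels is not None and in_channels != plan.in_channels:
        plan = NetPlan(in_channels, plan.base_channels, plan.depth,
                       plan.head_channels)
    return Autoencoder(plan, seed=seed)


def build_discriminator(plan: NetPlan, seed: int = 0) -> Discriminator:
    return Discriminator(plan, seed=seed)


# ---------------------------------------------------------------------------
# Stage-two and stage-three compositions
# ---------------------------------------------------------------------------

def stack_triplets(stack: SliceStack) -> list[np.ndarray]:
    """The three overlapping triplets of a 5-slice stack, as 3-channel
    arrays: S1 = {s_{i-2}, s_{i-1}, s_i}, S2 = {s_{i-1}, s_i, s_{i+1}},
    S3 = {s_i, s_{i+1}, s_{i+2}}."""
    if len(stack) != 5:
        raise ValueError(f"spatial stage needs a 5-slice stack, got "
                         f"{len(stack)}")
    s = stack.slices
    return [s[0:3], s[1:4], s[2:5]]


def spatial_forward(stack: SliceStack, g1: Autoencoder,
                    g2: Autoencoder) -> ImageSlice:
    """Restore the center slice of a 5-stack with the two-step cascade.

    The first AE block (shared weights) maps each 3-slice triplet to one
    intermediate image; the second fuses the three intermediates:
    s_i'' = G2(concat(G1(S1), G1(S2), G1(S3))).
    """
    triplets = stack_triplets(stack)
    batch = np.stack(triplets)                     # (3, 3, H, W)
    inter = g1.forward(batch)                      # (3, 1, H, W)
    fused_in = inter.data.transpose(1, 0, 2, 3)    # (1, 3, H, W)
    out = g2.forward(fused_in)
    return ImageSlice(out.data[0, 0])


def refine_forward(img: ImageSlice, g: Autoencoder,
                   method: str = "corner") -> ImageSlice:
    """Patch-wise texture refinement: crop -> shared AE block -> reassemble."""
    if not isinstance(img, ImageSlice):
        img = ImageSlice(np.asarray(img))
    ps = crop_patches(img, method=method)
    batch = np.stack(ps.patches)[:, None]          # (4 or 1, 1, h, w)
    out = g.forward(batch)
    restored = PatchSet([out.data[i, 0] for i in range(out.data.shape[0])],
                        layout=ps.layout, flip_mode=ps.flip_mode,
                        offsets=ps.offsets, source_shape=ps.source_shape)
    return assemble_patches(restored)


# ---------------------------------------------------------------------------
# Checkpoints (self-describing: the plan travels with the weights)
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: _Module, extra: dict | None = None):
    plan = model.plan
    meta = {"kind": type(model).__name__,
            "plan": {"in_channels": plan.in_channels,
                     "base_channels": plan.base_channels,
                     "depth": plan.depth,
                     "head_channels": plan.head_channels},
            "extra": extra or {}}
    np.savez(path, meta=json.dumps(meta), **model.state_arrays())


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = {k: np.array(z[k]) for k in z.files if k != "meta"}
    plan = NetPlan(**meta["plan"])
    model = (Autoencoder(plan) if meta["kind"] == "Autoencoder"
             else Discriminator(plan))
    model.load_state_arrays(arrays)
    return model, meta["extra"]
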