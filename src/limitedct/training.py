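"""Loss functions and the per-stage adversarial training loops.

The autoencoder objective is a weighted sum of three terms,

    l_AE = a1 * l_MSE + a2 * l_Adv + a3 * l_Reg,

where l_MSE is the mean squared error against the ground truth, l_Adv =
1 - D(prediction) rewards fooling the discriminator, and l_Reg is a total
variation regularizer (mean forward-difference gradient magnitude, replicate
boundary, isotropic with a 1e-8 smoothing constant). Default weights are
(1, 1e-3, 2e-8). The discriminator minimizes

    l_Dis = (1 - D(ground truth)) + D(prediction),

bounded in [0, 2]. Both players are optimized with Adam at learning rate
1e-4 by default, alternating one discriminator step with one autoencoder
step per batch. All randomness flows from ``TrainConfig.seed``; identical
configurations reproduce bit-identical loss histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .networks import Autoencoder, Discriminator, NetPlan, build_autoencoder, \
    build_discriminator

__all__ = [
    "LossWeights", "TrainConfig",
    "loss_mse", "loss_adv", "loss_reg", "loss_ae", "loss_disc",
    "train_autoencoder", "train_stage", "TrainResult",
]

_TV_EPS = 1e-8


@dataclass
class LossWeights:
    alpha1: float = 1.0      # l_MSE
    alpha2: float = 1e-3     # l_Adv
    alpha3: float = 2e-8     # l_Reg


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 4
    max_steps: int = 200
    seed: int = 0
    d_steps_per_g_step: int = 1
    lr_decay_steps: int = 0   # 0 = constant learning rate
    lr_decay_factor: float = 0.5

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def _pair(pred, gt):
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    g = np.asarray(gt.data if isinstance(gt, Tensor) else gt, dtype=float)
    if p.data.shape != g.shape:
        raise ValueError(
            f"shape mismatch: prediction {p.data.shape} vs target {g.shape}")
    return p, g


def loss_mse(pred, gt):
    """Mean squared error (1/(W*H) per image; mean over any batch axes)."""
    p, g = _pair(pred, gt)
    return ad.mean(ad.square(p - g))


def loss_adv(pred, disc: Discriminator):
    """Adversarial term 1 - D(pred), averaged over the batch."""
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    return ad.mean(1.0 - disc.forward(p))


def loss_reg(pred):
    """Mean isotropic forward-difference gradient magnitude (TV loss)."""
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    dx = ad.forward_diff(p, axis=p.data.ndim - 1)
    dy = ad.forward_diff(p, axis=p.data.ndim - 2)
    mag = ad.sqrt(ad.square(dx) + ad.square(dy) + _TV_EPS)
    return ad.mean(mag)


def loss_ae(pred, gt, disc: Discriminator | None,
            w: LossWeights = LossWeights()):
    """The composite autoencoder objective."""
    total = ad.mul(loss_mse(pred, gt), w.alpha1)
    if disc is not None and w.alpha2 != 0.0:
        total = total + ad.mul(loss_adv(pred, disc), w.alpha2)
    if w.alpha3 != 0.0:
        total = total + ad.mul(loss_reg(pred), w.alpha3)
    return total


def loss_disc(gt, pred, disc: Discriminator):
    """Discriminator objective (1 - D(gt)) + D(pred), in [0, 2]."""
    g = gt if isinstance(gt, Tensor) else Tensor(gt)
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    return ad.mean(1.0 - disc.forward(g)) + ad.mean(disc.forward(p))


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: Autoencoder
    discriminator: Discriminator | None
    history: list      # dicts: step, l_mse, l_adv, l_reg, l_dis

    def history_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["step", "l_mse", "l_adv",
                                                "l_reg", "l_dis"])
            wr.writeheader()
            wr.writerows(self.history)


def train_autoencoder(inputs: np.ndarray, targets: np.ndarray,
                      plan: NetPlan, cfg: TrainConfig,
                      w: LossWeights = LossWeights(),
                      adversarial: bool = True) -> TrainResult:
    """Train one AE block on paired (input, target) tensors.

    ``inputs``/``targets``: (N, C, H, W) and (N, 1, H, W) arrays. One Adam
    step on the discriminator is followed by one on the autoencoder per
    batch (``d_steps_per_g_step`` controls the ratio; 0 disables the
    discriminator entirely). Aborts with ``RuntimeError`` on a non-finite
    loss, naming the step.
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError("inputs and targets differ in sample count")
    rng = np.random.default_rng(cfg.seed)
    gen = build_autoencoder(plan, seed=int(rng.integers(2 ** 31)))
    use_d = adversarial and cfg.d_steps_per_g_step > 0
    disc = None
    opt_d = None
    if use_d:
        dplan = NetPlan(1, plan.base_channels, plan.depth, plan.head_channels)
        disc = build_discriminator(dplan, seed=int(rng.integers(2 ** 31)))
        opt_d = Adam(disc.parameters(), lr=cfg.learning_rate)
    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate)
    n = inputs.shape[0]
    history = []
    gen.train()
    if disc is not None:
        disc.train()
    for step in range(cfg.max_steps):
        if cfg.lr_decay_steps and step and step % cfg.lr_decay_steps == 0:
            opt_g.lr *= cfg.lr_decay_factor
            if opt_d is not None:
                opt_d.lr *= cfg.lr_decay_factor
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        x, y = inputs[idx], targets[idx]
        l_dis_val = float("nan")
        if use_d:
            for _ in range(cfg.d_steps_per_g_step):
                pred = gen.forward(x).detach()
                opt_d.zero_grad()
                l_dis = loss_disc(y, pred, disc)
                l_dis.backward()
                opt_d.step()
                l_dis_val = l_dis.item()
        opt_g.zero_grad()
        pred = gen.forward(x)
        l_m = loss_mse(pred, y)
        total = ad.mul(l_m, w.alpha1)
        l_a_val = float("nan")
        if use_d:
            l_a = loss_adv(pred, disc)
            l_a_val = l_a.item()
            total = total + ad.mul(l_a, w.alpha2)
        l_r = loss_reg(pred)
        total = total + ad.mul(l_r, w.alpha3)
        if not np.isfinite(total.item()):
            raise RuntimeError(f"non-finite training loss at step {step}")
        total.backward()
        opt_g.step()
        history.append({"step": step, "l_mse": l_m.item(),
                        "l_adv": l_a_val, "l_reg": l_r.item(),
                        "l_dis": l_dis_val})
    gen.eval()
    if disc is not None:
        disc.eval()
    return TrainResult(gen, disc, history)


def _spatial_pairs(stacks: np.ndarray, targets: np.ndarray):
    """5-slice stacks -> triplet inputs and per-triplet center targets.

    Triplet S_k's training target is the ground truth of the common center
    slice s_i, so the shared first-step block learns triplet -> center.
    """
    trip_in, trip_gt = [], []
    for s, t in zip(stacks, targets):
        for lo in (0, 1, 2):
            trip_in.append(s[lo:lo + 3])
            trip_gt.append(t[None])
    return np.stack(trip_in), np.stack(trip_gt)


def train_stage(stage: str, data: dict, cfg: TrainConfig,
                w: LossWeights = LossWeights(),
                plan: NetPlan | None = None,
                adversarial: bool = True):
    """Train one pipeline stage; returns one TrainResult (two for spatial).

    * ``stage="radon"``: data has ``inputs`` (merged sinograms, padded to
      the network's divisibility) and ``targets`` (full sinograms), both
      (N, 1, H, W), normalized.
    * ``stage="spatial"``: data has ``stacks`` (N, 5, H, W) and ``targets``
      (N, H, W) center ground truths. The shared triplet block G1 is
      trained first (triplet -> center), then frozen while the fusion
      block G2 is trained on G1's concatenated outputs.
    * ``stage="refine"``: data has ``inputs``/``targets`` (N, 1, H, W)
      patch pairs (use ``preprocess.crop_patches`` to build them).
    """
    if stage == "radon" or stage == "refine":
        plan = plan or NetPlan(in_channels=1)
        return train_autoencoder(data["inputs"], data["targets"], plan,
                                 cfg, w, adversarial=adversarial)
    if stage == "spatial":
        plan1 = plan or NetPlan(in_channels=3)
        if plan1.in_channels != 3:
            plan1 = NetPlan(3, plan1.base_channels, plan1.depth,
                            plan1.head_channels)
        trip_in, trip_gt = _spatial_pairs(data["stacks"], data["targets"])
        res1 = train_autoencoder(trip_in, trip_gt, plan1, cfg, w,
                                 adversarial=adversarial)
        g1 = res1.model
        fused_in = []
        for s in data["stacks"]:
            trips = np.stack([s[0:3], s[1:4], s[2:5]])
            inter = g1.forward(trips).data            # (3, 1, H, W)
            fused_in.append(inter[:, 0])              # (3, H, W)
        fused_in = np.stack(fused_in)                 # (N, 3, H, W)
        plan2 = NetPlan(3, plan1.base_channels, plan1.depth,
                        plan1.head_channels)
        cfg2 = TrainConfig(cfg.learning_rate, cfg.optimizer, cfg.batch_size,
                           cfg.max_steps, cfg.seed + 1,
                           cfg.d_steps_per_g_step, cfg.lr_decay_steps,
                           cfg.lr_decay_factor)
        res2 = train_autoencoder(fused_in, data["targets"][:, None],
                                 plan2, cfg2, w, adversarial=adversarial)
        return res1, res2
    raise ValueError(f"unknown stage {stage!r}")
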