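"""The desk-scale reference study: train all three stages end to end on
synthetic volumes and measure the per-stage restoration quality.

Conditions (fixed once for a single-CPU workstation; see docs/methods.md):
64x64 images, 180 views, 64 detector bins, cut_post-60 masking, twenty
6-slice volumes split 16 train / 1 val / 3 test, reduced-width networks
(sinogram stage base 8 / depth 3, image stages base 16 / depth 3), Adam at
1e-3 with step halving. Stages one and two train adversarially; the
patch refiner trains without its discriminator at this scale (a
from-scratch discriminator on a few hundred patches injects more noise
than the data can average out — see the methods note). All randomness
derives from one seed; repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Sinogram, ViewMask
from .networks import NetPlan, SliceStack, spatial_forward
from .phantoms import PhantomSpec, generate_dataset
from .pipeline import PipelineConfig, psnr, run_pipeline, ssim
from .preprocess import crop_patches, normalize, pad_views
from .training import TrainConfig, train_autoencoder, train_stage

__all__ = ["StudyConfig", "StudyResult", "run_desk_study"]


@dataclass
class StudyConfig:
    image_size: int = 64
    n_views: int = 180
    n_missing: int = 60
    scheme: str = "cut_post"
    n_volumes: int = 20
    n_slices: int = 6
    split: tuple = (16, 1, 3)
    sino_plan: NetPlan = None
    image_plan: NetPlan = None
    stage1_steps: int = 300
    stage2_steps: int = 450
    stage3_steps: int = 1500
    stage3_adversarial: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 2

    def __post_init__(self):
        if self.sino_plan is None:
            self.sino_plan = NetPlan(1, 8, 3)
        if self.image_plan is None:
            self.image_plan = NetPlan(3, 16, 3)


@dataclass
class StudyResult:
    metrics: dict          # scalar summary quantities
    models: dict           # stage name -> trained network(s)
    dataset: object


def _stage1_pairs(records, divisibility):
    xs, ys = [], []
    for r in records:
        normed, p = normalize(r.merged_sinogram)
        tgt = (r.full_sinogram - p.vmin) / (p.vmax - p.vmin)
        xs.append(pad_views(normed, divisibility)[0])
        ys.append(pad_views(tgt, divisibility)[0])
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def run_desk_study(seed: int, cfg: StudyConfig | None = None,
                   progress=None) -> StudyResult:
    """Generate data, train the three stages, and evaluate on held-out
    volumes. Returns summary metrics, the trained models and the dataset."""
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2 ** 31))
             for k in ("data", "stage1", "stage2", "stage3")}

    def note(msg):
        if progress is not None:
            progress(msg)

    mask = ViewMask(cfg.scheme, cfg.n_missing, n_full=cfg.n_views)
    spec = PhantomSpec(image_size=cfg.image_size, n_slices=cfg.n_slices,
                       n_views=cfg.n_views, n_bins=cfg.image_size,
                       seed=seeds["data"])
    ds = generate_dataset(spec, mask, n_volumes=cfg.n_volumes,
                          split_ratio=cfg.split)
    train_vols, test_vols = ds.split["train"], ds.split["test"]
    train_recs = [r for v in train_vols for r in ds.volumes[v]]
    note(f"dataset ready: {len(train_recs)} training slices")

    # merged-vs-zero-fill completion quality in the sinogram domain
    merge_gain = []
    for recs in ds.volumes:
        for r in recs:
            zero_filled = np.zeros_like(r.full_sinogram)
            zero_filled[mask.measured_indices] = r.limited_sinogram
            merge_gain.append(
                np.linalg.norm(zero_filled - r.full_sinogram)
                / np.linalg.norm(r.merged_sinogram - r.full_sinogram))

    div = cfg.sino_plan.divisibility
    x1, y1 = _stage1_pairs(train_recs, div)
    res1 = train_autoencoder(
        x1, y1, cfg.sino_plan,
        TrainConfig(cfg.learning_rate, batch_size=cfg.batch_size,
                    max_steps=cfg.stage1_steps, seed=seeds["stage1"],
                    lr_decay_steps=cfg.stage1_steps // 2))
    note("stage 1 trained")

    def volume_sinos(recs):
        return [Sinogram(r.limited_sinogram,
                         ds.angles[mask.measured_indices], role="limited")
                for r in recs]

    cfg_s1 = PipelineConfig(mask=mask, out_size=cfg.image_size,
                            stage1=res1.model)
    s1_imgs, gts = {}, {}
    for v in range(cfg.n_volumes):
        pr = run_pipeline(volume_sinos(ds.volumes[v]), cfg_s1)
        s1_imgs[v] = pr.stage1_fbp
        gts[v] = np.stack([r.ground_truth for r in ds.volumes[v]])
    note("stage 1 inference done")

    stacks, targets = [], []
    for v in train_vols:
        for i in range(cfg.n_slices):
            idx = np.clip(np.arange(i - 2, i + 3), 0, cfg.n_slices - 1)
            stacks.append(s1_imgs[v][idx])
            targets.append(gts[v][i])
    r2a, r2b = train_stage(
        "spatial", {"stacks": np.stack(stacks), "targets": np.stack(targets)},
        TrainConfig(cfg.learning_rate, batch_size=cfg.batch_size,
                    max_steps=cfg.stage2_steps, seed=seeds["stage2"],
                    lr_decay_steps=cfg.stage2_steps // 2),
        plan=cfg.image_plan)
    note("stage 2 trained")

    def spatial_out(v):
        outs = []
        for i in range(cfg.n_slices):
            idx = np.clip(np.arange(i - 2, i + 3), 0, cfg.n_slices - 1)
            out = spatial_forward(SliceStack(s1_imgs[v][idx]),
                                  r2a.model, r2b.model).pixels
            outs.append(np.clip(out, 0.0, 1.0))
        return np.stack(outs)

    xp, yp = [], []
    for v in train_vols:
        for img, gt in zip(spatial_out(v), gts[v]):
            for pa, pb in zip(crop_patches(img, "corner").patches,
                              crop_patches(gt, "corner").patches):
                xp.append(pa[None])
                yp.append(pb[None])
    refine_plan = NetPlan(1, cfg.image_plan.base_channels,
                          cfg.image_plan.depth)
    res3 = train_autoencoder(
        np.stack(xp), np.stack(yp), refine_plan,
        TrainConfig(cfg.learning_rate, batch_size=4,
                    max_steps=cfg.stage3_steps, seed=seeds["stage3"],
                    lr_decay_steps=cfg.stage3_steps // 3),
        adversarial=cfg.stage3_adversarial)
    note("stage 3 trained")

    cfg_full = PipelineConfig(mask=mask, out_size=cfg.image_size,
                              stage1=res1.model,
                              stage2=(r2a.model, r2b.model),
                              stage3=res3.model)
    per_stage = {"fbp_limited": [], "input_fbp": [], "stage1": [],
                 "stage2": [], "stage3": [], "ssim_final": []}
    for v in test_vols:
        recs = ds.volumes[v]
        pr = run_pipeline(volume_sinos(recs), cfg_full)
        gt = gts[v]
        per_stage["fbp_limited"].append(np.mean(
            [psnr(r.fbp_limited, r.ground_truth) for r in recs]))
        per_stage["input_fbp"].append(np.mean(
            [psnr(r.fbp_merged, r.ground_truth) for r in recs]))
        per_stage["stage1"].append(np.mean(
            [psnr(a, b) for a, b in zip(pr.stage1_fbp, gt)]))
        per_stage["stage2"].append(np.mean(
            [psnr(a, b) for a, b in zip(pr.stage2_images, gt)]))
        per_stage["stage3"].append(np.mean(
            [psnr(a, b) for a, b in zip(pr.final.slices, gt)]))
        per_stage["ssim_final"].append(np.mean(
            [ssim(a, b) for a, b in zip(pr.final.slices, gt)]))
    note("evaluation done")

    metrics = {
        "merged_over_zerofill_l2_gain": float(np.mean(merge_gain)),
        "psnr_fbp_limited": float(np.mean(per_stage["fbp_limited"])),
        "psnr_input_fbp_merged": float(np.mean(per_stage["input_fbp"])),
        "psnr_stage1": float(np.mean(per_stage["stage1"])),
        "psnr_stage2": float(np.mean(per_stage["stage2"])),
        "psnr_stage3": float(np.mean(per_stage["stage3"])),
        "ssim_stage3": float(np.mean(per_stage["ssim_final"])),
        "stage1_lmse_first": float(res1.history[0]["l_mse"]),
        "stage1_lmse_last": float(res1.history[-1]["l_mse"]),
        "n_train_slices": len(train_recs),
        "n_test_volumes": len(test_vols),
    }
    models = {"stage1": res1.model, "stage2": (r2a.model, r2b.model),
              "stage3": res3.model}
    return StudyResult(metrics, models, ds)
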