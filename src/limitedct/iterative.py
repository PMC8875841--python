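"""SART with total-variation regularization — the classical iterative baseline.

One outer iteration is a full sweep of per-view SART updates (natural angle
order, relaxation ``relaxation``), a nonnegativity projection, and
``tv_inner_steps`` steps of gradient descent on the smoothed isotropic total
variation. With ``tv_weight = 0`` the TV stage is skipped entirely and the
method reduces bitwise to plain SART.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ImageSlice, Sinogram, _splat_geometry

__all__ = ["SartConfig", "sart_tv_reconstruct", "total_variation"]


@dataclass
class SartConfig:
    n_iterations: int = 50
    relaxation: float = 1.0
    tv_weight: float = 0.1
    tv_inner_steps: int = 10

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.relaxation < 2.0):
            raise ValueError("relaxation must lie in (0, 2)")
        if self.tv_weight < 0:
            raise ValueError("tv_weight must be nonnegative")
        if self.tv_inner_steps < 1:
            raise ValueError("tv_inner_steps must be >= 1")


def total_variation(img: np.ndarray, eps: float = 1e-8) -> float:
    """Smoothed isotropic TV: sum of sqrt(dx^2 + dy^2 + eps) over pixels."""
    dx = np.diff(img, axis=1, append=img[:, -1:])
    dy = np.diff(img, axis=0, append=img[-1:, :])
    return float(np.sum(np.sqrt(dx * dx + dy * dy + eps)))


def _tv_gradient(img: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    dx = np.diff(img, axis=1, append=img[:, -1:])
    dy = np.diff(img, axis=0, append=img[-1:, :])
    mag = np.sqrt(dx * dx + dy * dy + eps)
    px = dx / mag
    py = dy / mag
    # dTV/dx = -div(p) with p the normalized gradient field
    g = np.zeros_like(img)
    g -= px
    g[:, 1:] += px[:, :-1]
    g -= py
    g[1:, :] += py[:-1, :]
    return g


def _view_geometry(n: int, n_bins: int, angle: float):
    i0, frac, v0, v1 = _splat_geometry(n, n_bins, angle)
    # per-bin ray weight sums (A 1) and per-pixel column sums (A^T 1)
    w_lo = np.where(v0, 1.0 - frac, 0.0)
    w_hi = np.where(v1, frac, 0.0)
    ray_sum = np.bincount(i0[v0], weights=w_lo[v0], minlength=n_bins)
    ray_sum += np.bincount((i0 + 1)[v1], weights=w_hi[v1], minlength=n_bins)
    pix_sum = w_lo + w_hi
    return i0, w_lo, w_hi, v0, v1, ray_sum, pix_sum


def sart_tv_reconstruct(sino: Sinogram, cfg: SartConfig, out_size: int,
                        callback=None) -> ImageSlice:
    """Reconstruct by SART sweeps with interleaved TV descent.

    ``callback(iteration, x, fidelity)`` is invoked after each SART sweep
    (before the TV stage) with the squared data-fidelity ||Rx - p||^2.

    Raises ``RuntimeError`` naming the iteration if the iterate diverges.
    """
    n = out_size
    x = np.zeros(n * n)
    geom = [_view_geometry(n, sino.n_bins, a) for a in sino.angles]

    for it in range(cfg.n_iterations):
        for k in range(sino.n_views):
            i0, w_lo, w_hi, v0, v1, ray_sum, pix_sum = geom[k]
            proj = np.bincount(i0[v0], weights=(x * w_lo)[v0],
                               minlength=sino.n_bins)
            proj += np.bincount((i0 + 1)[v1], weights=(x * w_hi)[v1],
                                minlength=sino.n_bins)
            resid = sino.values[k] - proj
            resid = np.divide(resid, ray_sum,
                              out=np.zeros_like(resid), where=ray_sum > 0)
            upd = np.zeros_like(x)
            upd[v0] += resid[i0[v0]] * w_lo[v0]
            upd[v1] += resid[(i0 + 1)[v1]] * w_hi[v1]
            upd = np.divide(upd, pix_sum,
                            out=np.zeros_like(upd), where=pix_sum > 0)
            x += cfg.relaxation * upd
        np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"SART iterate diverged at iteration {it}")
        if callback is not None:
            fid = 0.0
            for k in range(sino.n_views):
                i0, w_lo, w_hi, v0, v1, ray_sum, _ = geom[k]
                proj = np.bincount(i0[v0], weights=(x * w_lo)[v0],
                                   minlength=sino.n_bins)
                proj += np.bincount((i0 + 1)[v1], weights=(x * w_hi)[v1],
                                    minlength=sino.n_bins)
                fid += float(np.sum((sino.values[k] - proj) ** 2))
            callback(it, x.reshape(n, n).copy(), fid)
        if cfg.tv_weight > 0:
            img = x.reshape(n, n)
            step = cfg.tv_weight * 0.02
            for _ in range(cfg.tv_inner_steps):
                tv_now = total_variation(img)
                g = _tv_gradient(img)
                trial_step = step
                for _ in range(12):
                    cand = np.maximum(img - trial_step * g, 0.0)
                    if total_variation(cand) <= tv_now:
                        img = cand
                        break
                    trial_step *= 0.5
            x = img.ravel()
    return ImageSlice(x.reshape(n, n))
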