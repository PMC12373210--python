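"""Patient-specific fine-tuning on full sparse-view projections, and volume rendering.

At inference the field (prior or freshly initialized) is optimized against the
patient's own 1-10 normalized projections: each iteration draws one reference
view uniformly, renders the full detector (R = H x W rays), and takes an
RMSprop step on the combined perceptual / PSNR-shortfall / Gaussian-NLL
objective.  Optimization stops once the rendered-vs-reference PSNR reaches the
stopping threshold on every reference view (configurable to "any"), or at the
iteration cap.  Rendering for the stopping check and for the final volume uses
deterministic midpoint bins, so results are reproducible from the seed alone.

Reference projections are min-max normalized; the rendered projection is
normalized by its own range (treated as constants of the iteration) before the
comparison, which leaves the field's global intensity scale as a harmless
gauge freedom — rendered volumes are min-max normalized to [0, 1] anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._autodiff import Tensor
from .field import FieldConfig, FieldParams, LatentCodes, init_field, sample_codes
from .geometry import Pose, SourceSetup, rays_for_detector
from .losses import FeatureExtractor, inference_loss
from .metrics import psnr, rmse, ssim, to_hounsfield
from .nn import RMSprop
from .projector import VoxelGrid
from .training import render_patch_graph

__all__ = [
    "FinetuneResult",
    "ReconstructionConfig",
    "finetune",
    "render_projection",
    "render_volume",
    "reconstruct",
]


def render_projection(params: FieldParams, codes: LatentCodes, setup: SourceSetup,
                      pose: Pose, bounds, q: int = 24, normalize: bool = True) -> np.ndarray:
    """Deterministic (midpoint-bin) full-detector rendering of the field."""
    rays = rays_for_detector(setup, pose, bounds=bounds)
    frac = (np.arange(q) + 0.5) / q
    t = rays.t_near[:, None] + (rays.t_far - rays.t_near)[:, None] * frac[None, :]
    dt = ((rays.t_far - rays.t_near) / q)[:, None] * np.ones((1, q))
    pts = rays.origins[:, None, :] + t[:, :, None] * rays.directions[:, None, :]
    dens = params(pts.reshape(-1, 3), pose, codes).reshape(t.shape)
    img = (dens * dt).sum(axis=1).reshape(rays.shape)
    if normalize:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


@dataclass
class FinetuneResult:
    params: FieldParams
    codes: LatentCodes
    history: np.ndarray           # per-iteration loss
    n_iter: int
    final_psnr: np.ndarray        # per reference view, at termination
    converged: bool               # stopping rule met before the iteration cap


def finetune(params: FieldParams, codes: LatentCodes, projections: np.ndarray,
             poses: list[Pose], setup: SourceSetup, bounds,
             fx: FeatureExtractor | None = None, stop_psnr: float = 25.0,
             max_iter: int = 1000, rng: np.random.Generator | None = None,
             lr: float = 5e-4, q: int = 24, check_every: int = 25,
             lambdas: tuple[float, float, float] = (0.3, 0.1, 0.3),
             stop_mode: str = "all") -> FinetuneResult:
    """Optimize field weights and both latent codes against full projections.

    `projections` is (n_views, H, W) in [0, 1] with matching `poses`; `bounds`
    is the reconstruction bounding box (lo, hi) in mm.  Only the supplied
    views are ever evaluated.  Deterministic for a given `rng` state.
    """
    projections = np.asarray(projections, dtype=np.float64)
    if projections.ndim != 3 or projections.shape[0] == 0:
        raise ValueError("need at least one projection (n_views, H, W)")
    if len(poses) != projections.shape[0]:
        raise ValueError("projection/pose count mismatch")
    if stop_mode not in ("all", "any"):
        raise ValueError("stop_mode must be 'all' or 'any'")
    rng = rng if rng is not None else np.random.default_rng(0)

    z_sh = Tensor(codes.z_sh, requires_grad=True)
    z_a = Tensor(codes.z_a, requires_grad=True)
    opt = RMSprop(params.parameters() + [z_sh, z_a], lr=lr)

    def eval_psnrs() -> np.ndarray:
        cur = LatentCodes(z_sh.data.astype(np.float64), z_a.data.astype(np.float64))
        vals = []
        for img, pose in zip(projections, poses):
            pred = render_projection(params, cur, setup, pose, bounds, q=q)
            vals.append(psnr(pred, img, max_val=1.0))
        return np.array(vals)

    history = []
    converged = False
    n_iter = 0
    psnrs = np.full(len(poses), -np.inf)
    for it in range(max_iter):
        vi = int(rng.integers(len(poses)))
        pose = poses[vi]
        rays = rays_for_detector(setup, pose, bounds=bounds)
        pred, _, _ = render_patch_graph(params, rays, q, rng, z_sh, z_a, pose)
        lo, hi = float(pred.data.min()), float(pred.data.max())
        denom = max(hi - lo, 1e-3)
        pred_n = (pred - lo) / denom
        loss = inference_loss(pred_n, projections[vi], fx, lambdas=lambdas,
                              stop_psnr=stop_psnr)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite fine-tuning loss at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
        n_iter = it + 1
        if (it + 1) % check_every == 0 or stop_psnr <= 0:
            psnrs = eval_psnrs()
            ok = psnrs.min() if stop_mode == "all" else psnrs.max()
            if ok >= stop_psnr:
                converged = True
                break
    if not converged:
        psnrs = eval_psnrs()
        converged = (psnrs.min() if stop_mode == "all" else psnrs.max()) >= stop_psnr
    tuned = LatentCodes(z_sh.data.astype(np.float64), z_a.data.astype(np.float64))
    return FinetuneResult(params=params, codes=tuned, history=np.array(history),
                          n_iter=n_iter, final_psnr=psnrs, converged=converged)


def render_volume(params: FieldParams, codes: LatentCodes, dims, spacing_mm,
                  pose: Pose | None = None, normalize: bool = True,
                  chunk: int = 65536) -> VoxelGrid:
    """Evaluate the field at voxel centers of an isocenter-centered grid.

    When view conditioning is enabled the density is rendered at a single
    canonical pose (AP unless another is supplied).  Values are clipped to be
    non-negative and min-max normalized to [0, 1] by default.
    """
    pose = pose if pose is not None else Pose(0.0, 0.0)
    dims = tuple(int(d) for d in np.broadcast_to(dims, (3,)))
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=np.float64), (3,))
    origin = -np.array(dims) * spacing / 2.0
    axes = [origin[i] + (np.arange(dims[i]) + 0.5) * spacing[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    out = np.empty(pts.shape[0])
    for s in range(0, pts.shape[0], chunk):
        out[s : s + chunk] = params(pts[s : s + chunk], pose, codes)
    vol = np.clip(out.reshape(dims), 0.0, None)
    if normalize:
        lo, hi = vol.min(), vol.max()
        vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
    return VoxelGrid(vol, spacing, origin)


@dataclass
class ReconstructionConfig:
    field: FieldConfig = dc_field(default_factory=lambda: FieldConfig.small(view_conditioning=False))
    stop_psnr: float = 25.0
    max_iter: int = 1000
    q: int = 24
    lr: float = 5e-4
    check_every: int = 25
    lambdas: tuple[float, float, float] = (0.3, 0.1, 0.3)
    volume_dims: int = 32
    volume_extent_mm: float = 300.0
    use_perceptual: bool = True
    fx_seed: int = 0
    stop_mode: str = "all"


def reconstruct(projections: np.ndarray, poses: list[Pose], setup: SourceSetup,
                cfg: ReconstructionConfig, rng: np.random.Generator,
                prior: FieldParams | None = None, codes: LatentCodes | None = None,
                reference: VoxelGrid | None = None):
    """Sparse-view pipeline: (prior or fresh field) -> fine-tune -> volume.

    Returns (volume, report); the report carries the fine-tuning trajectory
    and, when a reference volume is supplied, PSNR/SSIM/RMSE(HU) against it.
    """
    half = cfg.volume_extent_mm / 2.0
    bounds = (np.array([-half] * 3), np.array([half] * 3))
    params = prior if prior is not None else init_field(cfg.field, rng)
    if codes is None:
        codes = sample_codes(rng, cfg.field.m_sh, cfg.field.m_a)
    fx = FeatureExtractor(2, (8, 16), seed=cfg.fx_seed) if cfg.use_perceptual else None
    ft = finetune(params, codes, projections, poses, setup, bounds, fx=fx,
                  stop_psnr=cfg.stop_psnr, max_iter=cfg.max_iter, rng=rng,
                  lr=cfg.lr, q=cfg.q, check_every=cfg.check_every,
                  lambdas=cfg.lambdas, stop_mode=cfg.stop_mode)
    spacing = cfg.volume_extent_mm / cfg.volume_dims
    volume = render_volume(ft.params, ft.codes, cfg.volume_dims, spacing)
    report = {
        "n_iter": int(ft.n_iter),
        "converged": bool(ft.converged),
        "view_psnr": [float(v) for v in ft.final_psnr],
    }
    if reference is not None:
        report["metrics"] = {
            "psnr": psnr(volume.values, reference.values, max_val=1.0),
            "ssim": ssim(volume.values, reference.values, dynamic_range=1.0),
            "rmse_hu": rmse(to_hounsfield(volume.values), to_hounsfield(reference.values)),
        }
    return volume, report
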