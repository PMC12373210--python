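"""Adversarial training of the density-field prior on patches and sub-volumes.

Per iteration the generator renders an s-dilated M x M projection patch P' and
its paired sub-volume lattice V' from stratified samples along patch rays; the
real counterparts P (bilinear crop of the stored projection) and V (trilinear
volume samples at the *same* 3D points) are extracted so fake and real pairs
are geometrically congruent.  Two auto-encoded convolutional discriminators —
3D for sub-volumes, 2D for patches, each with its own weights but shared
across every augmentation — provide hinge scores and decoded reconstructions.

The per-augmentation losses are combined exactly as
:func:`tomofield.losses.dag_training_loss` prescribes (identity term plus
lambda1/(n-1) times the sum over flip/rotation terms, patch terms weighted by
lambda2); for efficiency the k = 0..n augmented samples are pushed through the
discriminators as one batch and the combination is applied as a weighted sum,
which is algebraically identical.

Two choices the printed objective leaves open are fixed here and documented in
the methods note: the discriminators minimize hinge classification plus a
self-supervised reconstruction loss on reals, while the generator minimizes
the perceptual terms plus the generator-side hinge -E[D(fake)]; and
discriminator inputs are standardized per sample, so the critics judge
structure rather than absolute amplitude (the field's global intensity scale
is a gauge freedom removed at volume rendering).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import map_coordinates

from ._autodiff import Tensor, as_tensor, concat
from .field import FieldConfig, FieldParams, init_field, sample_codes
from .geometry import (
    PatchPattern,
    Pose,
    SourceSetup,
    rays_for_patch,
    sample_patch_pattern,
    stratified_sample,
)
from .losses import FeatureExtractor, perceptual_loss, standardize_per_sample
from .nn import Conv, Linear, Module, RMSprop, upsample
from .phantom import SparseViewDataset
from .projector import VoxelGrid, trilinear_sample

__all__ = [
    "Discriminator",
    "DiscriminatorPair",
    "TrainConfig",
    "TrainResult",
    "extract_real_pair",
    "augment",
    "render_patch_graph",
    "train",
]


class Discriminator(Module):
    """Auto-encoded CNN critic: strided conv encoder -> (scores, decoded inputs).

    Consumes a batch (N, ...spatial) of patches (ndim=2) or sub-volume
    lattices (ndim=3); every sample is standardized independently before
    encoding.  The decoder reconstructs the standardized input from the
    bottleneck; its output is the feature map assessed by the perceptual
    loss.  Spatial sides must be divisible by 2**levels.
    """

    def __init__(self, ndim: int, rng: np.random.Generator,
                 channels: tuple[int, ...] = (8, 16, 32)):
        self.ndim = ndim
        self.levels = len(channels)
        cs = (1,) + tuple(channels)
        self.enc = [Conv(ndim, cs[i], cs[i + 1], rng, stride=2) for i in range(self.levels)]
        self.dec = [Conv(ndim, cs[i + 1], cs[i], rng) for i in reversed(range(self.levels))]
        self.score_head = Linear(channels[-1], 1, rng)

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        if x.data.ndim == self.ndim:
            x = x.reshape(1, *x.shape)
        for s in x.shape[1:]:
            if s % (2**self.levels) != 0:
                raise ValueError(
                    f"spatial sides must be divisible by {2**self.levels}, got {x.shape}")
        n = x.shape[0]
        xs = standardize_per_sample(x)
        feat = xs.reshape(n, 1, *xs.shape[1:])
        for conv in self.enc:
            feat = conv(feat).relu()
        pooled = feat.reshape(n, feat.shape[1], -1).mean(axis=2)
        scores = self.score_head(pooled).reshape(-1)
        dec = feat
        for i, conv in enumerate(self.dec):
            dec = conv(upsample(dec, 2))
            if i < len(self.dec) - 1:
                dec = dec.relu()
        decoded = dec.reshape(*x.shape)
        return scores, decoded

    def parameters(self):
        ps = [p for c in self.enc for p in c.parameters()]
        ps += [p for c in self.dec for p in c.parameters()]
        ps += self.score_head.parameters()
        return ps


@dataclass
class DiscriminatorPair:
    """D1 (3D, sub-volumes) and D2 (2D, patches); separate weights, each
    shared across every augmentation."""

    d_vol: Discriminator
    d_patch: Discriminator

    def parameters(self):
        return self.d_vol.parameters() + self.d_patch.parameters()


def extract_real_pair(volume: VoxelGrid, projection: np.ndarray, pose: Pose,
                      setup: SourceSetup, pattern: PatchPattern,
                      points_mm: np.ndarray | None = None, q: int = 16,
                      rng: np.random.Generator | None = None):
    """Ground-truth pair (P, V) for a patch pattern.

    P is the s-dilated M x M bilinear crop of the stored projection at the
    pattern's continuous coordinates.  V holds trilinear volume samples on the
    ray-by-bin lattice; pass the generator's stratified `points_mm`
    (shape (M*M, Q, 3)) so V' and V are sampled at identical locations, or
    leave None to draw stratified points here.
    """
    pattern.validate(setup)
    m = pattern.size_m
    cols, rows = pattern.pixel_coords()
    patch = map_coordinates(np.asarray(projection, dtype=np.float64),
                            [rows, cols], order=1, mode="nearest")
    if points_mm is None:
        rays = rays_for_patch(setup, pose, pattern, bounds=volume.bounds)
        t, _ = stratified_sample(rays, q, rng if rng is not None else np.random.default_rng(0))
        points_mm = rays.origins[:, None, :] + t[:, :, None] * rays.directions[:, None, :]
    pts = np.asarray(points_mm)
    nq = pts.shape[1]
    vals = trilinear_sample(volume, pts.reshape(-1, 3)).reshape(m, m, nq)
    return patch, vals


def _rot90(x, times: int):
    """Rotate the leading two axes by 90 degrees `times` times (Tensor or array)."""
    times = times % 4
    for _ in range(times):
        if isinstance(x, Tensor):
            axes = (1, 0) + tuple(range(2, len(x.shape)))
            x = x.transpose(axes).flip(0)
        else:
            x = np.flip(np.transpose(x, (1, 0) + tuple(range(2, x.ndim))), axis=0)
    return x


def _flip(x, axis: int):
    return x.flip(axis) if isinstance(x, Tensor) else np.flip(x, axis=axis)


def augment(patch, subvol, k: int):
    """Deterministic per-k flip/rotation family applied consistently to the
    patch and the sub-volume ray lattice (its leading two axes).

    k = 0 identity; 1 horizontal flip; 2 vertical flip; 3 rotate 90; 4 rotate 180.
    """
    if k == 0:
        return patch, subvol
    if k == 1:
        return _flip(patch, 1), _flip(subvol, 1)
    if k == 2:
        return _flip(patch, 0), _flip(subvol, 0)
    if k == 3:
        return _rot90(patch, 1), _rot90(subvol, 1)
    if k == 4:
        return _rot90(patch, 2), _rot90(subvol, 2)
    raise ValueError(f"unknown augmentation index {k}")


def render_patch_graph(params: FieldParams, rays, q: int, rng: np.random.Generator,
                       z_sh, z_a, pose: Pose):
    """Differentiable patch rendering: returns (patch Tensor (M, M),
    V' density lattice Tensor (M, M, Q), sample points (M*M, Q, 3))."""
    t, dt = stratified_sample(rays, q, rng)
    pts = rays.origins[:, None, :] + t[:, :, None] * rays.directions[:, None, :]
    dens = params.density_graph(pts.reshape(-1, 3), pose, z_sh, z_a)
    dens2 = dens.reshape(t.shape[0], q)
    patch = (dens2 * Tensor(dt)).sum(axis=1).reshape(*rays.shape)
    m = rays.shape[0]
    lattice = dens2.reshape(m, rays.shape[1], q)
    return patch, lattice, pts


def _aug_stack(patch, subvol, n_aug: int):
    """Stacks of the k = 0..n augmented (patch, subvol) pairs."""
    ps, vs = [], []
    for k in range(n_aug + 1):
        p, v = augment(patch, subvol, k)
        if isinstance(p, Tensor):
            ps.append(p.reshape(1, *p.shape))
            vs.append(v.reshape(1, *v.shape))
        else:
            ps.append(np.ascontiguousarray(p)[None])
            vs.append(np.ascontiguousarray(v)[None])
    if isinstance(ps[0], Tensor):
        return concat(ps, axis=0), concat(vs, axis=0)
    return np.concatenate(ps, axis=0), np.concatenate(vs, axis=0)


def _per_sample_sq(a: Tensor, b) -> Tensor:
    """Per-sample mean squared difference over all non-batch axes -> (N,)."""
    diff = a - as_tensor(b)
    n = diff.shape[0]
    return (diff * diff).reshape(n, -1).mean(axis=1)


@dataclass
class TrainConfig:
    iterations: int = 1000
    batch_size: int = 4
    lr_g: float = 5e-4
    lr_d: float = 1e-4
    n_aug: int = 4                 # augmentations beyond the identity (k = 1..n)
    lambda1: float = 0.2
    lambda2: float = 0.5
    patch_m: int = 16
    q: int = 16
    use_3d: bool = True            # keep the sub-volume (V) supervision terms
    adversarial: bool = True       # False: plain reconstruction of P (and V)
    fixed_draw: bool = False       # reuse a single (pose, pattern, codes) draw
    ae_weight: float = 1.0         # discriminator self-reconstruction weight
    disc_channels: tuple[int, ...] = (8, 16, 32)
    field: FieldConfig = dc_field(default_factory=FieldConfig.small)
    fx_seed: int = 0

    def __post_init__(self):
        if min(self.iterations, self.batch_size, self.patch_m, self.q) < 1:
            raise ValueError("sizes must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambdas must be >= 0")
        if self.adversarial and self.n_aug < 2:
            raise ValueError("the augmentation combination needs n >= 2")

    def dag_weights(self) -> np.ndarray:
        w = np.full(self.n_aug + 1, self.lambda1 / (self.n_aug - 1))
        w[0] = 1.0
        return w


@dataclass
class TrainResult:
    params: FieldParams
    discriminators: DiscriminatorPair
    history: dict[str, np.ndarray]


def train(dataset: SparseViewDataset, cfg: TrainConfig, rng: np.random.Generator) -> TrainResult:
    """Alternating generator/discriminator RMSprop updates on patch and
    sub-volume pairs drawn from the dataset's empirical pose distribution."""
    if not dataset.patients:
        raise ValueError("empty dataset")
    if any(len(p.poses) < 2 for p in dataset.patients):
        raise ValueError("each patient needs at least two posed projections")
    if cfg.adversarial:
        div = 2 ** len(cfg.disc_channels)
        if cfg.patch_m % div or cfg.q % div:
            raise ValueError(
                f"patch_m and q must be divisible by {div} for the "
                f"{len(cfg.disc_channels)}-level auto-encoded discriminators")

    params = init_field(cfg.field, rng)
    pair = DiscriminatorPair(
        d_vol=Discriminator(3, rng, cfg.disc_channels),
        d_patch=Discriminator(2, rng, cfg.disc_channels),
    )
    fx2 = FeatureExtractor(2, (8, 16), seed=cfg.fx_seed)
    fx3 = FeatureExtractor(3, (8, 16), seed=cfg.fx_seed + 1)
    opt_g = RMSprop(params.parameters(), lr=cfg.lr_g)
    opt_d = RMSprop(pair.parameters(), lr=cfg.lr_d)
    w = Tensor(cfg.dag_weights())

    def draw_one():
        pat = dataset.patients[rng.integers(len(dataset.patients))]
        vi = int(rng.integers(len(pat.poses)))
        pattern = sample_patch_pattern(rng, pat.setup, cfg.patch_m)
        codes = sample_codes(rng, cfg.field.m_sh, cfg.field.m_a)
        rays = rays_for_patch(pat.setup, pat.poses[vi], pattern, bounds=pat.volume.bounds)
        return pat, vi, pattern, codes, rays

    fixed = draw_one() if cfg.fixed_draw else None

    hist_g, hist_d, hist_rec = [], [], []
    for it in range(cfg.iterations):
        batch = []
        for _ in range(cfg.batch_size):
            pat, vi, pattern, codes, rays = fixed if fixed is not None else draw_one()
            pose = pat.poses[vi]
            fake_p, fake_v, pts = render_patch_graph(
                params, rays, cfg.q, rng, codes.z_sh, codes.z_a, pose)
            lo, hi = pat.proj_scales[vi]
            fake_p = (fake_p - lo) / max(hi - lo, 1e-6)
            real_p, real_v = extract_real_pair(
                pat.volume, pat.projections[vi], pose, pat.setup, pattern, points_mm=pts)
            batch.append((fake_p, fake_v, real_p, real_v))

        # ---- generator step --------------------------------------------
        g_terms = []
        rec_terms = []
        detached = []
        for fake_p, fake_v, real_p, real_v in batch:
            if not cfg.adversarial:
                loss = perceptual_loss(fake_p, real_p, None, standardize_inputs=False)
                if cfg.use_3d:
                    loss = loss + perceptual_loss(fake_v, real_v, None, standardize_inputs=False)
                g_terms.append(loss)
                rec_terms.append(float(loss.data))
                continue
            fps, fvs = _aug_stack(fake_p, fake_v, cfg.n_aug)
            rps, rvs = _aug_stack(real_p, real_v, cfg.n_aug)
            sc_p, dec_p = pair.d_patch(fps)
            rps_std = standardize_per_sample(Tensor(rps)).data
            l_rp = _per_sample_sq(fx2(dec_p), fx2(Tensor(rps_std)).data)
            l_hp = -sc_p
            patch_part = ((l_rp + l_hp) * w).sum() * cfg.lambda2
            if cfg.use_3d:
                sc_v, dec_v = pair.d_vol(fvs)
                rvs_std = standardize_per_sample(Tensor(rvs)).data
                l_rv = _per_sample_sq(fx3(dec_v), fx3(Tensor(rvs_std)).data)
                l_hv = -sc_v
                vol_part = ((l_rv + l_hv) * w).sum()
            else:
                vol_part = Tensor(0.0)
            g_terms.append(vol_part + patch_part)
            # identity-augmentation perceptual terms: the reconstruction-quality
            # component of the objective, tracked separately in the history
            rec = float(l_rp.data[0])
            if cfg.use_3d:
                rec += float(l_rv.data[0])
            rec_terms.append(rec)
            detached.append((fps.detach(), fvs.detach() if cfg.use_3d else None, rps, rvs))

        loss_g = g_terms[0]
        for t_ in g_terms[1:]:
            loss_g = loss_g + t_
        loss_g = loss_g / float(len(g_terms))
        if not np.isfinite(loss_g.data):
            raise RuntimeError(f"non-finite generator loss at iteration {it}")
        opt_g.zero_grad()
        opt_d.zero_grad()
        loss_g.backward()
        opt_g.step()

        # ---- discriminator step ----------------------------------------
        if cfg.adversarial:
            d_terms = []
            for fps_d, fvs_d, rps, rvs in detached:
                sc_fp, _ = pair.d_patch(fps_d)
                sc_rp, dec_rp = pair.d_patch(Tensor(rps))
                hinge_p = (((sc_fp + 1.0).relu() + (1.0 - sc_rp).relu()) * w).sum()
                recon_p = (_per_sample_sq(dec_rp, standardize_per_sample(Tensor(rps)).data) * w).sum()
                term = cfg.lambda2 * (hinge_p + cfg.ae_weight * recon_p)
                if cfg.use_3d:
                    sc_fv, _ = pair.d_vol(fvs_d)
                    sc_rv, dec_rv = pair.d_vol(Tensor(rvs))
                    hinge_v = (((sc_fv + 1.0).relu() + (1.0 - sc_rv).relu()) * w).sum()
                    recon_v = (_per_sample_sq(dec_rv, standardize_per_sample(Tensor(rvs)).data) * w).sum()
                    term = term + hinge_v + cfg.ae_weight * recon_v
                d_terms.append(term)
            loss_d = d_terms[0]
            for t_ in d_terms[1:]:
                loss_d = loss_d + t_
            loss_d = loss_d / float(len(d_terms))
            if not np.isfinite(loss_d.data):
                raise RuntimeError(f"non-finite discriminator loss at iteration {it}")
            opt_d.zero_grad()
            opt_g.zero_grad()
            loss_d.backward()
            opt_d.step()
            hist_d.append(loss_d.item())
        else:
            hist_d.append(0.0)
        hist_g.append(loss_g.item())
        hist_rec.append(float(np.mean(rec_terms)))

    history = {"generator": np.array(hist_g), "discriminator": np.array(hist_d),
               "reconstruction": np.array(hist_rec)}
    return TrainResult(params=params, discriminators=pair, history=history)
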