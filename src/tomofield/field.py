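"""The conditional generative density field g_theta.

A coordinate MLP maps an encoded 3D location x (plus a shape latent z_sh) to a
hidden shape feature h, and a small density head maps (h, encoded view
direction, appearance latent z_a) to a non-negative X-ray attenuation density
delta.  Attenuation is physically view-independent; the view/appearance
conditioning of the head is kept as the reference formulation and can be
switched off (``view_conditioning=False``) for the physically cleaner variant.

Positions are normalized by ``coord_scale_mm`` before sine/cosine positional
encoding (log-spaced frequencies, the coordinate-network convention), so the
encoding operates on roughly [-1, 1] inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._autodiff import Tensor, affine
from .geometry import Pose
from .nn import MLP

__all__ = [
    "EncodingSpec",
    "LatentCodes",
    "FieldConfig",
    "FieldParams",
    "positional_encode",
    "sample_codes",
    "init_field",
    "field_density",
]


@dataclass(frozen=True)
class EncodingSpec:
    """Sine/cosine positional encoding: sin(2^k pi p), cos(2^k pi p), k < L."""

    n_freq: int = 10
    include_identity: bool = True

    def __post_init__(self):
        if self.n_freq < 0:
            raise ValueError("n_freq must be >= 0")

    def out_dim(self, in_dim: int) -> int:
        return in_dim * (2 * self.n_freq + (1 if self.include_identity else 0))


def positional_encode(p: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode points (..., d) -> (..., d*(2L [+1])): identity (optional), then
    per frequency k the blocks sin(2^k pi p) and cos(2^k pi p)."""
    p = np.asarray(p, dtype=np.float32)
    d = p.shape[-1]
    L = spec.n_freq
    if L == 0:
        return p.copy() if spec.include_identity else np.empty(p.shape[:-1] + (0,), dtype=p.dtype)
    freqs = ((2.0 ** np.arange(L)) * np.pi).astype(np.float32)
    ang = p[..., None, None, :] * freqs[:, None, None]        # (..., L, 1, d)
    trig = np.empty(p.shape[:-1] + (L, 2, d), dtype=np.float32)
    np.sin(ang[..., 0, :], out=trig[..., 0, :])
    np.cos(ang[..., 0, :], out=trig[..., 1, :])
    trig = trig.reshape(p.shape[:-1] + (2 * L * d,))
    if spec.include_identity:
        return np.concatenate([p, trig], axis=-1)
    return trig


@dataclass
class LatentCodes:
    """Shape and appearance latents, standard-Gaussian priors at train time."""

    z_sh: np.ndarray
    z_a: np.ndarray

    def __post_init__(self):
        self.z_sh = np.asarray(self.z_sh, dtype=np.float64).ravel()
        self.z_a = np.asarray(self.z_a, dtype=np.float64).ravel()
        if not (np.all(np.isfinite(self.z_sh)) and np.all(np.isfinite(self.z_a))):
            raise ValueError("latent codes must be finite")


def sample_codes(rng: np.random.Generator, m_sh: int, m_a: int) -> LatentCodes:
    return LatentCodes(rng.standard_normal(m_sh), rng.standard_normal(m_a))


@dataclass(frozen=True)
class FieldConfig:
    hidden_width: int = 128
    hidden_depth: int = 8
    head_width: int = 64
    m_sh: int = 128
    m_a: int = 32
    enc_x: EncodingSpec = dc_field(default_factory=lambda: EncodingSpec(10))
    enc_xi: EncodingSpec = dc_field(default_factory=lambda: EncodingSpec(4))
    view_conditioning: bool = True
    coord_scale_mm: float = 150.0

    @classmethod
    def small(cls, view_conditioning: bool = True, coord_scale_mm: float = 150.0) -> "FieldConfig":
        """Desk-scale configuration used by the phantom benchmarks."""
        return cls(hidden_width=48, hidden_depth=4, head_width=32, m_sh=16, m_a=8,
                   enc_x=EncodingSpec(6), enc_xi=EncodingSpec(2),
                   view_conditioning=view_conditioning, coord_scale_mm=coord_scale_mm)


class FieldParams:
    """Trainable parameters: shape encoder h_theta and density head d_theta."""

    def __init__(self, config: FieldConfig, rng: np.random.Generator):
        self.config = config
        in_x = config.enc_x.out_dim(3) + config.m_sh
        sizes_h = [in_x] + [config.hidden_width] * config.hidden_depth
        self.h_net = MLP(sizes_h, rng)
        in_d = config.hidden_width + config.m_a
        if config.view_conditioning:
            in_d += config.enc_xi.out_dim(3)
        self.d_net = MLP([in_d, config.head_width, 1], rng)

    def parameters(self) -> list[Tensor]:
        return self.h_net.parameters() + self.d_net.parameters()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=p.data.dtype).reshape(p.data.shape).copy()

    # -- forward ----------------------------------------------------------
    def density_graph(self, x_mm: np.ndarray, xi: Pose,
                      z_sh: Tensor | np.ndarray, z_a: Tensor | np.ndarray) -> Tensor:
        """Differentiable density evaluation; returns a Tensor of shape (N,).

        `z_sh`/`z_a` may be Tensors to let gradients reach the latent codes.
        The latent codes and the (per-call constant) encoded view direction
        enter through the first-layer weight blocks as broadcast bias vectors
        — algebraically identical to concatenating them to every input row,
        but without materializing the N-row concatenation.
        """
        cfg = self.config
        x = np.asarray(x_mm, dtype=np.float64).reshape(-1, 3)
        n = x.shape[0]
        if n == 0:
            raise ValueError("point batch must be nonempty")
        zsh = z_sh if isinstance(z_sh, Tensor) else Tensor(np.asarray(z_sh).ravel())
        if zsh.data.size != cfg.m_sh:
            raise ValueError(f"z_sh must have length {cfg.m_sh}")
        za = z_a if isinstance(z_a, Tensor) else Tensor(np.asarray(z_a).ravel())
        if za.data.size != cfg.m_a:
            raise ValueError(f"z_a must have length {cfg.m_a}")

        enc_x = Tensor(positional_encode(x / cfg.coord_scale_mm, cfg.enc_x))
        e_dim = cfg.enc_x.out_dim(3)

        l0 = self.h_net.layers[0]
        bias0 = zsh.reshape(1, -1) @ l0.w.rows(e_dim, e_dim + cfg.m_sh) + l0.b.reshape(1, -1)
        h = affine(enc_x, l0.w.rows(0, e_dim), bias0).relu()
        for layer in self.h_net.layers[1:]:
            h = affine(h, layer.w, layer.b).relu()

        d0 = self.d_net.layers[0]
        k = self.config.hidden_width
        bias1 = d0.b.reshape(1, -1)
        if cfg.view_conditioning:
            view_dir = -xi.source_position(1.0)
            enc_xi = positional_encode(view_dir, cfg.enc_xi).reshape(1, -1)
            xi_dim = cfg.enc_xi.out_dim(3)
            bias1 = bias1 + Tensor(enc_xi) @ d0.w.rows(k, k + xi_dim)
            k_za = k + xi_dim
        else:
            k_za = k
        bias1 = bias1 + za.reshape(1, -1) @ d0.w.rows(k_za, k_za + cfg.m_a)
        t = affine(h, d0.w.rows(0, cfg.hidden_width), bias1).relu()
        for i, layer in enumerate(self.d_net.layers[1:]):
            t = affine(t, layer.w, layer.b)
            if i < len(self.d_net.layers) - 2:
                t = t.relu()
        return t.softplus().reshape(-1)

    def __call__(self, x_mm: np.ndarray, xi: Pose, codes: LatentCodes) -> np.ndarray:
        return self.density_graph(x_mm, xi, codes.z_sh, codes.z_a).data.astype(np.float64)


def init_field(config: FieldConfig, rng: np.random.Generator) -> FieldParams:
    """Reproducible parameter initialization from an injected generator."""
    return FieldParams(config, rng)


def field_density(params: FieldParams, x: np.ndarray, xi: Pose, codes: LatentCodes) -> np.ndarray:
    """Densities delta >= 0 at a batch of 3D points (deterministic)."""
    return params(x, xi, codes)
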