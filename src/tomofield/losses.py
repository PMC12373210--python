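"""Loss terms for adversarial training and patient-specific fine-tuning.

The perceptual distance compares fixed convolutional features of two images or
volumes after intensity standardization.  The default feature extractor is a
deterministic, seeded random-weight convolutional stack (random perceptual
features are an established surrogate for pretrained backbones and keep the
package hermetic); any callable with the same signature can be plugged in,
including a pretrained network.

All losses accept either numpy arrays or autodiff Tensors; with Tensor inputs
gradients flow to the generator through the full graph.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, conv2d, conv3d

__all__ = [
    "FeatureExtractor",
    "standardize",
    "perceptual_loss",
    "hinge_loss_d",
    "hinge_loss_g",
    "dag_training_loss",
    "psnr_term",
    "inference_loss",
]

_EPS = 1e-8


def standardize(x: Tensor) -> Tensor:
    """Zero-mean / unit-variance intensity standardization (the pre-processing
    applied to both inputs of the perceptual distance)."""
    x = as_tensor(x)
    mu = x.mean()
    centered = x - mu
    std = ((centered * centered).mean() + _EPS) ** 0.5
    return centered / std


def standardize_per_sample(x: Tensor) -> Tensor:
    """Standardize each item of a batch (N, ...) independently."""
    x = as_tensor(x)
    n = x.shape[0]
    flat = x.reshape(n, -1)
    mu = flat.mean(axis=1, keepdims=True)
    centered = flat - mu
    std = ((centered * centered).mean(axis=1, keepdims=True) + _EPS) ** 0.5
    return (centered / std).reshape(*x.shape)


class FeatureExtractor:
    """Fixed (non-trainable) multi-layer convolutional feature map.

    `ndim` is 2 for patches/projections and 3 for sub-volumes; `tap` selects
    which layer's activations are returned.  Weights are drawn once from a
    seeded generator and never updated, so the map is deterministic.
    """

    def __init__(self, ndim: int = 2, channels: tuple[int, ...] = (8, 16),
                 k: int = 3, tap: int = -1, seed: int = 0):
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        rng = np.random.default_rng(seed)
        self.ndim = ndim
        self.tap = tap
        self.k = k
        self.weights: list[Tensor] = []
        c_in = 1
        for c_out in channels:
            fan_in = c_in * k**ndim
            shape = (c_out, c_in) + (k,) * ndim
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
            self.weights.append(Tensor(w))  # requires_grad False: frozen
            c_in = c_out
        self.n_layers = len(channels)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.data.ndim == self.ndim:
            feat = x.reshape(1, 1, *x.shape)
        elif x.data.ndim == self.ndim + 1:  # leading batch axis
            feat = x.reshape(x.shape[0], 1, *x.shape[1:])
        else:
            raise ValueError(f"expected a {self.ndim}D input, got shape {x.shape}")
        taps = []
        op = conv2d if self.ndim == 2 else conv3d
        for w in self.weights:
            feat = op(feat, w, stride=1, pad=self.k // 2).relu()
            taps.append(feat)
        return taps[self.tap]


def perceptual_loss(a, b, fx: FeatureExtractor | None = None,
                    standardize_inputs: bool = True) -> Tensor:
    """Mean squared distance between feature maps of (standardized) inputs.

    With ``fx=None`` the feature map is the identity, and with
    ``standardize_inputs=False`` the loss reduces to the plain mean squared
    difference of the inputs."""
    a = as_tensor(a)
    b = as_tensor(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if standardize_inputs:
        ga, tb = standardize(a), standardize(b)
    else:
        ga, tb = a, b
    if fx is not None:
        ga, tb = fx(ga), fx(tb)
    diff = ga - tb
    return (diff * diff).mean()


def hinge_loss_d(real_scores, fake_scores) -> Tensor:
    """Discriminator hinge: E[max(0, 1 + D(fake))] + E[max(0, 1 - D(real))]."""
    real = as_tensor(real_scores)
    fake = as_tensor(fake_scores)
    if real.size == 0 or fake.size == 0:
        raise ValueError("score sets must be nonempty")
    return (fake + 1.0).relu().mean() + (1.0 - real).relu().mean()


def hinge_loss_g(fake_scores) -> Tensor:
    """Generator-side hinge objective: -E[D(fake)]."""
    fake = as_tensor(fake_scores)
    if fake.size == 0:
        raise ValueError("score set must be nonempty")
    return -fake.mean()


def _combine(entry, lambda2: float):
    if isinstance(entry, (tuple, list)):
        l_rv, l_hv, l_rp, l_hp = entry
        return as_tensor(l_rv) + as_tensor(l_hv) + lambda2 * (as_tensor(l_rp) + as_tensor(l_hp))
    return as_tensor(entry)


def dag_training_loss(per_augmentation_losses, lambda1: float = 0.2,
                      lambda2: float = 0.5) -> Tensor:
    """Augmentation-combined training objective.

    `per_augmentation_losses` holds one entry per augmentation k = 0..n, with
    k = 0 the identity transformation.  Each entry is either an already
    combined scalar loss L(k), or a 4-tuple (L_r,V, L_h,V, L_r,P, L_h,P) that
    is combined as L(k) = L_r,V + L_h,V + lambda2 (L_r,P + L_h,P).  The total
    is L(0) + lambda1/(n-1) * sum_{k=1..n} L(k).
    """
    entries = list(per_augmentation_losses)
    n = len(entries) - 1
    if n < 2:
        raise ValueError("need at least two non-identity augmentations (n >= 2)")
    total = _combine(entries[0], lambda2)
    rest = _combine(entries[1], lambda2)
    for e in entries[2:]:
        rest = rest + _combine(e, lambda2)
    return total + (lambda1 / (n - 1)) * rest


def psnr_term(pred, ref, max_val: float = 1.0, stop_psnr: float = 25.0) -> Tensor:
    """Differentiable PSNR shortfall: max(0, stop_psnr - PSNR(pred, ref)).

    PSNR is unbounded above, so the raw negative PSNR has no minimum; clipping
    at the stopping threshold gives a term that vanishes exactly when the
    stopping rule is satisfied."""
    pred = as_tensor(pred)
    ref = as_tensor(ref)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    diff = pred - ref
    mse = (diff * diff).mean() + 1e-12
    psnr = (10.0 / np.log(10.0)) * ((max_val * max_val) / mse).log()
    return (stop_psnr - psnr).relu()


def inference_loss(pred_proj, ref_proj, fx: FeatureExtractor | None = None,
                   lambdas: tuple[float, float, float] = (0.3, 0.1, 0.3),
                   max_val: float = 1.0, stop_psnr: float = 25.0) -> Tensor:
    """Fine-tuning objective: perceptual + PSNR shortfall + Gaussian NLL.

    The negative log-likelihood term is a unit-variance Gaussian on pixel
    residuals (1/2 the mean squared error, constants dropped)."""
    pred = as_tensor(pred_proj)
    ref = as_tensor(ref_proj)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    l1, l2, l3 = lambdas
    diff = pred - ref
    nll = 0.5 * (diff * diff).mean()
    total = l2 * psnr_term(pred, ref, max_val=max_val, stop_psnr=stop_psnr) + l3 * nll
    if l1 != 0.0:
        total = total + l1 * perceptual_loss(pred, ref, fx)
    return total
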