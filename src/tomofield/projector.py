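"""Exact Siddon voxel traversal and X-ray projection rendering.

Two projection routes live here:

* :func:`siddon_trace` / :func:`line_integral` — exact per-voxel path lengths of
  a ray through a regular attenuation grid, the ground-truth route used to
  synthesize digitally reconstructed radiographs (DRRs).
* :func:`render_patch_from_field` — discrete X-ray line integral of a
  *continuous* density field over stratified ray bins (no optical opacity
  compositing); the generative route that must stay congruent with Siddon.

Axis convention: ``VoxelGrid.values[i, j, k]`` spans world x, y, z;
``origin_mm`` is the outer corner of voxel (0, 0, 0) and voxel centers sit at
``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import Pose, Ray, RayBundle, SourceSetup, rays_for_detector, stratified_sample

__all__ = [
    "VoxelGrid",
    "RayPathSegment",
    "SubVolumeSamples",
    "siddon_trace",
    "line_integral",
    "line_integrals",
    "make_drr",
    "render_patch_from_field",
    "trilinear_sample",
]


@dataclass
class VoxelGrid:
    """Discrete attenuation volume with spacing and origin (mm)."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.broadcast_to(np.asarray(self.spacing_mm, dtype=np.float64), (3,)).copy()
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with >= 1 voxel per axis")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")

    @classmethod
    def centered(cls, values: np.ndarray, spacing_mm) -> "VoxelGrid":
        """A grid whose physical center is the isocenter (origin)."""
        values = np.asarray(values)
        spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=np.float64), (3,))
        origin = -np.array(values.shape) * spacing / 2.0
        return cls(values, spacing, origin)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin_mm
        hi = self.origin_mm + np.array(self.dims) * self.spacing_mm
        return lo, hi

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.dims) * self.spacing_mm


@dataclass(frozen=True)
class RayPathSegment:
    voxel_index: tuple[int, int, int]
    length_mm: float


@dataclass
class SubVolumeSamples:
    """The point set V': stratified 3D sample positions along a ray bundle,
    their densities, and per-bin lengths.  Shapes are (R, Q[, 3])."""

    points_mm: np.ndarray
    densities: np.ndarray
    bin_lengths_mm: np.ndarray

    def lattice(self, shape: tuple[int, int]) -> np.ndarray:
        """Densities reshaped onto the (M, M, Q) ray-by-bin lattice."""
        q = self.densities.shape[1]
        return self.densities.reshape(shape[0], shape[1], q)


# ---------------------------------------------------------------------------
# Siddon traversal
# ---------------------------------------------------------------------------

def _crossing_params(grid: VoxelGrid, origins: np.ndarray, dirs: np.ndarray):
    """Sorted, box-clipped plane-crossing parameters per ray.

    Returns (alphas (N, K) sorted ascending and clipped to [amin, amax],
    amin, amax, valid-mask).  Zero-length intervals between equal clipped
    values correspond to degenerate crossings and carry no path length.
    """
    lo, hi = grid.bounds
    n = origins.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t0 = (lo[None, :] - origins) * inv
        t1 = (hi[None, :] - origins) * inv
    # axis-parallel components: inside the slab constrain nothing, outside
    # make the interval empty (entry parameter +inf beats every exit)
    par = np.abs(dirs) < 1e-300
    if par.any():
        inside = (origins >= lo[None, :]) & (origins <= hi[None, :])
        t0 = np.where(par, np.where(inside, -np.inf, np.inf), t0)
        t1 = np.where(par, np.inf, t1)
    amin = np.maximum(np.minimum(t0, t1).max(axis=1), 0.0)
    amax = np.maximum(t0, t1).min(axis=1)
    valid = amax > amin

    pieces = [amin[:, None], amax[:, None]]
    for ax in range(3):
        planes = lo[ax] + grid.spacing_mm[ax] * np.arange(grid.dims[ax] + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (planes[None, :] - origins[:, ax : ax + 1]) / dirs[:, ax : ax + 1]
        a = np.where(np.isfinite(a), a, np.inf)
        pieces.append(a)
    alphas = np.concatenate(pieces, axis=1)
    safe_min = np.where(valid, amin, 0.0)
    safe_max = np.where(valid, amax, 0.0)
    alphas = np.clip(alphas, safe_min[:, None], safe_max[:, None])
    alphas.sort(axis=1)
    return alphas, amin, amax, valid


def _segment_lengths_indices(grid: VoxelGrid, origins: np.ndarray, dirs: np.ndarray):
    alphas, amin, amax, valid = _crossing_params(grid, origins, dirs)
    lengths = np.diff(alphas, axis=1)
    np.maximum(lengths, 0.0, out=lengths)
    mids = 0.5 * (alphas[:, :-1] + alphas[:, 1:])
    lo, _ = grid.bounds
    pts = origins[:, None, :] + mids[:, :, None] * dirs[:, None, :]
    idx = np.floor((pts - lo[None, None, :]) / grid.spacing_mm[None, None, :]).astype(np.int64)
    for ax in range(3):
        np.clip(idx[:, :, ax], 0, grid.dims[ax] - 1, out=idx[:, :, ax])
    lengths[~valid, :] = 0.0
    return lengths, idx, valid


def siddon_trace(grid: VoxelGrid, ray: Ray) -> list[RayPathSegment]:
    """Ordered per-voxel chord lengths of one ray through the grid.

    Coincident plane crossings (edge/corner hits) produce zero-length
    intervals which are dropped; consecutive intervals falling in the same
    voxel are merged so every traversed voxel appears exactly once.
    """
    d = np.asarray(ray.direction, dtype=np.float64)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("ray direction must be unit-norm")
    o = np.asarray(ray.origin_mm, dtype=np.float64)[None, :]
    lengths, idx, valid = _segment_lengths_indices(grid, o, d[None, :])
    if not valid[0]:
        return []
    segs: list[RayPathSegment] = []
    for ln, (i, j, k) in zip(lengths[0], idx[0]):
        if ln <= 1e-12:
            continue
        key = (int(i), int(j), int(k))
        if segs and segs[-1].voxel_index == key:
            segs[-1] = RayPathSegment(key, segs[-1].length_mm + float(ln))
        else:
            segs.append(RayPathSegment(key, float(ln)))
    return segs


def line_integrals(grid: VoxelGrid, bundle: RayBundle, chunk: int = 2048) -> np.ndarray:
    """Siddon line integrals (value * mm) for every ray in a bundle."""
    n = len(bundle)
    out = np.zeros(n)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        lengths, idx, valid = _segment_lengths_indices(
            grid, bundle.origins[s:e], bundle.directions[s:e]
        )
        vals = grid.values[idx[:, :, 0], idx[:, :, 1], idx[:, :, 2]]
        out[s:e] = (vals * lengths).sum(axis=1)
    return out


def line_integral(grid: VoxelGrid, ray: Ray) -> float:
    """Exact line integral of the voxel field along one ray (0 for a miss)."""
    segs = siddon_trace(grid, ray)
    return float(sum(grid.values[s.voxel_index] * s.length_mm for s in segs))


def make_drr(grid: VoxelGrid, setup: SourceSetup, pose: Pose,
             normalize: bool = True, return_scale: bool = False,
             beer_lambert: bool = False):
    """Digitally reconstructed radiograph: Siddon integrals over the full
    detector, min-max normalized to [0, 1] (a constant image maps to zeros).

    `beer_lambert` maps the raw integrals through exp(-x) (transmission
    image) before normalization; off by default — the linear integral is the
    supervised quantity throughout the package."""
    bundle = rays_for_detector(setup, pose, bounds=grid.bounds)
    raw = line_integrals(grid, bundle).reshape(setup.det_rows, setup.det_cols)
    if beer_lambert:
        raw = np.exp(-raw)
    lo, hi = float(raw.min()), float(raw.max())
    if not normalize:
        img = raw
    elif hi > lo:
        img = (raw - lo) / (hi - lo)
    else:
        img = np.zeros_like(raw)
    if return_scale:
        return img, (lo, hi)
    return img


def render_patch_from_field(field_fn, rays: RayBundle, q: int,
                            rng: np.random.Generator) -> tuple[np.ndarray, SubVolumeSamples]:
    """Discrete X-ray line integral of a continuous density field.

    Each pixel is sum_i density(x_i) * dt_i over the ray's stratified bins —
    straight attenuation accumulation, with no opacity compositing.  Returns
    the rendered image (in the bundle's shape) and the sampled point set V'.
    """
    t, dt = stratified_sample(rays, q, rng)
    pts = rays.origins[:, None, :] + t[:, :, None] * rays.directions[:, None, :]
    dens = np.asarray(field_fn(pts.reshape(-1, 3)), dtype=np.float64).reshape(t.shape)
    image = (dens * dt).sum(axis=1).reshape(rays.shape)
    return image, SubVolumeSamples(pts, dens, dt)


def trilinear_sample(grid: VoxelGrid, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the voxel field at world points (mm).

    Points outside the grid return 0 (the surrounding air)."""
    pts = np.asarray(points_mm, dtype=np.float64)
    coords = (pts - grid.origin_mm[None, :]) / grid.spacing_mm[None, :] - 0.5
    return map_coordinates(grid.values, coords.T, order=1, mode="constant", cval=0.0)
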