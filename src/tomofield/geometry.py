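"""Cone-beam acquisition geometry: source/detector model, poses, patch patterns, rays.

Conventions (fixed for reproducibility):

* Right-handed world frame, isocenter at the origin, lengths in mm.
* The anterior-posterior (AP) view is azimuth ``theta = 0`` with the source on
  the +y axis; azimuth rotates about z (the axial/vertical rotation axis);
  ``phi`` is elevation off the axial plane.
* The central ray always points from the source to the origin; the detector is
  perpendicular to it at distance ``sid_mm`` from the source.
* Detector coordinates are continuous, 0-based, pixel-center sampled:
  column ``u`` increases along the detector's horizontal axis, row ``v``
  downward from the top row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceSetup",
    "Pose",
    "PatchPattern",
    "Ray",
    "RayBundle",
    "make_circular_poses",
    "sample_patch_pattern",
    "rays_for_patch",
    "rays_for_detector",
    "stratified_sample",
    "fit_detector_pitch",
]


@dataclass(frozen=True)
class SourceSetup:
    """Cone-beam source/detector configuration.

    sad_mm : source-to-axis (isocenter) distance, d1
    sid_mm : source-to-image (detector) distance, d2; magnification is sid/sad
    det_rows, det_cols : detector pixel counts H, W
    det_pitch_mm : detector pixel spacing (both axes)
    """

    sad_mm: float = 570.0
    sid_mm: float = 1040.0
    det_rows: int = 128
    det_cols: int = 128
    det_pitch_mm: float = 4.7

    def __post_init__(self):
        if self.sad_mm <= 0:
            raise ValueError("sad_mm must be > 0")
        if self.sid_mm <= self.sad_mm:
            raise ValueError("sid_mm must exceed sad_mm")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError("detector must have at least one pixel per axis")
        if self.det_pitch_mm <= 0:
            raise ValueError("det_pitch_mm must be > 0")

    @property
    def magnification(self) -> float:
        return self.sid_mm / self.sad_mm


def fit_detector_pitch(sad_mm: float, sid_mm: float, n_pixels: int,
                       object_extent_mm: float, margin: float = 0.10) -> float:
    """Pixel pitch so the detector spans the magnified object plus a margin."""
    return (1.0 + margin) * object_extent_mm * (sid_mm / sad_mm) / n_pixels


@dataclass(frozen=True)
class Pose:
    """View direction on the source ring; the source always faces the origin."""

    theta_deg: float = 0.0
    phi_deg: float = 0.0

    def source_position(self, sad_mm: float) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        ph = np.deg2rad(self.phi_deg)
        return sad_mm * np.array(
            [-np.sin(th) * np.cos(ph), np.cos(th) * np.cos(ph), np.sin(ph)]
        )

    def frame(self, setup: SourceSetup) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(source, central direction, detector u-axis, detector v-axis)."""
        src = self.source_position(setup.sad_mm)
        c = -src / np.linalg.norm(src)
        z = np.array([0.0, 0.0, 1.0])
        u = np.cross(c, z)
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError("degenerate pose: central ray parallel to the rotation axis")
        u /= nu
        v = np.cross(u, c)
        return src, c, u, v


@dataclass(frozen=True)
class PatchPattern:
    """GRAF-style sparse patch: an s-dilated M x M pixel lattice on the detector.

    center_uv : continuous (col, row) detector coordinates of the patch center
    scale_s   : dilation of the inter-pixel stride (s = 1 is a contiguous crop)
    size_m    : patch side M
    """

    center_uv: tuple[float, float]
    scale_s: float = 1.0
    size_m: int = 32

    def __post_init__(self):
        if self.scale_s < 1.0:
            raise ValueError("scale_s must be >= 1")
        if self.size_m < 1:
            raise ValueError("size_m must be >= 1")

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(cols, rows) arrays of shape (M, M), row-major patch ordering."""
        m = self.size_m
        offs = (np.arange(m) - (m - 1) / 2.0) * self.scale_s
        u0, v0 = self.center_uv
        rows = v0 + offs[:, None] + np.zeros((1, m))
        cols = u0 + offs[None, :] + np.zeros((m, 1))
        return cols, rows

    def validate(self, setup: SourceSetup) -> None:
        cols, rows = self.pixel_coords()
        if (cols.min() < -1e-9 or cols.max() > setup.det_cols - 1 + 1e-9
                or rows.min() < -1e-9 or rows.max() > setup.det_rows - 1 + 1e-9):
            raise ValueError("patch footprint exceeds the detector domain")


@dataclass(frozen=True)
class Ray:
    """A single cone-beam ray with its bounding-box parameter interval (mm)."""

    origin_mm: np.ndarray
    direction: np.ndarray
    t_near: float = 0.0
    t_far: float = np.inf
    valid: bool = True


class RayBundle:
    """A row-major collection of rays sharing one source point (cone beam)."""

    def __init__(self, origins: np.ndarray, directions: np.ndarray, shape: tuple[int, ...]):
        self.origins = np.asarray(origins, dtype=np.float64)
        self.directions = np.asarray(directions, dtype=np.float64)
        n = self.origins.shape[0]
        self.t_near = np.zeros(n)
        self.t_far = np.full(n, np.inf)
        self.valid = np.ones(n, dtype=bool)
        self.shape = shape

    def __len__(self) -> int:
        return self.origins.shape[0]

    def __getitem__(self, i: int) -> Ray:
        return Ray(self.origins[i], self.directions[i],
                   float(self.t_near[i]), float(self.t_far[i]), bool(self.valid[i]))

    def clip_to_box(self, lo: np.ndarray, hi: np.ndarray) -> "RayBundle":
        """Slab-intersect every ray with the axis-aligned box [lo, hi] (in place)."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / self.directions
            t0 = (lo[None, :] - self.origins) * inv
            t1 = (hi[None, :] - self.origins) * inv
        # axis-parallel rays: inside the slab -> (-inf, inf); outside -> empty
        # (both entries +inf so the entry parameter exceeds every exit)
        par = np.abs(self.directions) < 1e-300
        if par.any():
            inside = (self.origins >= lo[None, :]) & (self.origins <= hi[None, :])
            t0 = np.where(par, np.where(inside, -np.inf, np.inf), t0)
            t1 = np.where(par, np.inf, t1)
        tmin = np.minimum(t0, t1).max(axis=1)
        tmax = np.maximum(t0, t1).min(axis=1)
        self.t_near = np.maximum(tmin, 0.0)
        self.t_far = tmax
        self.valid = self.t_far > self.t_near
        self.t_near[~self.valid] = 0.0
        self.t_far[~self.valid] = 0.0
        return self


def make_circular_poses(n_views: int, start_deg: float = 0.0) -> list[Pose]:
    """Equally spaced azimuths on the axial source ring, starting at `start_deg`."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    step = 360.0 / n_views
    return [Pose(theta_deg=start_deg + k * step, phi_deg=0.0) for k in range(n_views)]


def sample_patch_pattern(rng: np.random.Generator, setup: SourceSetup, size_m: int) -> PatchPattern:
    """Draw v = (u, s): scale uniform on [1, min(H,W)/M], center uniform over the
    admissible sub-domain that keeps the s-dilated footprint on the detector."""
    if size_m > min(setup.det_rows, setup.det_cols):
        raise ValueError("patch size exceeds detector")
    s_max = min(setup.det_rows, setup.det_cols) / size_m
    s = float(rng.uniform(1.0, s_max)) if s_max > 1.0 else 1.0
    half = s * (size_m - 1) / 2.0
    u_lo, u_hi = half, (setup.det_cols - 1) - half
    v_lo, v_hi = half, (setup.det_rows - 1) - half
    u = float(rng.uniform(u_lo, u_hi)) if u_hi > u_lo else (setup.det_cols - 1) / 2.0
    v = float(rng.uniform(v_lo, v_hi)) if v_hi > v_lo else (setup.det_rows - 1) / 2.0
    return PatchPattern(center_uv=(u, v), scale_s=s, size_m=size_m)


def _rays_through_detector_coords(setup: SourceSetup, pose: Pose,
                                  cols: np.ndarray, rows: np.ndarray,
                                  shape: tuple[int, ...]) -> RayBundle:
    src, c, u_ax, v_ax = pose.frame(setup)
    det_center = src + setup.sid_mm * c
    du = (cols - (setup.det_cols - 1) / 2.0) * setup.det_pitch_mm
    dv = ((setup.det_rows - 1) / 2.0 - rows) * setup.det_pitch_mm
    pts = (det_center[None, :]
           + du.reshape(-1, 1) * u_ax[None, :]
           + dv.reshape(-1, 1) * v_ax[None, :])
    dirs = pts - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    origins = np.broadcast_to(src, dirs.shape).copy()
    return RayBundle(origins, dirs, shape)


def rays_for_patch(setup: SourceSetup, pose: Pose, pattern: PatchPattern,
                   bounds: tuple[np.ndarray, np.ndarray] | None = None) -> RayBundle:
    """One ray per patch pixel (row-major M x M), source through the s-dilated
    pixel centers on the detector plane; optionally clipped to a bounding box."""
    pattern.validate(setup)
    cols, rows = pattern.pixel_coords()
    bundle = _rays_through_detector_coords(setup, pose, cols, rows,
                                           (pattern.size_m, pattern.size_m))
    if bounds is not None:
        bundle.clip_to_box(*bounds)
    else:
        bundle.t_far = np.full(len(bundle), setup.sid_mm, dtype=np.float64)
    return bundle


def rays_for_detector(setup: SourceSetup, pose: Pose,
                      bounds: tuple[np.ndarray, np.ndarray] | None = None) -> RayBundle:
    """A ray per detector pixel (H x W, row-major)."""
    rr, cc = np.meshgrid(np.arange(setup.det_rows, dtype=np.float64),
                         np.arange(setup.det_cols, dtype=np.float64), indexing="ij")
    bundle = _rays_through_detector_coords(setup, pose, cc, rr,
                                           (setup.det_rows, setup.det_cols))
    if bounds is not None:
        bundle.clip_to_box(*bounds)
    else:
        bundle.t_far = np.full(len(bundle), setup.sid_mm, dtype=np.float64)
    return bundle


def stratified_sample(ray, q: int, rng: np.random.Generator):
    """Stratified positions along [t_near, t_far]: q equal bins, one uniform
    draw per bin.  Accepts a single Ray (returns (t, dt) of shape (q,)) or a
    RayBundle (shapes (R, q)).  Empty-interval rays yield empty/zero bins."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if isinstance(ray, Ray):
        if not ray.valid or ray.t_far <= ray.t_near:
            return np.empty(0), np.empty(0)
        edges = np.linspace(ray.t_near, ray.t_far, q + 1)
        dt = np.diff(edges)
        t = edges[:-1] + rng.uniform(size=q) * dt
        return t, dt
    bundle: RayBundle = ray
    n = len(bundle)
    frac = np.linspace(0.0, 1.0, q + 1)[None, :]
    edges = bundle.t_near[:, None] + (bundle.t_far - bundle.t_near)[:, None] * frac
    edges[:, 0] = bundle.t_near
    edges[:, -1] = bundle.t_far
    dt = np.diff(edges, axis=1)
    t = edges[:, :-1] + rng.uniform(size=(n, q)) * dt
    return t, dt
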