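"""Procedural thorax-like phantoms and paired multi-view projection datasets.

The generator stands in for a clinical training cohort: each "patient" is a
piecewise-smooth composition of ellipsoids — a soft-tissue body containing two
low-attenuation lungs, a high-attenuation spine-like cylinder, up to three
tumor spheres inside the lungs and (occasionally) a very dense pacemaker-like
blob — voxelized on a seeded grid with values in [0, 1] and projected to
cone-beam DRRs on a full 360 degree ring.  Everything is fully determined by
the injected random generator.

Intensity semantics follow normalized CT: 0 is air, 0.5 water/soft tissue;
:func:`tomofield.metrics.to_hounsfield` maps to HU for RMSE reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Pose, SourceSetup, fit_detector_pitch, make_circular_poses
from .projector import VoxelGrid, make_drr

__all__ = [
    "PatientCase",
    "SparseViewDataset",
    "make_phantom",
    "make_dataset",
    "voxelized_sphere",
    "default_setup",
]

# tissue values on the normalized [0, 1] scale
_BODY, _LUNG, _SPINE, _TUMOR, _DEVICE = 0.50, 0.12, 0.85, 0.65, 0.95


def default_setup(det_pixels: int, object_extent_mm: float = 300.0,
                  sad_mm: float = 570.0, sid_mm: float = 1040.0) -> SourceSetup:
    """Geometry whose detector subtends the magnified object with 10% margin."""
    pitch = fit_detector_pitch(sad_mm, sid_mm, det_pixels, object_extent_mm)
    return SourceSetup(sad_mm=sad_mm, sid_mm=sid_mm, det_rows=det_pixels,
                       det_cols=det_pixels, det_pitch_mm=pitch)


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_phantom(rng: np.random.Generator, dims: int = 64, complexity: float = 1.0,
                 extent_mm: float = 300.0, return_masks: bool = False):
    """A seeded thorax-like attenuation volume (values in [0, 1]).

    `complexity` scales how many incidental features (tumors, device) are
    drawn; 0 gives the bare body/lungs/spine composition.
    """
    if dims < 8:
        raise ValueError("dims must be >= 8 per axis")
    spacing = extent_mm / dims
    c = (np.arange(dims) + 0.5) / dims * 2.0 - 1.0  # normalized [-1, 1]
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    coords = (x, y, z)

    vol = np.zeros((dims, dims, dims))
    jit = lambda lo, hi: float(rng.uniform(lo, hi))

    body_ax = (jit(0.78, 0.88), jit(0.58, 0.68), jit(0.88, 0.96))
    body = _ellipsoid_mask(coords, (0.0, jit(-0.04, 0.04), 0.0), body_ax)
    vol[body] = _BODY

    lungs = np.zeros_like(body)
    for side in (-1.0, 1.0):
        lung = _ellipsoid_mask(
            coords,
            (side * jit(0.33, 0.40), jit(-0.12, -0.02), jit(-0.05, 0.05)),
            (jit(0.24, 0.30), jit(0.30, 0.38), jit(0.55, 0.68)),
        )
        lungs |= lung & body
    vol[lungs] = _LUNG

    # spine: posterior high-density cylinder along z (posterior is +y here,
    # behind the isocenter as seen from the theta=0 anterior source)
    spine_r = jit(0.07, 0.10)
    spine_y = jit(0.42, 0.50)
    spine = (x**2 + (y - spine_y) ** 2 <= spine_r**2) & body
    vol[spine] = _SPINE

    tumor_mask = np.zeros_like(body)
    n_tumors = int(rng.integers(0, max(int(round(3 * complexity)), 0) + 1))
    lung_idx = np.argwhere(lungs)
    placed = 0
    attempts = 0
    while placed < n_tumors and attempts < 50 and lung_idx.size:
        attempts += 1
        center_idx = lung_idx[rng.integers(len(lung_idx))]
        center = tuple(c[i] for i in center_idx)
        r = jit(0.05, 0.11)
        sphere = _ellipsoid_mask(coords, center, (r, r, r))
        if not (sphere & ~lungs).any():  # keep tumors wholly inside the lungs
            tumor_mask |= sphere
            placed += 1
    vol[tumor_mask] = _TUMOR

    device_mask = np.zeros_like(body)
    if complexity > 0 and rng.uniform() < 0.3:
        r = jit(0.05, 0.08)
        device_mask = _ellipsoid_mask(
            coords, (jit(-0.45, -0.3), jit(-0.5, -0.38), jit(0.35, 0.55)),
            (r, r, 0.6 * r)) & body
        vol[device_mask] = _DEVICE

    vol = gaussian_filter(vol, sigma=0.6)
    np.clip(vol, 0.0, 1.0, out=vol)
    grid = VoxelGrid.centered(vol, spacing)
    if return_masks:
        return grid, {"body": body, "lungs": lungs, "spine": spine,
                      "tumors": tumor_mask, "device": device_mask}
    return grid


@dataclass
class PatientCase:
    """One phantom with its multi-view DRR stack and pose metadata."""

    volume: VoxelGrid
    projections: np.ndarray            # (n_views, H, W), each min-max in [0, 1]
    poses: list[Pose]
    proj_scales: list[tuple[float, float]]  # raw-integral (min, max) per view
    setup: SourceSetup


@dataclass
class SparseViewDataset:
    patients: list[PatientCase] = dc_field(default_factory=list)

    @property
    def setup(self) -> SourceSetup:
        return self.patients[0].setup

    def all_poses(self) -> list[Pose]:
        return [p for pat in self.patients for p in pat.poses]


def make_dataset(rng: np.random.Generator, n_patients: int = 1, dims: int = 64,
                 n_views: int = 72, every_deg: float | None = None,
                 extent_mm: float = 300.0, complexity: float = 1.0,
                 setup: SourceSetup | None = None) -> SparseViewDataset:
    """Phantom cohort with circular-ring DRRs (default 72 views, one per 5 deg).

    `every_deg`, when given, overrides `n_views` as 360/every_deg."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if every_deg is not None:
        n_views = int(round(360.0 / every_deg))
    if setup is None:
        setup = default_setup(dims, extent_mm)
    poses = make_circular_poses(n_views, start_deg=0.0)
    patients = []
    for _ in range(n_patients):
        grid = make_phantom(rng, dims=dims, complexity=complexity, extent_mm=extent_mm)
        projs = np.empty((n_views, setup.det_rows, setup.det_cols))
        scales = []
        for i, pose in enumerate(poses):
            img, scale = make_drr(grid, setup, pose, normalize=True, return_scale=True)
            projs[i] = img
            scales.append(scale)
        patients.append(PatientCase(grid, projs, list(poses), scales, setup))
    return SparseViewDataset(patients)


def voxelized_sphere(dims: int = 64, extent_mm: float = 260.0, radius_mm: float = 110.0,
                     supersample: int = 4, value: float = 1.0) -> VoxelGrid:
    """Anti-aliased (supersampled partial-volume) centered sphere, for
    validating projections against the analytic chord-length image."""
    spacing = extent_mm / dims
    fine = dims * supersample
    c = (np.arange(fine) + 0.5) * spacing / supersample - extent_mm / 2.0
    xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
    occ = (xx**2 + yy**2 + zz**2 <= radius_mm**2).astype(np.float64) * value
    occ = occ.reshape(dims, supersample, dims, supersample, dims, supersample).mean(axis=(1, 3, 5))
    return VoxelGrid.centered(occ, spacing)
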