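"""Readers/writers: volumes (NIfTI or raw+JSON), projection stacks (TIFF+JSON),
field checkpoints (NPZ), geometry configs (YAML) and dataset manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .field import EncodingSpec, FieldConfig, FieldParams, LatentCodes
from .geometry import Pose, SourceSetup
from .phantom import PatientCase, SparseViewDataset
from .projector import VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_projection_stack",
    "write_projection_stack",
    "save_checkpoint",
    "load_checkpoint",
    "load_geometry",
    "geometry_hash",
    "write_dataset",
    "read_dataset",
    "dataset_manifest",
]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(grid: VoxelGrid, path) -> None:
    """NIfTI (.nii/.nii.gz) with spacing+origin in the affine, or .npy with a
    JSON sidecar; values stored as float32."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(grid.spacing_mm)
        affine[:3, 3] = grid.origin_mm + 0.5 * grid.spacing_mm  # center of voxel (0,0,0)
        nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), str(path))
    elif path.suffix == ".npy":
        np.save(path, grid.values.astype(np.float32))
        meta = {"spacing_mm": grid.spacing_mm.tolist(), "origin_mm": grid.origin_mm.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path) -> VoxelGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.diag(affine)[:3].copy()
        origin = affine[:3, 3] - 0.5 * spacing
        return VoxelGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
    if path.suffix == ".npy":
        meta = json.loads(path.with_suffix(".json").read_text())
        return VoxelGrid(np.load(path).astype(np.float64),
                         np.asarray(meta["spacing_mm"]), np.asarray(meta["origin_mm"]))
    raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# projection stacks
# ---------------------------------------------------------------------------

def write_projection_stack(images: np.ndarray, poses: list[Pose], setup: SourceSetup,
                           path_tiff, scales=None, normalized: bool = True) -> None:
    """Multi-page float32 TIFF plus a sidecar JSON with per-view poses,
    geometry and the recorded normalization."""
    path_tiff = Path(path_tiff)
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3 or images.shape[0] != len(poses):
        raise ValueError("images must be (n_views, H, W) matching poses")
    tifffile.imwrite(path_tiff, images, photometric="minisblack")
    manifest = {
        "geometry": dataclasses.asdict(setup),
        "poses": [dataclasses.asdict(p) for p in poses],
        "normalized": bool(normalized),
        "scales": [list(map(float, s)) for s in scales] if scales is not None else None,
    }
    path_tiff.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_projection_stack(path) -> tuple[np.ndarray, list[Pose], SourceSetup, dict]:
    """Read a TIFF stack (or a directory holding exactly one) + pose manifest."""
    path = Path(path)
    if path.is_dir():
        cands = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not cands:
            raise ValueError(f"no TIFF stacks found in {path}")
        path = cands[0]
    if not path.exists():
        raise FileNotFoundError(f"projection stack not found: {path}")
    images = np.asarray(tifffile.imread(path), dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    manifest = json.loads(path.with_suffix(".json").read_text())
    poses = [Pose(**p) for p in manifest["poses"]]
    if len(poses) != images.shape[0]:
        raise ValueError(
            f"pose/image count mismatch: {len(poses)} poses vs {images.shape[0]} images")
    setup = SourceSetup(**manifest["geometry"])
    return images, poses, setup, manifest


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _field_config_dict(cfg: FieldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _field_config_from_dict(d: dict) -> FieldConfig:
    d = dict(d)
    d["enc_x"] = EncodingSpec(**d["enc_x"])
    d["enc_xi"] = EncodingSpec(**d["enc_xi"])
    return FieldConfig(**d)


def save_checkpoint(path, params: FieldParams, codes: LatentCodes,
                    setup: SourceSetup | None = None, extra: dict | None = None) -> None:
    """Single-file NPZ archive: weights, field config, codes, geometry hash."""
    meta = {
        "version": 1,
        "config": _field_config_dict(params.config),
        "geometry_hash": geometry_hash(setup) if setup is not None else None,
        "extra": extra or {},
    }
    arrays = {f"w{i}": a for i, a in enumerate(params.state_arrays())}
    np.savez(path, z_sh=codes.z_sh, z_a=codes.z_a,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[FieldParams, LatentCodes, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        cfg = _field_config_from_dict(meta["config"])
        params = FieldParams(cfg, np.random.default_rng(0))
        n = len(params.parameters())
        params.load_state_arrays([npz[f"w{i}"] for i in range(n)])
        codes = LatentCodes(npz["z_sh"], npz["z_a"])
    return params, codes, meta


# ---------------------------------------------------------------------------
# geometry config / manifests
# ---------------------------------------------------------------------------

def load_geometry(path) -> tuple[SourceSetup, int, float]:
    """YAML geometry block -> (SourceSetup, n_views, start_deg)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    setup = SourceSetup(
        sad_mm=float(cfg.get("sad_mm", 570.0)),
        sid_mm=float(cfg.get("sid_mm", 1040.0)),
        det_rows=int(cfg.get("det_rows", 128)),
        det_cols=int(cfg.get("det_cols", 128)),
        det_pitch_mm=float(cfg.get("det_pitch_mm", 4.7)),
    )
    return setup, int(cfg.get("n_views", 72)), float(cfg.get("start_deg", 0.0))


def geometry_hash(setup: SourceSetup) -> str:
    payload = json.dumps(dataclasses.asdict(setup), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def dataset_manifest(ds: SparseViewDataset) -> dict:
    """Deterministic description of a dataset (used for reproducibility hashes)."""
    patients = []
    for pat in ds.patients:
        patients.append({
            "volume_sha": hashlib.sha256(
                np.ascontiguousarray(pat.volume.values.astype(np.float32)).tobytes()
            ).hexdigest()[:16],
            "dims": list(pat.volume.dims),
            "spacing_mm": pat.volume.spacing_mm.tolist(),
            "poses": [dataclasses.asdict(p) for p in pat.poses],
            "proj_scales": [list(map(float, s)) for s in pat.proj_scales],
            "proj_sha": hashlib.sha256(
                np.ascontiguousarray(pat.projections.astype(np.float32)).tobytes()
            ).hexdigest()[:16],
        })
    manifest = {"geometry": dataclasses.asdict(ds.setup), "patients": patients}
    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    return manifest


def write_dataset(ds: SparseViewDataset, out_dir) -> Path:
    """Write NIfTI volumes, TIFF projection stacks and a linking manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pat in enumerate(ds.patients):
        vpath = out / f"patient{i:03d}_volume.nii.gz"
        ppath = out / f"patient{i:03d}_projections.tif"
        write_volume(pat.volume, vpath)
        write_projection_stack(pat.projections, pat.poses, pat.setup, ppath,
                               scales=pat.proj_scales)
        entries.append({"volume": vpath.name, "projections": ppath.name})
    manifest = dataset_manifest(ds)
    manifest["files"] = entries
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(in_dir) -> SparseViewDataset:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    patients = []
    for entry in manifest["files"]:
        grid = read_volume(in_dir / entry["volume"])
        images, poses, setup, pm = read_projection_stack(in_dir / entry["projections"])
        scales = [tuple(s) for s in (pm.get("scales") or [(0.0, 1.0)] * len(poses))]
        patients.append(PatientCase(grid, images, poses, scales, setup))
    return SparseViewDataset(patients)
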