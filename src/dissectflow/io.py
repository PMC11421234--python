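"""Dataset layout: NIfTI volumes plus a JSON sidecar.

A scan directory holds one 4D NIfTI per velocity component (``vel_x.nii.gz``
etc., cm/s), a 4D magnitude volume, uint8 masks, and ``scan.json`` with venc,
timing and provenance metadata.  The phantom writes this layout and the
pipeline reads it, so synthetic and real data share one ingestion path.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LumenMasks, MagnitudeSeries, VelocityField4D, VoxelGrid
from .geometry import CenterlinePlanes

__all__ = [
    "write_scan",
    "read_scan",
    "write_centerline_csv",
    "read_centerline_csv",
]

_COMPONENT_FILES = {"vx": "vel_x.nii.gz", "vy": "vel_y.nii.gz", "vz": "vel_z.nii.gz"}
_MASK_FILES = {
    "whole": "mask_whole.nii.gz",
    "tl": "mask_tl.nii.gz",
    "fl": "mask_fl.nii.gz",
    "static_tissue": "mask_static.nii.gz",
}


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    return VoxelGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=tuple(float(aff[a, a]) for a in range(3)),
        origin=tuple(float(aff[a, 3]) for a in range(3)),
    )


def write_scan(
    out_dir: str | Path,
    field: VelocityField4D,
    magnitude: MagnitudeSeries | None = None,
    masks: LumenMasks | None = None,
    extra_metadata: dict | None = None,
) -> Path:
    """Write a scan directory (NIfTI volumes + ``scan.json`` sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.grid)
    for name, fname in _COMPONENT_FILES.items():
        data = getattr(field, name).astype(np.float32)
        nib.save(nib.Nifti1Image(data, aff), out / fname)
    if magnitude is not None:
        nib.save(
            nib.Nifti1Image(magnitude.magnitude.astype(np.float32), aff),
            out / "magnitude.nii.gz",
        )
    if masks is not None:
        for name, fname in _MASK_FILES.items():
            nib.save(
                nib.Nifti1Image(getattr(masks, name).astype(np.uint8), aff),
                out / fname,
            )
    meta = {
        "venc_cm_s": field.venc,
        "temporal_resolution_ms": field.temporal_resolution,
        "rr_interval_ms": field.rr_interval,
        "gating_mode": field.gating_mode,
        "n_timepoints": field.n_timepoints,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    (out / "scan.json").write_text(json.dumps(meta, indent=2))
    return out


def read_scan(
    scan_dir: str | Path,
) -> tuple[VelocityField4D, MagnitudeSeries | None, LumenMasks | None, dict]:
    """Read a scan directory written by :func:`write_scan`."""
    d = Path(scan_dir)
    meta = json.loads((d / "scan.json").read_text())
    comps = {}
    grid = None
    for name, fname in _COMPONENT_FILES.items():
        img = nib.load(d / fname)
        if grid is None:
            grid = _grid_from_img(img)
        comps[name] = np.asarray(img.dataobj, dtype=float)
    field = VelocityField4D(
        vx=comps["vx"], vy=comps["vy"], vz=comps["vz"], grid=grid,
        venc=meta["venc_cm_s"],
        temporal_resolution=meta["temporal_resolution_ms"],
        rr_interval=meta["rr_interval_ms"],
        gating_mode=meta.get("gating_mode", "retrospective"),
    )
    magnitude = None
    if (d / "magnitude.nii.gz").exists():
        magnitude = MagnitudeSeries(
            magnitude=np.asarray(nib.load(d / "magnitude.nii.gz").dataobj, dtype=float),
            grid=grid,
        )
    masks = None
    if (d / _MASK_FILES["whole"]).exists():
        arrays = {
            name: np.asarray(nib.load(d / fname).dataobj) > 0
            for name, fname in _MASK_FILES.items()
            if (d / fname).exists()
        }
        masks = LumenMasks(**arrays)
    return field, magnitude, masks, meta


def write_centerline_csv(path: str | Path, centerline: CenterlinePlanes) -> None:
    df = pd.DataFrame(
        np.column_stack(
            [centerline.points, centerline.tangents, centerline.arc_length]
        ),
        columns=["x", "y", "z", "tx", "ty", "tz", "arc_length"],
    )
    df.to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> CenterlinePlanes:
    df = pd.read_csv(path)
    return CenterlinePlanes(
        points=df[["x", "y", "z"]].to_numpy(),
        tangents=df[["tx", "ty", "tz"]].to_numpy(),
        arc_length=df["arc_length"].to_numpy(),
    )
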