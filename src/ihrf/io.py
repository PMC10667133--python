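"""Readers and writers for the pipeline's on-disk formats.

Volumes and slab stacks travel as multi-page TIFF (one page per B-scan or
per slab); surfaces and all tables are CSV; every artifact may carry a JSON
provenance sidecar (seed, config hash, package version).  Depth convention
in every file: z is a 0-based voxel index increasing posteriorly (from the
vitreous toward the RPE/choroid).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .detection import IHRFTable
from .slabs import N_SLABS, SlabStack, SurfacePair
from .volume import OCTVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_surfaces",
    "read_surfaces",
    "write_slab_stack",
    "read_slab_stack",
    "write_ihrf_table",
    "write_sidecar",
    "file_sha256",
]


def write_volume(path, volume: OCTVolume) -> None:
    """Multi-page TIFF, one page per B-scan (page shape: depth x A-scans)."""
    pages = np.transpose(volume.data, (1, 2, 0)).astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "axes": "QYX",
            "voxel_dz_um": volume.voxel_dz_um,
            "eye_id": volume.eye_id,
            "visit": volume.visit,
        },
    )


def read_volume(path) -> OCTVolume:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    data = np.transpose(pages, (2, 0, 1))
    return OCTVolume(
        data=data,
        voxel_dz_um=float(meta.get("voxel_dz_um", 1.0)),
        eye_id=str(meta.get("eye_id", "")),
        visit=str(meta.get("visit", "")),
    )


def write_surfaces(path, surfaces: SurfacePair) -> None:
    """CSV with one row per A-scan: x, y, ilm_z, rpe_z."""
    nx, ny = surfaces.shape
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame(
        {
            "x": xg.ravel(),
            "y": yg.ravel(),
            "ilm_z": surfaces.ilm_z.ravel(),
            "rpe_z": surfaces.rpe_z.ravel(),
        }
    ).to_csv(path, index=False)


def read_surfaces(path) -> SurfacePair:
    df = pd.read_csv(path)
    nx, ny = int(df["x"].max()) + 1, int(df["y"].max()) + 1
    ilm = np.full((nx, ny), np.nan)
    rpe = np.full((nx, ny), np.nan)
    ilm[df["x"], df["y"]] = df["ilm_z"]
    rpe[df["x"], df["y"]] = df["rpe_z"]
    return SurfacePair(ilm_z=ilm, rpe_z=rpe)


def write_slab_stack(path, stack: SlabStack) -> None:
    """5-page TIFF, page k-1 = slab k (1 = outermost, adjacent to the RPE)."""
    tifffile.imwrite(
        path,
        stack.images.astype(np.float32),
        metadata={
            "axes": "QYX",
            "slab_order": "1..5 outer to inner",
            "projection": stack.projection,
            "volume_id": stack.volume_id,
            "visit": stack.visit,
        },
    )


def read_slab_stack(path) -> SlabStack:
    with tifffile.TiffFile(path) as tif:
        images = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return SlabStack(
        images=images,
        volume_id=str(meta.get("volume_id", "")),
        visit=str(meta.get("visit", "")),
        projection=str(meta.get("projection", "max")),
    )


def write_ihrf_table(components_path, table: IHRFTable, counts_path=None) -> None:
    """Component CSV (eye, visit, slab, centroid, area) and optional counts CSV."""
    table.frame.to_csv(components_path, index=False)
    if counts_path is not None:
        counts = table.per_slab_counts()
        pd.DataFrame(
            {
                "eye_id": [table.eye_id] * N_SLABS,
                "visit": [table.visit] * N_SLABS,
                "slab": list(range(1, N_SLABS + 1)),
                "count": counts,
            }
        ).to_csv(counts_path, index=False)


def write_sidecar(artifact_path, payload: dict) -> Path:
    """JSON provenance sidecar next to an artifact (adds package version)."""
    path = Path(str(artifact_path) + ".json")
    out = dict(payload)
    out.setdefault("ihrf_version", __version__)
    path.write_text(json.dumps(out, indent=2, sort_keys=True, default=str) + "\n")
    return path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
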