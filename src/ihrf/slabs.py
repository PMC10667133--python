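"""Fractional-depth slab geometry between the ILM and the RPE.

The neurosensory retina at each A-scan is bounded by the internal limiting
membrane (ILM, fractional depth 0) and the inner RPE surface (fractional
depth 1).  It is partitioned into five sequential slabs of equal fractional
thickness (20% each), numbered from the outside in:

    slab 1 : [0.8, 1.0]   adjacent to the RPE (outermost)
    slab 2 : [0.6, 0.8)
    slab 3 : [0.4, 0.6)
    slab 4 : [0.2, 0.4)
    slab 5 : [0.0, 0.2)   just under the ILM (innermost)

Each slab is projected to a 2-D en-face image.  Both slab boundaries follow
the segmented contours, so slab thickness in voxels varies laterally with
retinal thickness.  Depth coordinates are 0-based voxel indices increasing
posteriorly (vitreous -> RPE); boundaries are kept continuous (no rounding
to whole voxels) and voxels are assigned to slabs by their center
coordinate, half-open [lo, hi) except slab 1 which is closed at the RPE end
so the outermost retinal voxel is never orphaned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

__all__ = [
    "SurfacePair",
    "SlabDefinition",
    "SlabBoundaries",
    "SlabStack",
    "SLABS",
    "get_slab",
    "slab_index_of_fraction",
    "slab_boundaries",
    "extract_enface",
    "make_slab_stack",
]

N_SLABS = 5


@dataclass
class SurfacePair:
    """Per-A-scan ILM and inner-RPE depth maps (voxel units, z inward)."""

    ilm_z: np.ndarray
    rpe_z: np.ndarray

    def __post_init__(self) -> None:
        self.ilm_z = np.asarray(self.ilm_z, dtype=float)
        self.rpe_z = np.asarray(self.rpe_z, dtype=float)
        if self.ilm_z.shape != self.rpe_z.shape:
            raise ValueError(
                f"ILM and RPE maps differ in shape: {self.ilm_z.shape} vs {self.rpe_z.shape}"
            )
        if not (np.isfinite(self.ilm_z).all() and np.isfinite(self.rpe_z).all()):
            raise ValueError("surface maps must be finite everywhere")
        bad = self.rpe_z <= self.ilm_z
        if bad.any():
            idx = np.argwhere(bad)[:5]
            locs = ", ".join(f"(x={i}, y={j})" for i, j in idx)
            raise ValueError(
                f"non-positive retinal thickness at {int(bad.sum())} A-scan(s), e.g. {locs}"
            )

    @property
    def shape(self) -> tuple:
        return self.ilm_z.shape

    def thickness(self) -> np.ndarray:
        """Retinal thickness map in voxels (rpe_z - ilm_z)."""
        return self.rpe_z - self.ilm_z


@dataclass(frozen=True)
class SlabDefinition:
    """One fractional-depth slab: index 1 (outer) .. 5 (inner)."""

    index: int
    frac_lo: float
    frac_hi: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_SLABS:
            raise ValueError(f"slab index must be 1..{N_SLABS}, got {self.index}")
        if not (0.0 <= self.frac_lo < self.frac_hi <= 1.0):
            raise ValueError("slab fractions must satisfy 0 <= lo < hi <= 1")
        if abs((self.frac_hi - self.frac_lo) - 0.2) > 1e-9:
            raise ValueError("each slab spans 20% of the retinal thickness")

    @property
    def closed_hi(self) -> bool:
        """Slab 1 includes its outer (RPE) boundary."""
        return self.index == 1


#: The five standard slabs; slab k spans fractions [0.2*(5-k), 0.2*(6-k)].
SLABS: tuple = tuple(
    SlabDefinition(k, round(0.2 * (N_SLABS - k), 10), round(0.2 * (N_SLABS - k + 1), 10))
    for k in range(1, N_SLABS + 1)
)


def get_slab(index: int) -> SlabDefinition:
    if not 1 <= index <= N_SLABS:
        raise ValueError(f"slab index must be 1..{N_SLABS}, got {index}")
    return SLABS[index - 1]


def slab_index_of_fraction(frac: float) -> Optional[int]:
    """Slab index owning fractional depth ``frac``, or None outside [0, 1].

    Interval convention matches en-face extraction: half-open at the inner
    boundary of each slab, with fraction 1.0 (the RPE surface) belonging to
    slab 1.  A fraction exactly on an interior boundary (e.g. 0.8) belongs
    to the outer of the two slabs it separates.
    """
    if frac < 0.0 or frac > 1.0:
        return None
    # count of whole 20% bands below frac, measured from the ILM
    # (multiply rather than divide by 0.2: 0.6*5 is exactly 3.0 in floats)
    k_inner = min(int(frac * N_SLABS), N_SLABS - 1)
    return N_SLABS - k_inner


@dataclass(frozen=True)
class SlabBoundaries:
    """Depth maps bounding one slab; both follow the retinal contours."""

    lo_z: np.ndarray
    hi_z: np.ndarray
    slab: SlabDefinition


def slab_boundaries(surfaces: SurfacePair, slab: SlabDefinition) -> SlabBoundaries:
    """Compute the two bounding surfaces of ``slab``.

    lo_z = ilm + frac_lo * (rpe - ilm), hi_z = ilm + frac_hi * (rpe - ilm);
    by construction the inner boundary follows the ILM contour and the
    outer boundary follows the RPE contour.
    """
    t = surfaces.thickness()
    lo = surfaces.ilm_z + slab.frac_lo * t
    hi = surfaces.ilm_z + slab.frac_hi * t
    return SlabBoundaries(lo_z=lo, hi_z=hi, slab=slab)


def _volume_data(volume) -> np.ndarray:
    data = getattr(volume, "data", volume)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume (x, y, z), got shape {data.shape}")
    return data


def extract_enface(
    volume,
    boundaries: SlabBoundaries,
    projection: Literal["max", "mean"] = "max",
) -> np.ndarray:
    """Project the sub-volume between two contour-following surfaces.

    Each en-face pixel is the maximum (default) or mean voxel intensity over
    the depth interval [lo_z, hi_z) at that (x, y); voxels participate when
    their center coordinate (integer z) falls inside the interval.  Slab 1
    uses a closed interval at the RPE end.  Where the interval contains no
    voxel center (pathologically thin retina), the pixel falls back to the
    voxel nearest the interval midpoint and a warning is emitted.
    """
    data = _volume_data(volume)
    nx, ny, nz = data.shape
    if boundaries.lo_z.shape != (nx, ny):
        raise ValueError("boundary maps do not match the volume's lateral grid")
    if np.nanmin(boundaries.lo_z) < -0.5 or np.nanmax(boundaries.hi_z) > nz - 0.5 + 1e-9:
        raise ValueError("slab boundaries fall outside the volume depth range")

    z = np.arange(nz, dtype=float)[None, None, :]
    lo = boundaries.lo_z[:, :, None]
    hi = boundaries.hi_z[:, :, None]
    if boundaries.slab.closed_hi:
        inside = (z >= lo) & (z <= hi)
    else:
        inside = (z >= lo) & (z < hi)

    n_inside = inside.sum(axis=2)
    if projection == "max":
        out = np.where(inside, data, -np.inf).max(axis=2)
    elif projection == "mean":
        with np.errstate(invalid="ignore"):
            out = np.where(inside, data, 0.0).sum(axis=2) / np.maximum(n_inside, 1)
    else:
        raise ValueError(f"unknown projection {projection!r}")

    empty = n_inside == 0
    if empty.any():
        warnings.warn(
            f"slab {boundaries.slab.index}: empty depth interval at "
            f"{int(empty.sum())} A-scan(s); using nearest voxel",
            RuntimeWarning,
            stacklevel=2,
        )
        xi, yi = np.nonzero(empty)
        mid = np.clip(np.round((boundaries.lo_z[xi, yi] + boundaries.hi_z[xi, yi]) / 2), 0, nz - 1)
        out[xi, yi] = data[xi, yi, mid.astype(int)]
    return out.astype(float)


@dataclass
class SlabStack:
    """Five en-face images (slab 1..5) sharing the volume's lateral grid."""

    images: np.ndarray  # (5, nx, ny)
    definitions: tuple = SLABS
    volume_id: str = ""
    visit: str = ""
    projection: str = "max"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.shape[0] != N_SLABS:
            raise ValueError(f"expected {N_SLABS} en-face images, got {self.images.shape[0]}")

    def image(self, slab_index: int) -> np.ndarray:
        return self.images[slab_index - 1]

    @property
    def lateral_shape(self) -> tuple:
        return self.images.shape[1:]


def make_slab_stack(
    volume,
    surfaces: SurfacePair,
    projection: Literal["max", "mean"] = "max",
    volume_id: str = "",
    visit: str = "",
) -> SlabStack:
    """Build the five-slab en-face stack for one volume."""
    data = _volume_data(volume)
    if surfaces.shape != data.shape[:2]:
        raise ValueError("surface maps do not match the volume's lateral grid")
    images = np.stack(
        [extract_enface(data, slab_boundaries(surfaces, s), projection) for s in SLABS]
    )
    vid = volume_id or getattr(volume, "eye_id", "")
    vis = visit or getattr(volume, "visit", "")
    return SlabStack(images=images, volume_id=vid, visit=vis, projection=projection)
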