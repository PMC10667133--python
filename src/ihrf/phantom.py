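"""Synthetic OCT phantoms with known hyperreflective-focus ground truth.

Real depth-stratified IHRF quantification runs on macular cube scans
(512x128 A-scans, ~1024 depth samples over 6x6 mm).  This module renders a
scaled-down analog — default 128x32x256 voxels — with the geometric and
photometric features the pipeline cares about:

* a layered retina between smooth ILM and RPE surfaces (five reflectivity
  bands on a linear scale, RPE strictly brightest);
* drusen that elevate the RPE locally with a smooth cosine-bump profile;
* implanted hyperreflective foci (balls of known center, fractional depth,
  radius and intensity >= the RPE reflectivity, matching the clinical IHRF
  definition);
* retinal vessels: small bright spots in the innermost band with a dimmed
  shadow column beneath, the classic en-face confounder;
* multiplicative Gamma(shape, 1/shape) speckle (mean 1), the standard OCT
  speckle surrogate; shape 0 disables noise.

Every rendered focus is recorded in a :class:`TruthTable` with the slab
index (or indices) its voxels actually occupy, using the same voxel-center
interval convention as :mod:`ihrf.slabs`, so a lesion straddling a slab
boundary is truthed in both slabs — the same double-counting convention the
en-face pipeline produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .slabs import SurfacePair, slab_index_of_fraction
from .volume import OCTVolume

__all__ = [
    "VolumeSpec",
    "FocusSpec",
    "DrusenSpec",
    "TruthTable",
    "generate_surfaces",
    "render_volume",
    "sample_interior_foci",
]

VITREOUS_REFLECTIVITY = 0.02
SUB_RPE_REFLECTIVITY = 0.06
VESSEL_RADIUS_PX = 1.5
VESSEL_SHADOW_FACTOR = 0.35


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry, reflectivity and noise parameters of a phantom cube.

    ``layer_reflectivities`` are the five intra-retinal bands ordered from
    inner (under the ILM) to outer (above the RPE), on a linear reflectivity
    scale in [0, 1].  The RPE band must be strictly brighter than every
    retinal band: IHRF are defined as lesions at least as bright as the RPE,
    so the RPE anchors the top of the intensity scale.
    """

    n_ascans_x: int = 128
    n_bscans_y: int = 32
    n_depth_z: int = 256
    voxel_dz_um: float = 7.8
    layer_reflectivities: tuple = (0.34, 0.20, 0.10, 0.14, 0.30)
    rpe_reflectivity: float = 0.80
    rpe_band_px: int = 4
    speckle_shape: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ascans_x", "n_bscans_y", "n_depth_z"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8")
        if len(self.layer_reflectivities) != 5:
            raise ValueError("exactly 5 layer reflectivities required (inner -> outer)")
        if not all(0.0 <= r <= 1.0 for r in self.layer_reflectivities):
            raise ValueError("layer reflectivities must lie in [0, 1]")
        if not 0.0 < self.rpe_reflectivity <= 1.0:
            raise ValueError("rpe_reflectivity must lie in (0, 1]")
        if self.rpe_reflectivity <= max(self.layer_reflectivities):
            raise ValueError("RPE must be strictly brighter than every retinal band")
        if self.speckle_shape < 0:
            raise ValueError("speckle_shape must be >= 0 (0 disables speckle)")
        if self.voxel_dz_um <= 0:
            raise ValueError("voxel_dz_um must be positive")


@dataclass(frozen=True)
class FocusSpec:
    """One implanted hyperreflective focus.

    ``frac_depth`` is the fractional depth of the center between the ILM (0)
    and the inner RPE surface (1); ``intensity`` must be at least the
    phantom's RPE reflectivity (the defining property of an IHRF).
    """

    x: int
    y: int
    frac_depth: float
    radius_px: float = 2.0
    intensity: float = 0.85

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("focus radius must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("focus intensity must lie in [0, 1]")


@dataclass(frozen=True)
class DrusenSpec:
    """A smooth RPE elevation (cosine bump) of given lateral radius/height."""

    x: int
    y: int
    radius_px: float = 10.0
    height_px: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0 or self.height_px <= 0:
            raise ValueError("drusen radius and height must be positive")


class TruthTable:
    """Ground-truth foci and the slab index (or indices) each occupies.

    One row per (focus, slab) pair; a boundary-straddling lesion
    contributes one row per slab it intersects and therefore counts once in
    each — the same convention as the en-face pipeline.
    """

    COLUMNS = ["focus_id", "x", "y", "frac_depth", "radius_px", "intensity", "slab"]

    def __init__(self, rows: Optional[Iterable[dict]] = None):
        self.frame = pd.DataFrame(list(rows or []), columns=self.COLUMNS)

    def per_slab_counts(self) -> np.ndarray:
        """Counts for slabs 1..5 (a straddling focus counts in each slab)."""
        counts = np.zeros(5, dtype=int)
        for slab, n in self.frame["slab"].value_counts().items():
            counts[int(slab) - 1] = int(n)
        return counts

    def slabs_of(self, focus_id: int) -> tuple:
        return tuple(sorted(self.frame.loc[self.frame.focus_id == focus_id, "slab"].astype(int)))

    def is_straddling(self, focus_id: int) -> bool:
        return len(self.slabs_of(focus_id)) > 1

    @property
    def n_foci(self) -> int:
        return self.frame["focus_id"].nunique()

    def __len__(self) -> int:
        return len(self.frame)


def _lateral_grids(spec: VolumeSpec):
    x = np.arange(spec.n_ascans_x, dtype=float)
    y = np.arange(spec.n_bscans_y, dtype=float)
    return np.meshgrid(x, y, indexing="ij")


def generate_surfaces(
    spec: VolumeSpec,
    drusen: Sequence[DrusenSpec] = (),
    *,
    rpe_center_frac: float = 0.72,
    thickness_frac: float = 0.50,
    curvature_px: float = 3.0,
) -> SurfacePair:
    """Smooth ILM/RPE depth maps; drusen raise the RPE locally.

    The ILM tracks the RPE base at a constant offset, so without drusen the
    thickness map is constant (a convenient degenerate geometry for tests).
    Overlapping drusen combine as the pointwise maximum of their bumps, as
    physical elevations would.
    """
    nx, ny, nz = spec.n_ascans_x, spec.n_bscans_y, spec.n_depth_z
    xg, yg = _lateral_grids(spec)

    base_rpe = rpe_center_frac * nz + curvature_px * np.cos(
        math.pi * (xg / (nx - 1) - 0.5)
    ) * np.cos(math.pi * (yg / (ny - 1) - 0.5))
    thickness = thickness_frac * nz

    elevation = np.zeros_like(base_rpe)
    for d in drusen:
        if not (0 <= d.x < nx and 0 <= d.y < ny):
            raise ValueError(
                f"drusen center ({d.x}, {d.y}) lies outside the {nx}x{ny} lateral field"
            )
        if d.height_px >= thickness:
            raise ValueError("drusen height must be smaller than the retinal thickness")
        dist = np.hypot(xg - d.x, yg - d.y)
        bump = np.where(
            dist < d.radius_px,
            d.height_px * 0.5 * (1.0 + np.cos(math.pi * dist / d.radius_px)),
            0.0,
        )
        elevation = np.maximum(elevation, bump)

    rpe_z = base_rpe - elevation  # drusen push the RPE inward (smaller z)
    ilm_z = base_rpe - thickness
    if ilm_z.min() < 1 or rpe_z.max() > nz - spec.rpe_band_px - 2:
        raise ValueError("surfaces do not fit inside the volume depth range")
    return SurfacePair(ilm_z=ilm_z, rpe_z=rpe_z)


def _ball_voxels(cx: float, cy: float, cz: float, r: float, shape: tuple):
    """Integer voxel coordinates intersecting a ball of radius r.

    A voxel spans one unit in depth, so its z-distance to the center is
    measured edge-to-center (|dz| - 0.5, floored at 0); this keeps the
    en-face footprint of a radius-1 ball at >= 3 pixels regardless of the
    sub-voxel depth of the center.
    """
    nx, ny, nz = shape
    x0, x1 = max(0, math.floor(cx - r)), min(nx - 1, math.ceil(cx + r))
    y0, y1 = max(0, math.floor(cy - r)), min(ny - 1, math.ceil(cy + r))
    z0, z1 = max(0, math.floor(cz - r - 0.5)), min(nz - 1, math.ceil(cz + r + 0.5))
    xs, ys, zs = np.mgrid[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1]
    dz = np.maximum(np.abs(zs - cz) - 0.5, 0.0)
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 + dz**2 <= r**2
    return xs[inside], ys[inside], zs[inside]


def render_volume(
    spec: VolumeSpec,
    surfaces: SurfacePair,
    foci: Sequence[FocusSpec] = (),
    vessels: Sequence[tuple] = (),
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Render a phantom cube and its ground-truth table.

    Rendering order: layered retina and RPE band, then foci, then vessels
    (whose shadow dims everything beneath them, including the RPE — the
    signature the artifact mask keys on), then multiplicative speckle.

    Returns ``(OCTVolume, TruthTable)``.
    """
    nx, ny, nz = spec.n_ascans_x, spec.n_bscans_y, spec.n_depth_z
    if surfaces.shape != (nx, ny):
        raise ValueError("surfaces do not match the spec's lateral grid")
    ilm = surfaces.ilm_z[:, :, None]
    rpe = surfaces.rpe_z[:, :, None]
    z = np.arange(nz, dtype=float)[None, None, :]

    vol = np.full((nx, ny, nz), VITREOUS_REFLECTIVITY, dtype=np.float32)
    with np.errstate(invalid="ignore"):
        frac = (z - ilm) / (rpe - ilm)
    retina = (z >= ilm) & (z <= rpe)
    bands = np.asarray(spec.layer_reflectivities, dtype=np.float32)
    band_idx = np.clip((frac * 5).astype(int), 0, 4)
    vol[retina] = bands[band_idx[retina]]
    rpe_band = (z > rpe) & (z <= rpe + spec.rpe_band_px)
    vol[rpe_band] = spec.rpe_reflectivity
    vol[z > rpe + spec.rpe_band_px] = SUB_RPE_REFLECTIVITY

    truth_rows = []
    for fid, f in enumerate(foci):
        if not (0 <= f.x < nx and 0 <= f.y < ny):
            raise ValueError(f"focus center ({f.x}, {f.y}) outside the lateral field")
        if f.frac_depth > 1.0:
            raise ValueError(f"focus at fractional depth {f.frac_depth} lies deeper than the RPE")
        if f.frac_depth < 0.0:
            raise ValueError(f"focus at fractional depth {f.frac_depth} lies above the ILM")
        if f.intensity < spec.rpe_reflectivity:
            raise ValueError(
                "focus intensity must be >= the RPE reflectivity (IHRF definition)"
            )
        t_local = surfaces.rpe_z[f.x, f.y] - surfaces.ilm_z[f.x, f.y]
        cz = surfaces.ilm_z[f.x, f.y] + f.frac_depth * t_local
        xs, ys, zs = _ball_voxels(f.x, f.y, cz, f.radius_px, (nx, ny, nz))
        vol[xs, ys, zs] = f.intensity
        # ground-truth slab membership from the rendered voxels themselves,
        # using the same voxel-center fractional-depth convention as slabs.py
        slabs_hit = set()
        for vx, vy, vz in zip(xs, ys, zs):
            lo, hi = surfaces.ilm_z[vx, vy], surfaces.rpe_z[vx, vy]
            if not (lo <= vz <= hi):
                continue
            s = slab_index_of_fraction((vz - lo) / (hi - lo))
            if s is not None:
                slabs_hit.add(s)
        for s in sorted(slabs_hit):
            truth_rows.append(
                dict(
                    focus_id=fid,
                    x=f.x,
                    y=f.y,
                    frac_depth=f.frac_depth,
                    radius_px=f.radius_px,
                    intensity=f.intensity,
                    slab=s,
                )
            )

    for vx, vy in vessels:
        vx, vy = int(vx), int(vy)
        if not (0 <= vx < nx and 0 <= vy < ny):
            raise ValueError(f"vessel center ({vx}, {vy}) outside the lateral field")
        r = VESSEL_RADIUS_PX
        x0, x1 = max(0, math.floor(vx - r)), min(nx - 1, math.ceil(vx + r))
        y0, y1 = max(0, math.floor(vy - r)), min(ny - 1, math.ceil(vy + r))
        for cx in range(x0, x1 + 1):
            for cy in range(y0, y1 + 1):
                if (cx - vx) ** 2 + (cy - vy) ** 2 > r**2:
                    continue
                t_local = surfaces.rpe_z[cx, cy] - surfaces.ilm_z[cx, cy]
                zc = surfaces.ilm_z[cx, cy] + 0.08 * t_local
                zlo, zhi = int(math.floor(zc - 1)), int(math.ceil(zc + 1))
                vol[cx, cy, max(0, zlo) : min(nz, zhi + 1)] = spec.rpe_reflectivity
                vol[cx, cy, min(nz, zhi + 2) :] *= VESSEL_SHADOW_FACTOR

    if spec.speckle_shape > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        vol *= rng.gamma(
            spec.speckle_shape, 1.0 / spec.speckle_shape, size=vol.shape
        ).astype(np.float32)

    volume = OCTVolume(data=vol, voxel_dz_um=spec.voxel_dz_um)
    return volume, TruthTable(truth_rows)


def sample_interior_foci(
    rng: np.random.Generator,
    spec: VolumeSpec,
    surfaces: SurfacePair,
    n_foci: int,
    radius_range: tuple = (1.6, 2.4),
    intensity_range: tuple = (0.85, 1.0),
    lateral_margin_px: int = 5,
    min_gap_px: float = 4.0,
    depth_margin_px: float = 3.0,
    max_tries: int = 2000,
) -> list:
    """Randomly place well-separated foci strictly interior to single slabs.

    Each focus is assigned a uniformly random slab; its fractional depth is
    drawn so the whole ball (plus ``depth_margin_px``) stays inside that
    slab's interval, and lateral placement keeps foci at least
    ``r_i + r_j + min_gap_px`` apart so they never merge in any en-face
    image.  Used by tests and the recovery benchmark, where ground truth
    must be a single unambiguous slab per focus.
    """
    nx, ny = spec.n_ascans_x, spec.n_bscans_y
    placed: list = []
    tries = 0
    while len(placed) < n_foci and tries < max_tries:
        tries += 1
        r = float(rng.uniform(*radius_range))
        x = int(rng.integers(lateral_margin_px, nx - lateral_margin_px))
        y = int(rng.integers(lateral_margin_px, ny - lateral_margin_px))
        if any(
            math.hypot(x - f.x, y - f.y) < r + f.radius_px + min_gap_px for f in placed
        ):
            continue
        t_local = surfaces.rpe_z[x, y] - surfaces.ilm_z[x, y]
        margin_frac = (r + depth_margin_px) / t_local
        if margin_frac >= 0.1:  # slab too thin for an interior ball
            continue
        slab = int(rng.integers(1, 6))
        frac_lo = 0.2 * (5 - slab) + margin_frac
        frac_hi = 0.2 * (6 - slab) - margin_frac
        frac = float(rng.uniform(frac_lo, frac_hi))
        placed.append(
            FocusSpec(
                x=x,
                y=y,
                frac_depth=frac,
                radius_px=r,
                intensity=float(rng.uniform(*intensity_range)),
            )
        )
    if len(placed) < n_foci:
        raise RuntimeError(
            f"could not place {n_foci} separated foci in {max_tries} tries"
        )
    return placed
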