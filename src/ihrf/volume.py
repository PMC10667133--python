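"""In-memory container for a macular OCT cube."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OCTVolume:
    """3-D reflectivity array with voxel spacing and eye/visit identity.

    Axis order is (x, y, z): x = A-scan along the fast axis, y = B-scan
    index, z = depth, 0-based and increasing posteriorly (vitreous toward
    choroid).  Intensities are linear-scale reflectivities, nominally in
    [0, 1] before speckle.
    """

    data: np.ndarray
    voxel_dz_um: float = 7.8
    eye_id: str = "eye"
    visit: str = "baseline"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D (x, y, z), got shape {self.data.shape}")
        if self.voxel_dz_um <= 0:
            raise ValueError("voxel_dz_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape
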