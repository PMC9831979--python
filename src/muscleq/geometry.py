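"""Acquisition geometry: voxel spacing, grid shape, and volume conversion.

All volumes in this package live on a regular 3D grid with axis order
(x, y, z), z being the slice axis.  The only geometric information the
analysis needs is the voxel spacing, because every comparison is
intra-case: masks and images are never resampled or registered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel spacing (mm) and grid dimensions (voxels) of one acquisition.

    Parameters
    ----------
    spacing : tuple of 3 floats
        Voxel edge lengths in mm along (x, y, z).  The default protocol
        used throughout the package is an in-plane resolution of
        0.14 x 0.14 mm with 1 mm slices.
    shape : tuple of 3 ints
        Grid dimensions in voxels along (x, y, z).
    """

    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or len(self.shape) != 3:
            raise GeometryError("geometry needs 3 spacings and 3 dimensions")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise GeometryError(
                f"voxel spacing must be strictly positive, got {self.spacing}"
            )
        if any(int(d) != d or d <= 0 for d in self.shape):
            raise GeometryError(f"grid dimensions must be positive integers, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (product of spacings)."""
        return float(self.spacing[0]) * float(self.spacing[1]) * float(self.spacing[2])

    def voxels_to_ml(self, n_voxels: int | float) -> float:
        """Convert a voxel count to millilitres (1 ml = 1000 mm^3)."""
        return float(n_voxels) * self.voxel_volume_mm3 / MM3_PER_ML

    def compatible_with(self, other: "AcquisitionGeometry", rtol: float = 1e-4) -> bool:
        """True when shapes match exactly and spacings agree within ``rtol``."""
        return self.shape == other.shape and bool(
            np.allclose(self.spacing, other.spacing, rtol=rtol, atol=0.0)
        )
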