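"""NIfTI input/output and validation of Dixon fat/water/mask triplets.

The interchange format is NIfTI-1 (.nii / .nii.gz), as produced by
DICOM converters and manual-segmentation tools such as ITK-SNAP.
Orientation metadata beyond voxel spacing is deliberately ignored: the
analysis never compares voxels across cases, so only the grid and the
spacing matter.  Absence of spacing in a header (zero zooms) is an
error, never silently defaulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, GeometryError, IncompatibilityError, InputError
from .geometry import AcquisitionGeometry

log = logging.getLogger(__name__)

# Label semantics.  Input leg-compartment (LC) masks are binary; the
# segmentation step refines LC into muscle vs. macroscopic fat.
BACKGROUND = 0
LC = 1
MUSCLE_LC = 1
FAT_LC = 2

LC_SEMANTICS = frozenset({BACKGROUND, LC})
SEGMENTED_SEMANTICS = frozenset({BACKGROUND, MUSCLE_LC, FAT_LC})

MANIFEST_COLUMNS = ["animal_id", "group", "fat_path", "water_path", "mask_path"]


@dataclass
class DixonPair:
    """Co-registered fat and water intensity volumes on one grid.

    Intensities are arbitrary scanner units, finite and non-negative.
    """

    fat: np.ndarray
    water: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.fat = np.asarray(self.fat, dtype=np.float32)
        self.water = np.asarray(self.water, dtype=np.float32)
        if self.fat.shape != self.water.shape:
            raise IncompatibilityError(
                f"fat grid {self.fat.shape} != water grid {self.water.shape}"
            )
        if tuple(self.fat.shape) != tuple(self.geometry.shape):
            raise IncompatibilityError(
                f"volume grid {self.fat.shape} != geometry {self.geometry.shape}"
            )
        for name, vol in (("fat", self.fat), ("water", self.water)):
            if not np.all(np.isfinite(vol)):
                raise DataError(f"{name} volume contains non-finite voxels")
            if np.any(vol < 0):
                raise DataError(f"{name} volume contains negative voxels")


@dataclass
class LabelMask:
    """Integer label volume with declared semantics.

    ``semantics`` is the set of admissible label values; any voxel
    outside it is a contract violation, not a warning.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    semantics: frozenset[int] = field(default=LC_SEMANTICS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise IncompatibilityError(
                f"mask grid {self.data.shape} != geometry {self.geometry.shape}"
            )
        present = set(np.unique(self.data).tolist())
        if not present <= set(self.semantics):
            raise InputError(
                f"mask contains labels {sorted(present - set(self.semantics))} "
                f"outside declared semantics {sorted(self.semantics)}"
            )

    def count(self, label: int) -> int:
        """Number of voxels carrying ``label``."""
        if label not in self.semantics:
            raise InputError(f"label {label} not in semantics {sorted(self.semantics)}")
        return int(np.count_nonzero(self.data == label))


def _geometry_from_header(img: nib.Nifti1Image, path: str | Path) -> AcquisitionGeometry:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"{path}: header carries no usable voxel spacing {zooms}")
    shape = tuple(int(d) for d in img.shape[:3])
    return AcquisitionGeometry(spacing=zooms, shape=shape)


def _load_volume(path: str | Path) -> tuple[np.ndarray, AcquisitionGeometry]:
    img = nib.load(str(path))
    geom = _geometry_from_header(img, path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IncompatibilityError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, geom


def load_case(
    fat_path: str | Path,
    water_path: str | Path,
    mask_path: str | Path,
    spacing_rtol: float = 1e-4,
) -> tuple[DixonPair, LabelMask]:
    """Load and validate one case: fat + water volumes and an LC mask.

    The mask is binarised: any nonzero label (e.g. ITK-SNAP label 7, or
    separate left/right leg labels) becomes LC = 1.  Grids and spacings
    must agree across the three files within ``spacing_rtol``.
    """
    fat, fat_geom = _load_volume(fat_path)
    water, water_geom = _load_volume(water_path)
    mask, mask_geom = _load_volume(mask_path)

    for name, geom in (("water", water_geom), ("mask", mask_geom)):
        path = water_path if name == "water" else mask_path
        if geom.shape != fat_geom.shape:
            raise IncompatibilityError(
                f"{path}: grid {geom.shape} incompatible with fat grid {fat_geom.shape}"
            )
        if not np.allclose(geom.spacing, fat_geom.spacing, rtol=spacing_rtol, atol=0.0):
            raise IncompatibilityError(
                f"{path}: spacing {geom.spacing} incompatible with fat spacing "
                f"{fat_geom.spacing} (rtol {spacing_rtol})"
            )

    pair = DixonPair(fat=fat, water=water, geometry=fat_geom)
    lc = LabelMask(
        data=(np.asarray(mask) != 0).astype(np.uint8),
        geometry=fat_geom,
        semantics=LC_SEMANTICS,
    )
    return pair, lc


def save_volume(data: np.ndarray, geometry: AcquisitionGeometry, path: str | Path) -> Path:
    """Write a float volume as NIfTI-1 with spacing in the header."""
    path = Path(path)
    affine = np.diag(list(geometry.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(geometry.spacing)
    nib.save(img, str(path))
    return path


def save_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as unsigned 8-bit NIfTI-1; reload equals original."""
    path = Path(path)
    affine = np.diag(list(mask.geometry.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.geometry.spacing)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path, semantics: frozenset[int] = SEGMENTED_SEMANTICS) -> LabelMask:
    """Load an integer label volume with the given semantics (no binarisation)."""
    data, geom = _load_volume(path)
    return LabelMask(data=data.astype(np.uint8), geometry=geom, semantics=semantics)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a case manifest CSV (animal_id, group, fat_path, water_path, mask_path)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} missing columns {missing}")
    if len(df) == 0:
        raise InputError(f"manifest {path} lists no cases")
    return df[MANIFEST_COLUMNS]
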