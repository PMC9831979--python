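"""Per-animal quantification: volumes, fat-fraction map, derived ratios.

Region volumes are voxel counts times voxel volume.  The fat fraction
of a voxel is FF = fat / (fat + water) from the two Dixon channels; it
is evaluated over muscle-compartment voxels only and summarised as a
percent mean per animal.  Fat infiltration is the fat-compartment
volume divided by the total compartment volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import AcquisitionGeometry
from .image_io import DixonPair, LabelMask

COHORT_COLUMNS = [
    "animal_id",
    "group",
    "lc_ml",
    "fat_lc_ml",
    "muscle_lc_ml",
    "fat_fraction_pct",
    "fat_infiltration",
    "muscle_to_fat",
]


@dataclass
class FatFractionMap:
    """Per-voxel fat fractions over the muscle compartment.

    ``values`` holds FF in [0, 1] for every included voxel; voxels with
    fat + water = 0 (signal voids, 0/0) are excluded and counted rather
    than set to an arbitrary value.
    """

    values: np.ndarray
    n_excluded: int
    geometry: AcquisitionGeometry

    def mean_pct(self) -> float:
        """Arithmetic mean FF over included voxels, in percent."""
        return float(np.mean(self.values)) * 100.0

    def median_pct(self) -> float:
        return float(np.median(self.values)) * 100.0


@dataclass(frozen=True)
class AnimalRecord:
    """Derived metrics for one animal (both hind legs pooled)."""

    animal_id: str
    group: str
    lc_ml: float
    fat_lc_ml: float
    muscle_lc_ml: float
    fat_fraction_pct: float
    fat_infiltration: float
    muscle_to_fat: float  # NaN when fat-LC is empty
    muscle_to_fat_undefined: bool = False

    def __post_init__(self) -> None:
        if abs(self.muscle_lc_ml + self.fat_lc_ml - self.lc_ml) > 1e-9:
            raise InputError("fat-LC + muscle-LC must equal LC to 1e-9 ml")
        if not (0.0 <= self.fat_infiltration < 1.0):
            raise InputError(f"fat infiltration {self.fat_infiltration} outside [0, 1)")
        if not (0.0 <= self.fat_fraction_pct <= 100.0):
            raise InputError(f"mean FF {self.fat_fraction_pct}% outside [0, 100]")


def mask_volume_ml(mask: LabelMask, label: int, geometry: AcquisitionGeometry | None = None
                   ) -> float:
    """Volume (ml) of all voxels carrying ``label``: count x voxel volume."""
    geom = geometry or mask.geometry
    return geom.voxels_to_ml(mask.count(label))


def fat_fraction_map(pair: DixonPair, muscle_mask: np.ndarray) -> FatFractionMap:
    """Compute FF = fat / (fat + water) over the given muscle voxels."""
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if muscle_mask.shape != pair.fat.shape:
        raise InputError("muscle mask and Dixon pair are on different grids")
    if not muscle_mask.any():
        raise InputError("muscle mask is empty")
    fat = pair.fat[muscle_mask].astype(np.float64)
    water = pair.water[muscle_mask].astype(np.float64)
    denom = fat + water
    included = denom > 0
    ff = fat[included] / denom[included]
    return FatFractionMap(
        values=ff,
        n_excluded=int((~included).sum()),
        geometry=pair.geometry,
    )


def summarize_animal(
    animal_id: str,
    group: str,
    lc_ml: float,
    fat_lc_ml: float,
    ff_map: FatFractionMap,
) -> AnimalRecord:
    """Fold one case's volumes and FF map into an AnimalRecord.

    Fat infiltration = fat-LC / LC; muscle-to-fat = muscle-LC / fat-LC,
    flagged undefined (NaN) when the fat compartment is empty.
    """
    if lc_ml <= 0:
        raise InputError(f"LC volume must be positive, got {lc_ml}")
    if fat_lc_ml < 0 or fat_lc_ml > lc_ml:
        raise InputError(f"fat-LC volume {fat_lc_ml} outside [0, LC={lc_ml}]")
    muscle_ml = lc_ml - fat_lc_ml
    undefined = fat_lc_ml == 0
    return AnimalRecord(
        animal_id=str(animal_id),
        group=str(group),
        lc_ml=float(lc_ml),
        fat_lc_ml=float(fat_lc_ml),
        muscle_lc_ml=float(muscle_ml),
        fat_fraction_pct=ff_map.mean_pct(),
        fat_infiltration=float(fat_lc_ml / lc_ml),
        muscle_to_fat=float("nan") if undefined else float(muscle_ml / fat_lc_ml),
        muscle_to_fat_undefined=undefined,
    )


def cohort_table(records: Iterable[AnimalRecord]) -> pd.DataFrame:
    """Assemble per-animal records into one cohort table (one row each).

    Note on schema: ``lc_ml`` is the TOTAL compartment volume (muscle +
    bone + macroscopic fat), the quantity published per animal alongside
    fat volume, FF and infiltration; ``muscle_lc_ml`` (= lc - fat) is
    exposed separately because group comparisons use it directly.
    """
    records = list(records)
    if not records:
        raise InputError("need at least one animal record")
    ids = [r.animal_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate animal ids {dupes}")
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "lc_ml": r.lc_ml,
                "fat_lc_ml": r.fat_lc_ml,
                "muscle_lc_ml": r.muscle_lc_ml,
                "fat_fraction_pct": r.fat_fraction_pct,
                "fat_infiltration": r.fat_infiltration,
                "muscle_to_fat": r.muscle_to_fat,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
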