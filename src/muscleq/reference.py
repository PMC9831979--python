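"""Packaged reference cohort: published per-animal MRI measurements.

The fixture holds the per-animal leg-compartment measurements reported
for 9 control (CNT, FVB strain) and 9 myotonic-dystrophy model (DM1,
HSA-LR strain) mice: total compartment volume (ml), macroscopic fat
volume (ml), mean muscle fat fraction (%) and fatty infiltration
(fat / total, dimensionless).  These are the values the reproduction
report recomputes ratios and significance calls from; the raw scans
behind them are not publicly deposited, so the fixture is the only
bridge to the in vivo results.

Note the published table labels the total-compartment column "Muscle
compartment (ml)"; it is nevertheless the TOTAL volume — fat / that
column reproduces the printed infiltration values, which the derived
muscle-only volume does not.  The loader exposes it as ``lc_ml`` and
adds ``muscle_lc_ml = lc_ml - fat_lc_ml``.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import IntegrityError

_FIXTURE_NAME = "reference_cohort.csv"
_FIXTURE_SHA256 = "8ae7065f53c41804d5bdf82ef555ef6f4db3da91990139fa89d2519a58d6c095"

CONTROL_GROUP = "CNT"
DISEASE_GROUP = "DM1"

# Printed precision of the source table: volumes 2 decimals, FF% 2,
# infiltration 3.  Independent rounding of numerator and denominator
# means recomputed infiltration can deviate from the printed value by
# up to ~0.002.
INFILTRATION_ROUNDING_TOL = 0.002


def _fixture_bytes() -> bytes:
    return resources.files("muscleq.data").joinpath(_FIXTURE_NAME).read_bytes()


def load_reference_cohort(verify: bool = True) -> pd.DataFrame:
    """Load the 18-animal reference cohort table.

    Columns: animal_id, group (CNT/DM1), lc_ml, fat_lc_ml,
    muscle_lc_ml, fat_fraction_pct, fat_infiltration.

    With ``verify`` (default) the packaged CSV is checked against its
    SHA-256 before parsing; a mismatch raises IntegrityError.
    """
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise IntegrityError(
                f"reference cohort fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype={"animal_id": str, "group": str})
    df["muscle_lc_ml"] = df["lc_ml"] - df["fat_lc_ml"]
    return df[
        [
            "animal_id",
            "group",
            "lc_ml",
            "fat_lc_ml",
            "muscle_lc_ml",
            "fat_fraction_pct",
            "fat_infiltration",
        ]
    ]
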