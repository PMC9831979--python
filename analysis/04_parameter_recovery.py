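#!/usr/bin/env python
"""Parameter recovery: segmented fat volume vs phantom ground truth.

For every phantom of both cohorts, compares the fat volume recovered by
Otsu segmentation of the noisy fat image (sigma 30) against the known
truth, reporting the per-case relative error.  Writes
results/parameter_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from muscleq import cohort_specs, generate_phantom, mask_volume_ml, segment_lc
from muscleq.image_io import FAT_LC

BASE_SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for profile in ("control", "disease"):
        for i, spec in enumerate(cohort_specs(profile, 9, BASE_SEED)):
            pair, lc, truth = generate_phantom(spec)
            seg, otsu = segment_lc(pair, lc)
            recovered = mask_volume_ml(seg, FAT_LC)
            rows.append(
                {
                    "animal_id": f"{profile}_{i + 1}",
                    "group": profile,
                    "true_fat_lc_ml": truth.fat_lc_ml,
                    "recovered_fat_lc_ml": recovered,
                    "rel_error": abs(recovered - truth.fat_lc_ml) / truth.fat_lc_ml,
                    "otsu_threshold": otsu.threshold,
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "parameter_recovery.csv", index=False)

    print(f"{len(df)} phantoms (sigma 30, base seed {BASE_SEED})")
    print(f"max relative fat-volume recovery error: {df.rel_error.max():.4%}")
    print(f"mean Otsu threshold: {df.otsu_threshold.mean():.1f} "
          f"(class means 100 / 1000)")
    print(f"written: {OUT / 'parameter_recovery.csv'}")


if __name__ == "__main__":
    main()
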