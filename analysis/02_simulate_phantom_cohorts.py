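#!/usr/bin/env python
"""Simulate two 9-animal phantom cohorts and quantify every case.

Control phantoms carry only the thin subcutaneous fat ring; disease
phantoms add macroscopic intramuscular clumps.  Each case is segmented
by per-case Otsu thresholding of its fat image and quantified into the
standard per-animal metrics.  Writes results/phantom_cohort.csv plus
the per-case ground truth in results/phantom_truth.csv.
"""

from pathlib import Path

import pandas as pd

from muscleq import PipelineConfig, cohort_specs, generate_phantom, run_pipeline

BASE_SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table, report = run_pipeline(
        PipelineConfig(mode="phantom", n_control=9, n_disease=9, base_seed=BASE_SEED)
    )
    table.to_csv(OUT / "phantom_cohort.csv", index=False)

    truth_rows = []
    for profile in ("control", "disease"):
        for i, spec in enumerate(cohort_specs(profile, 9, BASE_SEED)):
            _, _, truth = generate_phantom(spec)
            truth_rows.append(
                {
                    "animal_id": f"{profile}_{i + 1}",
                    "group": profile,
                    "true_lc_ml": truth.lc_ml,
                    "true_fat_lc_ml": truth.fat_lc_ml,
                    "true_muscle_lc_ml": truth.muscle_lc_ml,
                    "true_fat_infiltration": truth.fat_infiltration,
                }
            )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(OUT / "phantom_truth.csv", index=False)

    print(f"simulated {len(table)} phantoms (base seed {BASE_SEED}); "
          f"exclusions: {len(report['exclusions'])}")
    print(table.groupby("group")[["lc_ml", "fat_lc_ml", "muscle_lc_ml"]].mean().round(3))
    print(f"written: {OUT / 'phantom_cohort.csv'}, {OUT / 'phantom_truth.csv'}")


if __name__ == "__main__":
    main()
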