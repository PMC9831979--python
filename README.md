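# muscleq — quantitative Dixon-MRI muscle composition

`muscleq` quantifies fatty replacement of skeletal muscle from Dixon
fat/water MRI of mouse hind legs. It was built around the imaging
phenotype of myotonic dystrophy type 1 (DM1): the HSA^LR transgenic
mouse (expressing ~250 CUG repeats from a skeletal-actin transgene)
develops macroscopic fat clumps inside limb muscle, and quantitative
MRI can measure that replacement noninvasively — a prerequisite for
using imaging as a preclinical drug-evaluation endpoint. The package
is aimed at small-animal imaging groups who have co-registered fat and
water volumes (e.g. from an mDIXON reconstruction, converted to
NIfTI-1) and a manually drawn leg-compartment mask (e.g. from
ITK-SNAP).

## Method

For each animal, with both hind legs pooled into one manually
delineated leg compartment (LC — all muscle, fat and bone of the leg):

1. **Segmentation.** The LC is split into macroscopic-fat voxels
   (fat LC) and the remaining muscle-plus-bone voxels (muscle LC) by
   Otsu thresholding of the Dixon fat image restricted to the LC: the
   threshold `t*` maximises the between-class variance
   `σ_b²(t) = ω₀(t)·ω₁(t)·(μ₀(t) − μ₁(t))²` over the interior edges of
   a 256-bin histogram, computed per animal.
2. **Quantification.** Volumes are voxel counts × voxel volume
   (default protocol 0.14 × 0.14 × 1 mm, so 1000 voxels = 0.0196 ml).
   Per muscle-LC voxel the fat fraction is
   `FF = fat / (fat + water)`, summarised as a percent mean; fatty
   infiltration is `fat LC / LC`; the muscle-to-fat ratio is
   `muscle LC / fat LC`.
3. **Cohort statistics.** Two-group comparisons are routed by
   Shapiro–Wilk (normality, per group) and Levene (homoscedasticity):
   both normal + homoscedastic → ANOVA; both normal + heteroscedastic
   → Welch's ANOVA; otherwise a two-tailed Mann–Whitney U test whose
   small-sample p is exact — the permutation distribution of U over
   all C(n+m, n) group assignments of the observed midranks.

Because the original scans are not publicly deposited, the package
ships (a) the published per-animal reference table (9 control FVB vs 9
HSA^LR mice) as a checksummed fixture, and (b) a synthetic Dixon
leg-phantom generator (cylindrical legs with bone, a subcutaneous fat
ring, optional intramuscular fat clumps, and Rician noise) with
voxel-exact ground truth for validating the segmentation and
statistics by parameter recovery.

## Worked example

Reproduce the published cohort numbers from the packaged fixture:

```sh
python analysis/01_reproduce_reference.py
```

```
[PASS] infiltration_recomputation_max_abs_dev: 0.0015373134328358204 (expected <= 0.002)
[PASS] lc_volume_pct_increase: 18.210238374364994 (expected rounds to 18)
[PASS] fat_lc_mean_ratio: 3.846153846153846 (expected in (3.5, 4.0] (almost fourfold))
[PASS] infiltration_mean_ratio: 3.2841530054644807 (expected >= 3 (more than threefold))
...
overall: PASS
```

Reading: disease-model mice have an 18% larger leg compartment, a
3.85× larger macroscopic fat volume, and 3.28× higher fatty
infiltration than controls; recomputing infiltration from the printed
volume columns agrees with the printed values within the 0.002 allowed
by independent rounding. The gated decision tree reproduces the
published significance pattern at α = 0.05 (total volume, fat volume
and infiltration differ; muscle-only volume and fat fraction do not),
with Mann–Whitney U statistics 14.5, 0, 2, 20 and 25 respectively —
U = 0 means the two groups' fat volumes do not overlap at all, giving
the smallest achievable exact p, 2/C(18,9) ≈ 4.1e-5.

Simulate and analyse synthetic cohorts end-to-end:

```sh
python analysis/02_simulate_phantom_cohorts.py
python analysis/03_compare_phantom_cohorts.py
python analysis/04_parameter_recovery.py
```

```
fat_lc_ml          ANOVA         p=1.567e-15  significant  ratio=3.633
muscle_lc_ml       ANOVA         p=0.7297     n.s.         ratio=1.008
...
max relative fat-volume recovery error: 0.0000%
```

The phantom cohorts reproduce the qualitative disease pattern (fat
strongly increased, muscle volume unchanged), and at the default noise
level the Otsu segmentation recovers the true fat volume essentially
exactly (the fat/muscle intensity separation is ~15 noise standard
deviations; see `docs/methods.md`).

The same stages are available as a CLI (`muscleq phantom / segment /
quantify / collect / compare / run / reproduce-reference`) for use on
real NIfTI cases via a manifest CSV.

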