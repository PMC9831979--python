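# Methods

This note documents the models, numerical choices and limitations of
`muscleq`. Everything quantitative stated here is computed by the test
suite, the analysis drivers, or `scripts/acceptance.py`.

## Problem setting

Quantitative muscle MRI in myotonic dystrophy type 1 rests on a small
set of per-animal quantities derived from a Dixon fat/water
acquisition and a manually drawn leg-compartment (LC) mask: the LC
volume, the macroscopic-fat volume inside it (fat LC), the remaining
muscle-plus-bone volume (muscle LC), the mean muscle fat fraction, and
the fatty-infiltration ratio fat LC / LC. Bone is deliberately lumped
into muscle LC: at mouse scale bone cannot be separated reliably from
muscle at this resolution, and bone size can be assumed constant
across same-age, same-sex animals. The package computes these
quantities per animal (both hind legs pooled) and compares two cohorts.

## Segmentation

The LC is partitioned by Otsu's criterion applied to the fat-image
intensities inside the mask. Choices the criterion itself does not
fix, and how this implementation resolves them:

* **Candidates.** Interior edges of a 256-bin equal-width histogram
  over [min, max] of the LC-restricted intensities. 256 bins matches
  common 8-bit practice; the exhaustive-scan oracle test pins the
  behaviour.
* **Exact moments.** Class weights and means at each candidate are
  computed from the raw values via sorted prefix sums rather than from
  bin-centre moments. The result is therefore the exact maximiser of
  σ_b² over the candidate set; scikit-image's histogram-moment
  variant agrees to within one bin width on bimodal data (tested).
* **Tie-break and classification.** Among tied optima the smallest
  threshold is returned; fat is strict `>` the threshold.
* **Per animal.** The threshold is computed per case, never pooled
  over a cohort, so each animal's segmentation is independent of the
  others.
* **Degenerate input.** A constant fat image yields an empty fat mask
  (with a logged warning), not an error: a fat-free compartment is a
  valid biological outcome.

## Quantification

Volumes are voxel counts times the voxel volume read from the NIfTI
header (default protocol 0.14 × 0.14 × 1 mm in a 50 × 50 × 22 mm field
of view, 22 slices; 1 ml = 1000 mm³). The fat-fraction map
FF = fat/(fat+water) is evaluated over muscle-LC voxels only; voxels
with fat + water = 0 are excluded from the mean and counted, because
0/0 carries no tissue information. The per-animal summary is the
arithmetic percent mean (a median is available). FF is invariant
under common rescaling of both channels (property-tested), so scanner
gain does not affect it.

The published reference table labels its total-volume column "muscle
compartment"; the loader documents and exposes it as the total LC
volume, because fat / that column reproduces the printed infiltration
values (to ≤ 0.002, the slack created by independently rounding
numerator and denominator) whereas the muscle-only volume does not.
The worst printed-rounding case in the table is 0.0015.

## Cohort statistics

Routing: Shapiro–Wilk per group and Levene (median-centred,
Brown–Forsythe variant; mean centring selectable) across groups, both
at α = 0.05. Both groups normal and homoscedastic → one-way ANOVA;
both normal, heteroscedastic → Welch's ANOVA; any group non-normal —
or too small (n < 3) or constant, where normality is untestable →
two-tailed Mann–Whitney U. With two groups, ANOVA is implemented as
its two-group special case (pooled-variance comparison) and Welch's
ANOVA as Welch's t with F = t²; both branches are cross-checked
against pingouin in the tests. No multiple-testing correction is
applied across the five metrics by default.

**Exact Mann–Whitney.** U = min(U_x, U_y) from midrank rank sums. For
per-group sizes ≤ 12 the two-tailed p is
P(|U − nm/2| ≥ |u_obs − nm/2|) under the exact permutation
distribution of the observed midrank multiset, computed by a
subset-sum dynamic program over doubled midranks (integer weights;
subset counts < 2⁵³, so float64 counting is exact). This is
equivalent to enumerating all C(n+m, n) assignments and is valid in
the presence of ties; for tie-free data it reduces to the familiar
2·P(U ≤ u_obs). The centred two-sided definition was chosen over
2·P(U ≤ u_obs) because the latter is not invariant under swapping the
samples when ties make the null distribution asymmetric. Larger
samples use the normal approximation with tie-corrected variance and
a 0.5 continuity correction. Two equal constant samples are reported
as p = 1 with a warning.

The significance level α = 0.05 is the conventional threshold the
reference results imply; it is configurable everywhere.

## Synthetic phantom

The generator emulates a transverse Dixon acquisition of one or two
cylindrical mouse thighs:

* **Anatomy.** Each leg is a stack of identical circular
  cross-sections: bone (radius 0.8 mm) at the centre, muscle around
  it, and a thin subcutaneous fat ring at the surface; two legs are
  placed symmetrically about the grid midline. Disease-like anatomy
  adds spherical intramuscular fat clumps (clipped to the muscle
  region), mimicking the macroscopic fatty clumps seen at necropsy in
  the disease model.
* **Truth by voxel centre.** A voxel's class is decided by its centre
  point; there is no partial-volume mixing, so fat + muscle voxel
  counts equal the LC count exactly and conservation tests can demand
  1e-9 ml.
* **Intensities.** Class means default to fat image
  (muscle 100, fat 1000, bone 50) and water image (muscle 1000,
  fat 100, bone 80), giving the strongly bimodal fat image a real
  Dixon reconstruction shows. Noise is Rician — the magnitude of the
  noiseless signal plus two independent N(0, σ) channels, σ = 30 by
  default — so intensities stay non-negative and σ → 0 recovers the
  class means exactly.
* **Cohort profiles.** Per-animal anatomy is sampled from the profile:
  control, leg radius ~ N(4.5, 0.18) mm, ring ~ N(0.045, 0.006) mm,
  no clumps; disease, leg radius ~ N(4.62, 0.18) mm, same ring, 22
  clumps with radii U(0.8, 1.6) mm. The calibration targets the
  reference cohort's pattern: ≈3.5–4× mean fat volume and ≈3×
  infiltration between profiles, with the disease radius enlarged just
  enough that the expected muscle-LC volume matches control (so the
  "muscle volume unchanged" comparison is a true null). Per-animal
  radius variation is deliberate: with identical geometry across
  animals, within-group variance collapses to segmentation noise and
  any systematic offset between profiles becomes statistically
  significant, which no real cohort behaves like.
* **Determinism.** All sampling flows through one NumPy generator
  keyed on the spec seed; cohort specs are keyed on
  (profile, base seed). Identical inputs reproduce outputs
  bit-for-bit (tested).

What the phantom does **not** model: k-space/coil effects, bias
fields, chemical-shift or motion artifacts, partial-volume mixing,
anatomically realistic muscle sub-compartments, or any FF
heterogeneity within a tissue class. Consequences worth noting:

* With the default means, fat and muscle are separated by ~15 noise
  standard deviations, so Otsu recovery of the fat volume is
  essentially error-free (the 10%-recovery test passes with large
  margin). Real scans, with partial volume and bias fields, will not
  be this clean; the phantom validates the machinery, not clinical
  accuracy.
* Phantom muscle FF is a single number (100/1100 ≈ 9.1%) rather than
  the 9–18% spread of real animals; FF comparisons between phantom
  cohorts are therefore near-degenerate nulls, and with ~150,000
  muscle voxels per animal even tiny systematic differences (e.g. the
  slightly different bone fraction of the two profiles) can reach
  significance. The phantom validation targets are the fat and muscle
  volume comparisons, not FF.
* The "muscle not significant" comparison is a true null by
  calibration (expected muscle volumes match analytically), so over
  random base seeds it is rejected at roughly the type-I rate —
  measured at ~10-15% across seeds, somewhat above the nominal 5%
  because the 9-animal cohort means of the sampled leg radii and clump
  volumes fluctuate. The analysis drivers and tests use a fixed
  documented base seed (0), where the comparison is comfortably
  non-significant.

Problem sizes: tests use a reduced grid (90 × 90 × 8 voxels at
0.25 × 0.25 × 1 mm) for most phantom work and the full 357 × 357 × 22
grid for calibration, recovery and the end-to-end cohort runs; the
full suite completes in well under a minute.

## I/O and geometry

NIfTI-1 is the interchange format. Only grid shape and voxel spacing
are honoured; orientation metadata is ignored because no operation
compares voxels across cases. Spacing must be present and positive —
a header reporting non-positive zooms is an error, never defaulted
(NIfTI readers repair literal zero pixdims upstream; the guard covers
whatever reaches the geometry layer). Input LC masks are binarised
from any nonzero labelling, so single-label, multi-label (left/right
leg) and ITK-SNAP-style masks all work. Masks are stored as uint8,
images as float32. Fat/water/mask triplets must agree in shape
exactly and in spacing to a relative 1e-4.

## Pipeline behaviour

A failing case (unreadable file, incompatible grids, empty mask) is
excluded with a recorded reason and the run continues — cohort
attrition is explicit in the report, mirroring how motion-corrupted
animals are dropped from real studies, and exclusion never alters
surviving cases' values (tested). Every output embeds its
configuration and seeds for provenance. In phantom mode the phantom's
true LC mask stands in for the manual segmentation; manual tracing
itself is out of scope.

## Known limitations

* The reference cohort's in vivo FF means and body weights cannot be
  recomputed from first principles here (raw scans and per-animal
  weights are unavailable); they are covered only at the fixture
  level.
* Whether the original analysis thresholded per animal or on pooled
  histograms is not recorded; per-animal is assumed and documented.
* No spatial regularisation or morphology cleanup is applied after
  thresholding, and no multi-class Otsu; the fat/muscle split is
  purely intensity-based.
* DICOM ingestion, resampling/registration and bone/muscle
  sub-separation are out of scope.
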