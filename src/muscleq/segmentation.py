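"""Otsu thresholding of the Dixon fat image inside the leg compartment.

The compartment is split into macroscopic-fat voxels (bright on the fat
image) and the remaining muscle-plus-bone voxels by maximising the
between-class variance

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

over candidate thresholds t, where w0/w1 are the fractions of voxels at
or below / above t and mu0/mu1 their mean intensities.  Candidates are
the interior edges of an equal-width histogram over [min, max] (256
bins by default), but class weights and means are computed exactly from
the raw values via sorted prefix sums, not from binned moments.  Ties
resolve to the smallest optimal threshold; classification uses a strict
">" for fat.  The threshold is computed per case, never pooled across
a cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, InputError
from .image_io import (
    FAT_LC,
    LC,
    MUSCLE_LC,
    SEGMENTED_SEMANTICS,
    DixonPair,
    LabelMask,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of one Otsu threshold search."""

    threshold: float
    between_class_variance: float
    bins: int
    degenerate: bool


def _between_class_variance(values_sorted: np.ndarray, prefix: np.ndarray,
                            thresholds: np.ndarray) -> np.ndarray:
    """Exact sigma_b^2 at each threshold, classes split as (<= t) vs (> t)."""
    n = values_sorted.size
    k = np.searchsorted(values_sorted, thresholds, side="right")
    total = prefix[-1]
    sig = np.zeros_like(thresholds, dtype=float)
    valid = (k > 0) & (k < n)
    kv = k[valid]
    w0 = kv / n
    w1 = 1.0 - w0
    mu0 = prefix[kv] / kv
    mu1 = (total - prefix[kv]) / (n - kv)
    sig[valid] = w0 * w1 * (mu0 - mu1) ** 2
    return sig


def otsu_threshold(intensities: np.ndarray, bins: int = 256) -> OtsuResult:
    """Find the between-class-variance-maximising threshold.

    Parameters
    ----------
    intensities : array-like
        Non-negative intensity values (at least 2).
    bins : int
        Number of equal-width histogram bins spanning [min, max]; the
        candidate thresholds are the ``bins - 1`` interior bin edges.

    Returns
    -------
    OtsuResult
        With ``degenerate=True`` when all values are equal, in which
        case no separation exists and the threshold is the common value.
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size < 2:
        raise InputError(f"need at least 2 intensity values, got {v.size}")
    if bins < 2:
        raise InputError(f"need at least 2 histogram bins, got {bins}")
    if not np.all(np.isfinite(v)):
        raise DataError("intensities contain non-finite values")

    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return OtsuResult(threshold=lo, between_class_variance=0.0, bins=bins, degenerate=True)

    edges = np.linspace(lo, hi, bins + 1)[1:-1]
    v_sorted = np.sort(v)
    prefix = np.concatenate([[0.0], np.cumsum(v_sorted)])
    sig = _between_class_variance(v_sorted, prefix, edges)
    best = int(np.argmax(sig))  # argmax returns the first (smallest) optimum
    return OtsuResult(
        threshold=float(edges[best]),
        between_class_variance=float(sig[best]),
        bins=bins,
        degenerate=False,
    )


def segment_lc(pair: DixonPair, lc: LabelMask, bins: int = 256
               ) -> tuple[LabelMask, OtsuResult]:
    """Partition the LC into fat-LC and muscle-LC by Otsu on the fat image.

    Every LC voxel receives exactly one of the two labels: fat intensity
    strictly above the threshold -> fat-LC, otherwise muscle-LC.  A
    degenerate (constant) fat image yields an empty fat mask — a
    fat-free compartment is biologically meaningful, not an error.
    """
    if not pair.geometry.compatible_with(lc.geometry):
        raise InputError("Dixon pair and LC mask are on different grids")
    inside = lc.data == LC
    n_lc = int(inside.sum())
    if n_lc == 0:
        raise InputError("LC mask is empty")

    result = otsu_threshold(pair.fat[inside], bins=bins)
    out = np.zeros(lc.data.shape, dtype=np.uint8)
    if result.degenerate:
        log.warning(
            "degenerate Otsu input (constant fat intensity %.4g over %d LC voxels); "
            "labelling the whole compartment muscle-LC",
            result.threshold,
            n_lc,
        )
        out[inside] = MUSCLE_LC
    else:
        fat_vox = inside & (pair.fat > result.threshold)
        out[fat_vox] = FAT_LC
        out[inside & ~fat_vox] = MUSCLE_LC
    seg = LabelMask(data=out, geometry=lc.geometry, semantics=SEGMENTED_SEMANTICS)
    return seg, result
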