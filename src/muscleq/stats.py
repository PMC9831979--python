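"""Two-group comparison with gated test selection and exact Mann-Whitney.

The decision tree mirrors common practice for small preclinical
cohorts: Shapiro-Wilk normality per group and Levene homoscedasticity
across groups decide the test —

* both groups normal and homoscedastic  -> one-way ANOVA
  (for two groups, the pooled-variance comparison, F = t^2),
* both normal but heteroscedastic       -> Welch's ANOVA
  (two-group special case: Welch's t, F = t^2),
* any group non-normal (or too small to test) -> two-tailed
  Mann-Whitney U.

The Mann-Whitney p is exact for small samples: the null distribution
of U is the permutation distribution of the observed midrank multiset
over all C(n+m, n) group assignments, computed by a subset-sum dynamic
program (equivalent to full enumeration, and valid in the presence of
ties).  Larger samples fall back to the normal approximation with tie
and continuity corrections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError

log = logging.getLogger(__name__)

EXACT_MAX_N = 12  # per-group size up to which the exact enumeration runs


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float            # min(U_x, U_y), from midrank rank sums
    u_x: float
    u_y: float
    p: float            # two-tailed
    exact: bool         # enumeration (True) vs corrected normal approximation


def _rank_sums(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_x = float(ranks[: x.size].sum())
    u_x = r_x - x.size * (x.size + 1) / 2.0
    u_y = x.size * y.size - u_x
    return ranks, u_x, u_y


def _exact_two_sided_p(ranks: np.ndarray, n_x: int, u_x: float) -> float:
    """P(|U - nm/2| >= |u_x - nm/2|) under uniform assignment of n_x
    labels to the observed (mid)ranks.

    This two-sided definition is invariant under swapping the samples
    even when ties make the null distribution of U asymmetric.  Works
    on doubled midranks (integers) with a size-by-sum subset-count
    dynamic program — equivalent to enumerating all C(n+m, n)
    assignments; counts stay below 2^53 for the sizes admitted here,
    so float64 arithmetic is exact.
    """
    d = np.rint(2.0 * ranks).astype(np.int64)
    total = int(d.sum())
    n = ranks.size
    n_y = n - n_x
    f = np.zeros((n_x + 1, total + 1))
    f[0, 0] = 1.0
    for w in d:
        f[1:, w:] += f[:-1, : total + 1 - w]
    # doubled U for each doubled rank-sum s: s - n_x (n_x + 1); doubled
    # distribution centre is n_x * n_y.
    du = np.arange(total + 1) - n_x * (n_x + 1)
    du_obs = int(np.rint(2.0 * u_x))
    dev_obs = abs(du_obs - n_x * n_y)
    count = f[n_x, np.abs(du - n_x * n_y) >= dev_obs].sum()
    return min(1.0, float(count) / comb(n, n_x))


def _tie_corrected_sigma(ranks: np.ndarray, n_x: int, n_y: int) -> float:
    n = n_x + n_y
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    return float(np.sqrt(max(var, 0.0)))


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U with exact small-sample inference.

    U is min(U_x, U_y) from midrank rank sums.  For per-group sizes up
    to 12 the two-tailed p is P(|U - nm/2| >= |observed - nm/2|) under
    the exact permutation distribution of the observed ranks (equal to
    2 * P(U <= observed) for tie-free data); beyond that, the
    tie-corrected normal approximation with a 0.5 continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("samples contain non-finite values")

    ranks, u_x, u_y = _rank_sums(x, y)
    u_min = min(u_x, u_y)

    if np.ptp(np.concatenate([x, y])) == 0:
        # All observations identical: no evidence of any difference.
        log.warning("Mann-Whitney on two constant, equal samples; p = 1")
        return MannWhitneyResult(u=u_min, u_x=u_x, u_y=u_y, p=1.0, exact=True)

    if max(x.size, y.size) <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, x.size, u_x)
        return MannWhitneyResult(u=u_min, u_x=u_x, u_y=u_y, p=p, exact=True)

    sigma = _tie_corrected_sigma(ranks, x.size, y.size)
    if sigma == 0.0:
        return MannWhitneyResult(u=u_min, u_x=u_x, u_y=u_y, p=1.0, exact=False)
    z = (u_min - x.size * y.size / 2.0 + 0.5) / sigma
    p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
    return MannWhitneyResult(u=u_min, u_x=u_x, u_y=u_y, p=p, exact=False)


# ---------------------------------------------------------------------------
# Gates

@dataclass(frozen=True)
class GateResult:
    """Normality and homoscedasticity gate outcomes for two samples."""

    normal_x: bool
    normal_y: bool
    homoscedastic: bool
    normal_x_applicable: bool
    normal_y_applicable: bool
    homoscedastic_applicable: bool
    shapiro_p_x: float
    shapiro_p_y: float
    levene_p: float

    @property
    def both_normal(self) -> bool:
        return (
            self.normal_x_applicable
            and self.normal_y_applicable
            and self.normal_x
            and self.normal_y
        )


def _shapiro_gate(sample: np.ndarray, alpha: float) -> tuple[bool, bool, float]:
    if sample.size < 3 or np.ptp(sample) == 0:
        return False, False, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.shapiro(sample).pvalue)
    return p > alpha, True, p


def gate_tests(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    levene_center: str = "median",
) -> GateResult:
    """Shapiro-Wilk per group and Levene across groups at level ``alpha``.

    A sample too small (n < 3) or constant cannot be tested for
    normality; its gate is reported inapplicable, which routes the
    comparison to the Mann-Whitney branch.  Levene uses median
    centering by default (the robust Brown-Forsythe variant); mean
    centering is selectable.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    norm_x, app_x, p_x = _shapiro_gate(x, alpha)
    norm_y, app_y, p_y = _shapiro_gate(y, alpha)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        homo, app_l, p_l = False, False, float("nan")
    else:
        p_l = float(sps.levene(x, y, center=levene_center).pvalue)
        homo, app_l = p_l > alpha, True
    return GateResult(
        normal_x=norm_x,
        normal_y=norm_y,
        homoscedastic=homo,
        normal_x_applicable=app_x,
        normal_y_applicable=app_y,
        homoscedastic_applicable=app_l,
        shapiro_p_x=p_x,
        shapiro_p_y=p_y,
        levene_p=p_l,
    )


# ---------------------------------------------------------------------------
# Routed comparison

@dataclass(frozen=True)
class GroupComparisonResult:
    """One metric compared across two cohorts with the gated decision tree."""

    metric: str
    test: str  # "ANOVA" | "Welch-ANOVA" | "Mann-Whitney"
    statistic: float  # F for the ANOVA branches, U for Mann-Whitney
    p: float
    alpha: float
    significant: bool
    group_means: dict[str, float]
    group_medians: dict[str, float]
    fold_change: float  # mean(comparison) / mean(reference)
    gates: GateResult
    degenerate: bool = False


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str = "",
    reference: str | None = None,
) -> GroupComparisonResult:
    """Compare one metric across exactly two groups.

    ``reference`` names the group the fold change is computed against
    (comparison mean / reference mean); it defaults to the first key of
    the mapping.  Routing: both groups normal and homoscedastic ->
    ANOVA; both normal, heteroscedastic -> Welch's ANOVA; otherwise ->
    exact two-tailed Mann-Whitney U.
    """
    if len(groups) != 2:
        raise InputError(f"need exactly 2 groups, got {len(groups)}")
    names = list(groups)
    if reference is None:
        reference = names[0]
    if reference not in groups:
        raise InputError(f"reference group {reference!r} not among {names}")
    other = next(n for n in names if n != reference)
    x = np.asarray(groups[reference], dtype=float).ravel()
    y = np.asarray(groups[other], dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")

    gates = gate_tests(x, y, alpha=alpha)
    means = {reference: float(x.mean()), other: float(y.mean())}
    medians = {reference: float(np.median(x)), other: float(np.median(y))}
    fold = float(y.mean() / x.mean()) if x.mean() != 0 else float("nan")

    degenerate = np.ptp(np.concatenate([x, y])) == 0
    if degenerate:
        log.warning("metric %r: both groups constant and equal; reporting p = 1", metric)
        mw = mann_whitney_exact(x, y)
        test, statistic, p = "Mann-Whitney", mw.u, 1.0
    elif gates.both_normal and gates.homoscedastic_applicable and gates.homoscedastic:
        f, p = sps.f_oneway(x, y)
        test, statistic, p = "ANOVA", float(f), float(p)
    elif gates.both_normal:
        t, p = sps.ttest_ind(x, y, equal_var=False)
        test, statistic, p = "Welch-ANOVA", float(t) ** 2, float(p)
    else:
        mw = mann_whitney_exact(x, y)
        test, statistic, p = "Mann-Whitney", mw.u, mw.p

    return GroupComparisonResult(
        metric=metric,
        test=test,
        statistic=statistic,
        p=p,
        alpha=alpha,
        significant=bool(p < alpha),
        group_means=means,
        group_medians=medians,
        fold_change=fold,
        gates=gates,
        degenerate=degenerate,
    )


DEFAULT_METRICS = (
    "lc_ml",
    "fat_lc_ml",
    "muscle_lc_ml",
    "fat_fraction_pct",
    "fat_infiltration",
)


@dataclass(frozen=True)
class MetricSummary:
    """Fold-change report for one metric across the two cohorts."""

    metric: str
    mean_reference: float
    mean_comparison: float
    mean_ratio: float  # comparison / reference
    pct_increase: float  # 100 * (ratio - 1)
    median_reference: float
    median_comparison: float
    comparison: GroupComparisonResult


def cohort_summary(
    table,
    metrics: Sequence[str] = DEFAULT_METRICS,
    reference_group: str | None = None,
    alpha: float = 0.05,
) -> dict[str, MetricSummary]:
    """Per-metric fold changes and routed comparisons for a cohort table.

    ``table`` is a DataFrame with a ``group`` column and one column per
    metric.  The reference (control) group defaults to the
    lexicographically first group label.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise InputError(f"cohort table must contain exactly 2 groups, got {groups}")
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise InputError(f"reference group {reference_group!r} not among {groups}")
    comparison_group = next(g for g in groups if g != reference_group)

    out: dict[str, MetricSummary] = {}
    for metric in metrics:
        by_group = {
            g: table.loc[table["group"] == g, metric].to_numpy(dtype=float)
            for g in (reference_group, comparison_group)
        }
        res = compare_groups(by_group, alpha=alpha, metric=metric, reference=reference_group)
        mean_ref = res.group_means[reference_group]
        mean_cmp = res.group_means[comparison_group]
        ratio = res.fold_change
        out[metric] = MetricSummary(
            metric=metric,
            mean_reference=mean_ref,
            mean_comparison=mean_cmp,
            mean_ratio=ratio,
            pct_increase=100.0 * (ratio - 1.0),
            median_reference=res.group_medians[reference_group],
            median_comparison=res.group_medians[comparison_group],
            comparison=res,
        )
    return out
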