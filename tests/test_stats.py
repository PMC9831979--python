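"""Exact Mann-Whitney inference, gates, and routed group comparison."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from muscleq import (
    InputError,
    cohort_summary,
    compare_groups,
    gate_tests,
    mann_whitney_exact,
)

CNT, DM1 = "CNT", "DM1"


def _enumeration_oracle(x, y):
    """Two-tailed Mann-Whitney p by explicit enumeration of all
    C(n+m, n) group assignments of the pooled midranks: the fraction of
    assignments whose U deviates from nm/2 at least as much as the
    observed one."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n_x, n = len(x), len(pooled)
    n_y = n - n_x
    centre = n_x * n_y / 2
    u_obs_x = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    dev_obs = abs(u_obs_x - centre)
    count = 0
    for subset in combinations(range(n), n_x):
        u = ranks[list(subset)].sum() - n_x * (n_x + 1) / 2
        if abs(u - centre) >= dev_obs - 1e-9:
            count += 1
    return min(1.0, count / comb(n, n_x))


def test_complete_separation_u_zero():
    res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
    assert res.u == 0.0
    assert res.exact
    assert res.p == pytest.approx(2.0 / comb(6, 3), rel=1e-12)


def test_reference_fat_columns_complete_separation(reference_table):
    """The fat volumes of the two published cohorts do not overlap:
    U = 0 and the exact two-tailed p is 2 / C(18, 9)."""
    cnt = reference_table.loc[reference_table.group == CNT, "fat_lc_ml"]
    dm1 = reference_table.loc[reference_table.group == DM1, "fat_lc_ml"]
    res = mann_whitney_exact(cnt, dm1)
    assert res.u == 0.0
    assert res.exact
    assert res.p == pytest.approx(2.0 / comb(18, 9), rel=1e-12)


def test_reference_fat_fraction_not_significant(reference_table):
    cnt = reference_table.loc[reference_table.group == CNT, "fat_fraction_pct"]
    dm1 = reference_table.loc[reference_table.group == DM1, "fat_fraction_pct"]
    res = mann_whitney_exact(cnt, dm1)
    assert res.u == 25.0
    assert res.p > 0.05


@pytest.mark.parametrize(
    "n_x,n_y,tied",
    [(3, 3, False), (3, 5, False), (4, 4, True), (5, 7, False), (6, 6, True), (7, 7, False)],
)
def test_exact_p_matches_full_enumeration(n_x, n_y, tied, rng):
    """Implementation (subset-sum DP) vs explicit enumeration oracle,
    with and without ties, across several sample-size combinations."""
    for rep in range(3):
        if tied:
            x = rng.integers(0, 4, n_x).astype(float)
            y = rng.integers(1, 5, n_y).astype(float)
        else:
            x = rng.normal(0, 1, n_x)
            y = rng.normal(0.5, 1, n_y)
        res = mann_whitney_exact(x, y)
        assert res.exact
        assert res.p == pytest.approx(_enumeration_oracle(x, y), rel=1e-12)


def test_exact_p_matches_scipy_on_tie_free_samples(rng):
    for _ in range(5):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        res = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert min(ref.statistic, len(x) * len(y) - ref.statistic) == res.u


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 20), min_size=1, max_size=10),
    st.lists(st.integers(0, 20), min_size=1, max_size=10),
)
def test_u_sums_and_symmetry(xs, ys):
    x, y = np.array(xs, float), np.array(ys, float)
    res = mann_whitney_exact(x, y)
    assert res.u_x + res.u_y == pytest.approx(len(x) * len(y), abs=1e-9)
    assert res.u == min(res.u_x, res.u_y)
    flipped = mann_whitney_exact(y, x)
    assert flipped.u == res.u
    assert flipped.p == pytest.approx(res.p, rel=1e-12)
    assert 0.0 <= res.p <= 1.0


def test_large_sample_approximation_branch(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.8, 1, 30)
    res = mann_whitney_exact(x, y)
    assert not res.exact
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_empty_sample_rejected():
    with pytest.raises(InputError):
        mann_whitney_exact([], [1.0])


def test_gates_null_behaviour(rng):
    x = rng.normal(10, 2, 50)
    y = rng.normal(10, 2, 50)
    g = gate_tests(x, y)
    assert g.normal_x and g.normal_y and g.homoscedastic
    assert g.both_normal


def test_gate_detects_outlier_sample(reference_table):
    """The disease muscle volumes contain one low outlier among nine
    points; Shapiro-Wilk flags the sample as non-normal at 0.05."""
    dm1 = reference_table.loc[reference_table.group == DM1, "muscle_lc_ml"].to_numpy()
    cnt = reference_table.loc[reference_table.group == CNT, "muscle_lc_ml"].to_numpy()
    g = gate_tests(cnt, dm1)
    assert g.normal_x
    assert not g.normal_y
    assert g.shapiro_p_y < 0.05


def test_gates_invariant_to_sample_ordering(rng):
    x = rng.normal(0, 1, 12)
    y = rng.exponential(1, 12)
    g1 = gate_tests(x, y)
    g2 = gate_tests(x[::-1], np.sort(y))
    assert (g1.normal_x, g1.normal_y, g1.homoscedastic) == (
        g2.normal_x,
        g2.normal_y,
        g2.homoscedastic,
    )
    assert g2.shapiro_p_x == pytest.approx(g1.shapiro_p_x, rel=1e-9)
    assert g2.shapiro_p_y == pytest.approx(g1.shapiro_p_y, rel=1e-9)
    assert g2.levene_p == pytest.approx(g1.levene_p, rel=1e-9)


def test_small_or_constant_samples_route_to_mann_whitney():
    g = gate_tests([1.0, 2.0], [3.0, 4.0, 5.0])
    assert not g.normal_x_applicable
    res = compare_groups({"a": [1.0, 2.0], "b": [3.0, 4.0, 5.0]})
    assert res.test == "Mann-Whitney"
    g_const = gate_tests([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    assert not g_const.normal_x_applicable


def test_degenerate_equal_constant_groups():
    res = compare_groups({"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0]}, metric="m")
    assert res.degenerate
    assert res.p == 1.0
    assert not res.significant


def test_compare_groups_requires_two_groups():
    with pytest.raises(InputError):
        compare_groups({"a": [1.0, 2.0]})
    with pytest.raises(InputError):
        compare_groups({"a": [1.0], "b": [2.0], "c": [3.0]})


@pytest.mark.parametrize(
    "metric,expected_test,expected_sig",
    [
        ("lc_ml", "ANOVA", True),
        ("fat_lc_ml", "Welch-ANOVA", True),
        ("muscle_lc_ml", "Mann-Whitney", False),
        ("fat_fraction_pct", "ANOVA", False),
        ("fat_infiltration", "Welch-ANOVA", True),
    ],
)
def test_reference_routing_and_significance(reference_table, metric, expected_test, expected_sig):
    """The gated decision tree reproduces the published pattern: total
    and fat volumes and infiltration differ, muscle volume and fat
    fraction do not."""
    groups = {
        g: reference_table.loc[reference_table.group == g, metric].to_numpy()
        for g in (CNT, DM1)
    }
    res = compare_groups(groups, metric=metric, reference=CNT)
    assert res.test == expected_test
    assert res.significant == expected_sig
    # recorded gates must be consistent with the routing
    if res.test == "ANOVA":
        assert res.gates.both_normal and res.gates.homoscedastic
    elif res.test == "Welch-ANOVA":
        assert res.gates.both_normal and not res.gates.homoscedastic
    else:
        assert not res.gates.both_normal


def test_anova_branches_match_pingouin(reference_table):
    """Independent cross-check of both ANOVA branches against pingouin."""
    pingouin = pytest.importorskip("pingouin")
    df = reference_table.copy()
    welch = pingouin.welch_anova(data=df, dv="fat_lc_ml", between="group")
    res_w = compare_groups(
        {g: df.loc[df.group == g, "fat_lc_ml"].to_numpy() for g in (CNT, DM1)},
        metric="fat_lc_ml",
    )
    assert res_w.test == "Welch-ANOVA"
    assert res_w.p == pytest.approx(float(welch["p_unc"].iloc[0]), rel=1e-6)
    anova = pingouin.anova(data=df, dv="lc_ml", between="group")
    res_a = compare_groups(
        {g: df.loc[df.group == g, "lc_ml"].to_numpy() for g in (CNT, DM1)},
        metric="lc_ml",
    )
    assert res_a.test == "ANOVA"
    assert res_a.p == pytest.approx(float(anova["p_unc"].iloc[0]), rel=1e-6)


def test_cohort_summary_fold_changes(reference_table):
    s = cohort_summary(reference_table, reference_group=CNT)
    assert round(s["lc_ml"].pct_increase) == 18
    assert 3.5 < s["fat_lc_ml"].mean_ratio <= 4.0
    assert s["fat_infiltration"].mean_ratio >= 3.0
    assert s["lc_ml"].mean_ratio == pytest.approx(
        s["lc_ml"].mean_comparison / s["lc_ml"].mean_reference, rel=1e-12
    )
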