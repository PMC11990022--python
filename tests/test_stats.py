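"""Descriptives, adaptive test selection, MWU exactness, chi-squared, p format."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycendo import (chi_squared_2x2, choose_test, compare_table, describe,
                      format_p, mann_whitney_u)
from glycendo import TestKind as StatTestKind


def test_describe_categorical_matches_published_rendering():
    assert describe((17, 95), "categorical").formatted == "17 (18%)"
    assert describe((37, 95), "categorical").formatted == "37 (39%)"


def test_describe_quartiles_of_five_points():
    d = describe([1, 2, 3, 4, 5], "nongaussian")
    assert (d.median, d.q1, d.q3) == (3, 2, 4)


def test_describe_gaussian_mean_sem():
    d = describe([1.0, 2.0, 3.0], "gaussian")
    assert d.mean == pytest.approx(2.0)
    assert d.sem == pytest.approx(1.0 / math.sqrt(3))


def test_describe_empty_sample_errors():
    with pytest.raises(ValueError):
        describe([], "gaussian")


def test_choose_test_normal_samples_give_t():
    rng = np.random.default_rng(0)
    assert choose_test(rng.normal(0, 1, 200), rng.normal(0, 1, 200)) is StatTestKind.T


def test_choose_test_lognormal_gives_u():
    rng = np.random.default_rng(1)
    x = np.exp(rng.normal(0, 1.2, 200))
    y = rng.normal(0, 1, 200)
    assert choose_test(x, y) is StatTestKind.MANN_WHITNEY_U


def test_choose_test_unequal_variances_give_u():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 100)
    y = rng.normal(0, 5, 100)  # F-test p << 0.05, verified via the F distribution
    from scipy.stats import f
    stat = np.var(x, ddof=1) / np.var(y, ddof=1)
    p = 2 * min(f(99, 99).cdf(stat), f(99, 99).sf(stat))
    assert p < 0.05
    assert choose_test(x, y) is StatTestKind.MANN_WHITNEY_U


def test_choose_test_requires_n3():
    with pytest.raises(ValueError):
        choose_test([1, 2], [1, 2, 3])


def brute_force_mwu_p(x, y):
    """Exact two-sided MWU p by enumerating all rank assignments."""
    combined = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    us = []
    for idx in itertools.combinations(range(len(combined)), n1):
        g1 = [combined[i] for i in idx]
        g2 = [combined[i] for i in range(len(combined)) if i not in idx]
        u = sum(1 for a in g1 for b in g2 if a > b) \
            + 0.5 * sum(1 for a in g1 for b in g2 if a == b)
        us.append(u)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


def test_mwu_exact_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)


def test_mwu_symmetry_and_identity():
    x, y = [1.0, 5.0, 2.5], [4.0, 0.5, 6.0, 3.0]
    assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])
    assert mann_whitney_u(x, x)[1] == pytest.approx(1.0)
    assert mann_whitney_u([7, 7, 7], [7, 7])[1] == 1.0


def test_mwu_exact_matches_brute_force_enumeration():
    """Implementation equals enumeration over all rank assignments for every
    tie-free split with combined n <= 10."""
    rng = np.random.default_rng(11)
    for n1, n2 in [(1, 3), (2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (5, 5), (2, 8)]:
        for _ in range(5):
            data = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = data[:n1], data[n1:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(brute_force_mwu_p(x, y), rel=1e-12), (n1, n2)


def test_chi_squared_published_tables():
    _, p_dm = chi_squared_2x2(17, 78, 2, 47)
    assert format_p(p_dm) == "0.039"
    _, p_sex = chi_squared_2x2(37, 58, 21, 28)
    assert format_p(p_sex) == "0.78"


def test_chi_squared_no_association():
    stat, p = chi_squared_2x2(10, 10, 10, 10)
    assert stat == 0.0 and p == 1.0


def test_chi_squared_swap_invariance():
    p1 = chi_squared_2x2(17, 78, 2, 47)[1]
    p2 = chi_squared_2x2(2, 47, 17, 78)[1]       # row swap
    p3 = chi_squared_2x2(47, 2, 78, 17)[1]       # row + column swap
    assert p1 == pytest.approx(p2) == pytest.approx(p3)


def test_chi_squared_zero_margin_warns_p1():
    with pytest.warns(UserWarning):
        stat, p = chi_squared_2x2(0, 10, 0, 20)
    assert (stat, p) == (0.0, 1.0)


@pytest.mark.parametrize("p,expected", [
    (0.7842, "0.78"),
    (0.0393, "0.039"),
    (0.00003, "<0.0001"),
    (0.0001, "0.00010"),
    (0.54, "0.54"),
    (0.0999, "0.10"),
    (0.05, "0.050"),
])
def test_format_p(p, expected):
    assert format_p(p) == expected


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.floats(1e-4, 1.0))
def test_format_p_idempotent(p):
    out = format_p(p)
    assert format_p(float(out)) == out


def test_compare_table_structure(default_cohort):
    from glycendo import augment_cohort

    df = augment_cohort(default_cohort)
    comps = compare_table(df, ["glucose", "insulin", "homa_ir", "diabetes"],
                          "group", ("HS", "control"))
    assert [c.variable for c in comps] == ["glucose", "insulin", "homa_ir", "diabetes"]
    dm = comps[-1]
    assert dm.test is StatTestKind.CHI_SQUARED
    for c in comps:
        assert c.p is not None and 0 <= c.p <= 1
        assert c.p_formatted == format_p(c.p)


def test_compare_table_all_missing_group_not_evaluable(default_cohort):
    from glycendo import augment_cohort

    df = augment_cohort(default_cohort)  # controls have no HbA1c
    comp = compare_table(df, ["hba1c"], "group", ("HS", "control"))[0]
    assert comp.test is StatTestKind.NOT_EVALUABLE
    assert comp.groups["control"].formatted == "N/A"


def test_compare_table_empty_group_errors(default_cohort):
    df = default_cohort.to_dataframe()
    with pytest.raises(ValueError, match="group"):
        compare_table(df[df.group == "HS"], ["glucose"], "group", ("HS", "control"))
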