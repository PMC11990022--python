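"""Two-group comparison machinery for case-control cohort tables.

The reporting convention: Gaussian variables as mean ± SEM, non-Gaussian as
median (Q1–Q3), categorical as count (%).  Test selection is adaptive — a
t-test only when both samples pass a Kolmogorov–Smirnov-type normality
check (Lilliefors variant, parameters estimated from the data) and an
F-test for homogeneity of variances, both at alpha = 0.05; otherwise the
Mann–Whitney U test.  Categorical 2x2 comparisons use the Pearson
chi-squared test with Yates continuity correction.  P-values at or above
1e-4 are formatted with two significant digits, smaller ones as "<0.0001".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

ALPHA_GATES = 0.05  # level of the normality and variance-homogeneity checks
EXACT_MWU_MAX_N = 12  # combined sample size up to which the exact MWU null is used


class TestKind(str, Enum):
    T = "t"
    MANN_WHITNEY_U = "mann_whitney_u"
    CHI_SQUARED = "chi_squared"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class Descriptives:
    """One group's summary for one variable."""

    n: int
    mean: float | None = None
    sem: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    count: int | None = None
    percent: int | None = None
    formatted: str = ""


@dataclass
class GroupComparison:
    """One variable's two-group comparison: descriptives, test, statistic, p."""

    variable: str
    groups: dict[str, Descriptives] = field(default_factory=dict)
    test: TestKind = TestKind.NOT_EVALUABLE
    statistic: float | None = None
    p: float | None = None
    p_formatted: str = ""


def describe(values, distribution: str) -> Descriptives:
    """Summarise one sample.

    distribution: ``"gaussian"`` -> mean ± SEM; ``"nongaussian"`` -> median
    (Q1–Q3) with linear-interpolation quartiles; ``"categorical"`` -> values
    is a ``(count, total)`` pair, summarised as count (%) with the percent
    rounded to an integer.
    """
    if distribution == "categorical":
        count, total = values
        if total < 1:
            raise ValueError("categorical description needs total >= 1")
        pct = int(round(100.0 * count / total))
        return Descriptives(n=total, count=int(count), percent=pct,
                            formatted=f"{int(count)} ({pct}%)")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    if distribution == "gaussian":
        mean = float(np.mean(x))
        sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
        return Descriptives(n=x.size, mean=mean, sem=sem,
                            formatted=f"{mean:.2f} ± {sem:.2g}")
    if distribution == "nongaussian":
        q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
        return Descriptives(n=x.size, median=med, q1=q1, q3=q3,
                            formatted=f"{med:.2f} ({q1:.2f}–{q3:.2f})")
    raise ValueError(f"unknown distribution kind {distribution!r}")


def lilliefors_normal(x, alpha: float = ALPHA_GATES) -> bool:
    """Normality check: Lilliefors KS test with estimated parameters."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False  # too few points to establish normality, or zero variance
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return p >= alpha


def f_test_equal_variance(x, y, alpha: float = ALPHA_GATES) -> bool:
    """Two-sided F-test of equal variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        return False
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = 2 * min(dist.sf(f), dist.cdf(f))
    return p >= alpha


def choose_test(x, y) -> TestKind:
    """Select t vs Mann–Whitney U for two samples.

    t only when both samples pass the Lilliefors normality check and the
    F-test for equal variances, each at alpha = 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("choose_test needs n >= 3 in both groups")
    if lilliefors_normal(x) and lilliefors_normal(y) and f_test_equal_variance(x, y):
        return TestKind.T
    return TestKind.MANN_WHITNEY_U


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact-enumeration null for combined n <= 12 without ties; otherwise
    normal approximation with tie and continuity corrections.  Returns
    (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney_u needs n >= 1 in both groups")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def t_test(x, y) -> tuple[float, float]:
    """Equal-variance two-sample t-test (two-sided)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table with Yates continuity correction.

    Table layout: rows are groups, columns are outcome yes/no —
    [[a, b], [c, d]].  A zero margin yields statistic 0, p = 1 with a
    warning (no association is estimable).
    """
    if min(a, b, c, d) < 0 or (a + b + c + d) < 1:
        raise ValueError("counts must be >= 0 with a positive total")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has a zero margin; association not estimable")
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def format_p(p: float) -> str:
    """Format a p-value: "<0.0001" below 1e-4, else two significant digits
    with trailing zeros preserved ("0.039", "0.78", "0.050")."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be within [0, 1], got {p}")
    if p < 1e-4:
        return "<0.0001"
    decimals = max(0, 1 - math.floor(math.log10(p)))
    rounded = round(p, decimals)
    if rounded > 0:  # rounding may promote to the next magnitude (0.099 -> 0.1)
        decimals = max(0, 1 - math.floor(math.log10(rounded)))
        rounded = round(p, decimals)
    return f"{rounded:.{decimals}f}"


def _compare_continuous(name: str, x, y, labels) -> GroupComparison:
    comp = GroupComparison(variable=name)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        comp.groups = {
            labels[0]: Descriptives(n=x.size, formatted="N/A" if x.size == 0 else ""),
            labels[1]: Descriptives(n=y.size, formatted="N/A" if y.size == 0 else ""),
        }
        return comp
    if x.size < 3 or y.size < 3:
        kind = TestKind.MANN_WHITNEY_U  # too small to assess normality
    else:
        kind = choose_test(x, y)
    if kind is TestKind.T:
        stat, p = t_test(x, y)
        dist = "gaussian"
    else:
        stat, p = mann_whitney_u(x, y)
        dist = "nongaussian"
    comp.groups = {labels[0]: describe(x, dist), labels[1]: describe(y, dist)}
    comp.test, comp.statistic, comp.p = kind, stat, p
    comp.p_formatted = format_p(p)
    return comp


def _compare_categorical(name: str, x, y, labels) -> GroupComparison:
    # x, y: boolean arrays (complete cases) per group
    comp = GroupComparison(variable=name)
    a, b = int(np.sum(x)), int(len(x) - np.sum(x))
    c, d = int(np.sum(y)), int(len(y) - np.sum(y))
    if (a + b) == 0 or (c + d) == 0:
        comp.groups = {labels[0]: Descriptives(n=a + b, formatted="N/A"),
                       labels[1]: Descriptives(n=c + d, formatted="N/A")}
        return comp
    stat, p = chi_squared_2x2(a, b, c, d)
    comp.groups = {labels[0]: describe((a, a + b), "categorical"),
                   labels[1]: describe((c, c + d), "categorical")}
    comp.test, comp.statistic, comp.p = TestKind.CHI_SQUARED, stat, p
    comp.p_formatted = format_p(p)
    return comp


def compare_table(df, variables, group_col: str = "group",
                  group_values: tuple[str, str] | None = None) -> list[GroupComparison]:
    """One GroupComparison per variable between two groups of a DataFrame.

    ``variables`` is a list of column names; boolean columns are compared
    with the chi-squared test, numeric ones with the adaptive t/U choice.
    Complete-case handling is per variable.  ``group_values`` names the two
    groups (defaults to the two distinct values of ``group_col``, in order
    of appearance); both must be non-empty.
    """
    if group_values is None:
        seen = list(dict.fromkeys(df[group_col].tolist()))
        if len(seen) != 2:
            raise ValueError(f"grouping column {group_col!r} must yield exactly two groups, got {seen}")
        group_values = (seen[0], seen[1])
    g1 = df[df[group_col] == group_values[0]]
    g2 = df[df[group_col] == group_values[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"empty group in {group_col!r} split {group_values}")
    out = []
    for var in variables:
        x = g1[var].dropna()
        y = g2[var].dropna()
        if x.dtype == bool or y.dtype == bool or set(x.unique()) | set(y.unique()) <= {0, 1, True, False}:
            out.append(_compare_categorical(var, x.astype(bool).to_numpy(),
                                            y.astype(bool).to_numpy(), group_values))
        else:
            out.append(_compare_continuous(var, x.to_numpy(float),
                                           y.to_numpy(float), group_values))
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]):
    """Render a list of comparisons as a tidy DataFrame (one row per variable)."""
    import pandas as pd

    labels = list(comparisons[0].groups.keys()) if comparisons else []
    rows = []
    for c in comparisons:
        row = {"variable": c.variable}
        for lab in labels:
            d = c.groups.get(lab)
            row[str(lab)] = d.formatted if d else ""
            row[f"n_{lab}"] = d.n if d else 0
        row["test"] = c.test.value
        row["statistic"] = c.statistic
        row["p"] = c.p
        row["p_formatted"] = c.p_formatted + (" *" if c.p is not None and c.p < 0.05 else "")
        rows.append(row)
    return pd.DataFrame(rows)
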