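"""Comparison battery: chi-square against printed values and scipy
oracle, t-test hand cases, Mann-Whitney exact enumeration, report."""
import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import chi2_contingency

import pandas as pd

from endoscore.afs import ValidationError
from endoscore.roc import TwoByTwoTable
from endoscore.stats import (
    VariableSpec,
    build_report,
    mann_whitney,
    pearson_chi_square,
    students_t,
    students_t_from_stats,
)

# --- Pearson chi-square --------------------------------------------------


@pytest.mark.parametrize(
    "cells,expected",
    [
        ((24, 60, 61, 54), 11.881),  # clinical pregnancy, EFI groups
        ((37, 111, 83, 155), 4.153),  # implantation, EFI groups
        ((33, 51, 74, 41), 12.266),  # cumulative pregnancy, EFI groups
        ((310, 165, 614, 217), 10.862),  # embryo availability, stage groups
        ((70, 601, 84, 1079), 5.698),  # polypronucleate rate, stage groups
    ],
)
def test_chi_square_published_values(cells, expected):
    stat, p = pearson_chi_square(TwoByTwoTable(*cells))
    assert round(stat, 3) == expected
    assert 0.0 <= p <= 1.0


@pytest.mark.parametrize("k", [1, 5, 40])
def test_chi_square_independent_table_is_zero(k):
    stat, p = pearson_chi_square(TwoByTwoTable(k, k, k, k))
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValidationError):
        pearson_chi_square(TwoByTwoTable(0, 0, 5, 5))


tables = hst.tuples(*[hst.integers(min_value=1, max_value=200)] * 4)


@settings(max_examples=200, deadline=None)
@given(tables)
def test_chi_square_matches_scipy_oracle(cells):
    a, b, c, d = cells
    stat, p = pearson_chi_square(TwoByTwoTable(a, b, c, d))
    ref = chi2_contingency([[a, b], [c, d]], correction=False)
    assert stat == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)


@settings(max_examples=100, deadline=None)
@given(tables)
def test_chi_square_symmetries(cells):
    a, b, c, d = cells
    base, _ = pearson_chi_square(TwoByTwoTable(a, b, c, d))
    rows_swapped, _ = pearson_chi_square(TwoByTwoTable(c, d, a, b))
    cols_swapped, _ = pearson_chi_square(TwoByTwoTable(b, a, d, c))
    transposed, _ = pearson_chi_square(TwoByTwoTable(a, c, b, d))
    assert base == pytest.approx(rows_swapped, rel=1e-12)
    assert base == pytest.approx(cols_swapped, rel=1e-12)
    assert base == pytest.approx(transposed, rel=1e-12)


# --- Student's t ---------------------------------------------------------


def test_t_identical_groups():
    t, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_hand_case():
    t, p = students_t([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=0.001)


def test_t_from_published_age_summaries():
    t, p = students_t_from_stats(33.3, 4.9, 84, 31.1, 3.3, 115)
    assert abs(t) == pytest.approx(3.789, abs=0.05)
    assert p < 0.001


def test_t_zero_pooled_variance_rejected():
    with pytest.raises(ValidationError):
        students_t([2.0, 2.0, 2.0], [2.0, 2.0])


def test_t_requires_two_per_group():
    with pytest.raises(ValidationError):
        students_t([1.0], [2.0, 3.0])


@settings(max_examples=100, deadline=None)
@given(
    hst.lists(hst.floats(-50, 50), min_size=2, max_size=20),
    hst.lists(hst.floats(-50, 50), min_size=2, max_size=20),
)
def test_t_group_exchange_negates_statistic(a, b):
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return
    t_ab, p_ab = students_t(a, b)
    t_ba, p_ba = students_t(b, a)
    assert t_ab == pytest.approx(-t_ba, abs=1e-9)
    assert p_ab == pytest.approx(p_ba, abs=1e-12)
    assert 0.0 <= p_ab <= 1.0


# --- Mann-Whitney --------------------------------------------------------


def exact_two_sided_p(a, b):
    """Oracle: enumerate all assignments of the pooled values to group
    sizes and count tables at least as extreme in |U - mean U|."""
    import collections

    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    positions = collections.defaultdict(list)
    for i, v in enumerate(sorted(pooled)):
        positions[v].append(i + 1)
    rank_of = {v: sum(ps) / len(ps) for v, ps in positions.items()}  # midranks

    def u_stat(group):
        r1 = sum(rank_of[v] for v in group)
        return r1 - n1 * (n1 + 1) / 2.0

    observed = abs(u_stat(list(a)) - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        group = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(group) - mu) >= observed - 1e-12:
            count += 1
    return count / total


def test_mw_identical_samples():
    z, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_mw_hand_case_exact():
    z, p = mann_whitney([1, 2, 3], [4, 5, 6], method="exact")
    assert p == pytest.approx(0.1, abs=1e-12)
    assert p == pytest.approx(exact_two_sided_p([1, 2, 3], [4, 5, 6]))
    assert z < 0  # first group stochastically smaller


def test_mw_exact_matches_enumeration_interleaved():
    a, b = [1, 2, 5], [3, 4, 6]
    _, p = mann_whitney(a, b, method="exact")
    assert p == pytest.approx(exact_two_sided_p(a, b), abs=1e-9)


def test_mw_z_grows_with_sample_size():
    zs = []
    for n in (5, 20, 80):
        a = list(range(n))
        b = [x + n for x in a]
        z, _ = mann_whitney(a, b)
        zs.append(abs(z))
    assert zs[0] < zs[1] < zs[2]


def test_mw_group_exchange_negates_z():
    a = [1.0, 3.0, 5.0, 7.0]
    b = [2.0, 4.0, 10.0]
    z_ab, p_ab = mann_whitney(a, b)
    z_ba, p_ba = mann_whitney(b, a)
    assert z_ab == pytest.approx(-z_ba, abs=1e-12)
    assert p_ab == pytest.approx(p_ba, abs=1e-12)


def test_mw_requires_nonempty():
    with pytest.raises(ValidationError):
        mann_whitney([], [1.0])


# --- report builder ------------------------------------------------------


def _toy_cohort():
    rng = np.random.default_rng(5)
    n = 60
    return pd.DataFrame(
        {
            "group": ["lo"] * 30 + ["hi"] * 30,
            "age_years": rng.normal(32, 4, n),
            "oocytes": rng.poisson(8, n),
            "events": rng.integers(0, 2, n),
            "embryos": rng.integers(1, 4, n),
            "implants": rng.integers(0, 2, n),
        }
    )


def test_report_rate_rows_recompute_percentages():
    df = _toy_cohort()
    spec = [
        VariableSpec("events", "rate", numerator="events"),
        VariableSpec("impl", "rate", numerator="implants",
                     denominator="embryos"),
    ]
    rep = build_report(df, "group", spec, group_order=["lo", "hi"])
    lo = df[df.group == "lo"]
    expected_pct = 100.0 * lo.events.sum() / len(lo)
    assert f"({expected_pct:.1f})" in rep.iloc[0]["group_lo"]
    # per-embryo denominator
    expected_impl = 100.0 * lo.implants.sum() / lo.embryos.sum()
    assert f"({expected_impl:.1f})" in rep.iloc[1]["group_lo"]


def test_report_routes_tests_per_declared_kind():
    df = _toy_cohort()
    spec = [
        VariableSpec("age", "normal", column="age_years"),
        VariableSpec("oocytes", "nonnormal", column="oocytes"),
        VariableSpec("events", "rate", numerator="events"),
    ]
    rep = build_report(df, "group", spec)
    assert list(rep["test"]) == ["t", "mann-whitney z", "chi2"]
    assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()


def test_report_skips_missing_variable_with_warning(caplog):
    df = _toy_cohort()
    spec = [
        VariableSpec("age", "normal", column="age_years"),
        VariableSpec("ghost", "normal", column="not_there"),
    ]
    with caplog.at_level(logging.WARNING):
        rep = build_report(df, "group", spec)
    assert len(rep) == 1
    assert "ghost" in caplog.text


def test_report_rejects_empty_or_nonbinary_grouping():
    df = _toy_cohort()
    df["all_same"] = "x"
    with pytest.raises(ValidationError):
        build_report(df, "all_same", [])
    with pytest.raises(ValidationError):
        build_report(df, "missing_col", [])


def test_variable_spec_validation():
    with pytest.raises(ValidationError):
        VariableSpec("x", "weird", column="c")
    with pytest.raises(ValidationError):
        VariableSpec("x", "rate")
    with pytest.raises(ValidationError):
        VariableSpec("x", "normal")
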