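"""Tabulation and contingency-table inference."""

import numpy as np
import pandas as pd
import pytest

from xskew.errors import (
    DegenerateTableError,
    InsufficientDataError,
    InvalidParameterError,
)
from xskew.stats import (
    AgeBinning,
    ContingencyTable,
    compare_mean_age,
    fisher_exact,
    g_test,
    headline_test,
    pearson_chi_square,
    percentage,
    stage_table,
    tabulate,
    two_group_table,
)


def table(rows, labels=None):
    rows = np.asarray(rows)
    r = labels or tuple(f"r{i}" for i in range(rows.shape[0]))
    c = tuple(f"c{j}" for j in range(rows.shape[1]))
    return ContingencyTable(tuple(r), c, rows)


def pearson_oracle(counts):
    """Hand evaluation of sum (O-E)^2 / E with margin-product expectations."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    return float(((counts - expected) ** 2 / expected).sum())


def frame_from_counts(rows):
    """Subject-level frame realising (age, k, n) frequency rows."""
    recs = []
    for age, k, n in rows:
        for i in range(n):
            recs.append({"age_years": age, "informative": True, "sxci_cr3": i < k, "sxci_cr10": False})
    return pd.DataFrame(recs)


def test_percentage_rounds_half_up_to_one_decimal():
    assert percentage(2, 46) == 4.3
    assert percentage(37, 144) == 25.7
    assert percentage(1, 8) == 12.5
    assert percentage(1, 800) == 0.1  # 0.125 -> half-up
    assert percentage(0, 0) is None


def test_homogeneous_table_has_zero_statistic():
    t = table([[5, 5], [5, 5]])
    assert pearson_chi_square(t).statistic == pytest.approx(0.0, abs=1e-12)
    assert pearson_chi_square(t).p_value == pytest.approx(1.0)
    assert g_test(t).statistic == pytest.approx(0.0, abs=1e-12)


def test_pearson_matches_hand_formula():
    counts = [[5, 9], [13, 157]]
    res = pearson_chi_square(table(counts))
    assert res.statistic == pytest.approx(pearson_oracle(counts), abs=1e-9)
    assert res.statistic == pytest.approx(11.55, abs=0.01)
    assert res.df == 1


def test_yates_never_exceeds_uncorrected(rng):
    for _ in range(50):
        counts = rng.integers(1, 60, size=(2, 2))
        t = table(counts)
        assert pearson_chi_square(t, yates=True).statistic <= pearson_chi_square(t).statistic + 1e-12


def test_pearson_equals_squared_two_proportion_z():
    # algebraic identity on 2x2 tables
    for counts in ([[5, 9], [13, 157]], [[20, 30], [40, 10]], [[3, 7], [9, 11]]):
        (a, b), (c, d) = counts
        n1, n2 = a + b, c + d
        p1, p2, p = a / n1, c / n2, (a + c) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert pearson_chi_square(table(counts)).statistic == pytest.approx(z**2, abs=1e-9)


def test_fisher_exact_edge_and_reference_tables():
    assert fisher_exact(table([[1, 0], [0, 1]])).p_value == pytest.approx(1.0)
    assert fisher_exact(table([[10, 90], [10, 90]])).p_value == pytest.approx(1.0)
    res = fisher_exact(table([[5, 9], [13, 157]]))
    assert res.p_value < 0.01
    assert round(res.p_value, 3) == 0.006
    with pytest.raises(InvalidParameterError):
        fisher_exact(table([[1, 2, 3], [4, 5, 6]]))


def test_g_and_pearson_agree_on_large_balanced_tables(rng):
    for shape in ((2, 2), (3, 3)):
        probs = np.full(shape, 1.0 / (shape[0] * shape[1]))
        for _ in range(10):
            counts = rng.multinomial(20_000, probs.ravel()).reshape(shape)
            t = table(counts)
            g = g_test(t).statistic
            x2 = pearson_chi_square(t).statistic
            assert abs(g - x2) / x2 < 0.05


def test_degenerate_margins_raise():
    with pytest.raises(DegenerateTableError):
        pearson_chi_square(table([[0, 0], [5, 5]]))
    with pytest.raises(DegenerateTableError):
        g_test(table([[5, 0], [5, 0]]))


def test_headline_rule_switches_on_small_expected_counts():
    small = two_group_table(5, 14, 13, 170)  # expected events < 5 in a cell
    assert headline_test(small).method == "fisher_exact"
    big = two_group_table(40, 200, 30, 200)
    assert headline_test(big).method == "pearson"


def test_type_one_error_is_calibrated(rng):
    # two identical binomial groups; uncorrected Pearson at alpha=.05
    n, p, reps = 200, 0.3, 10_000
    k1 = rng.binomial(n, p, size=reps)
    k2 = rng.binomial(n, p, size=reps)
    rejections = 0
    for a, c in zip(k1, k2):
        if a + c == 0 or a + c == 2 * n:
            continue
        t = two_group_table(int(a), n, int(c), n)
        if pearson_chi_square(t).p_value < 0.05:
            rejections += 1
    assert rejections / reps == pytest.approx(0.05, abs=0.01)


def test_age_association_on_reference_counts_is_strong():
    t = table([[2, 44], [13, 153], [37, 107]], labels=("neonates", "16-50", "51-96"))
    assert g_test(t).p_value < 0.001
    assert pearson_chi_square(t).p_value < 0.001


def test_welch_identical_and_separated_samples(rng):
    ages = [50.0, 60.0, 70.0, 80.0]
    cmp = compare_mean_age(ages, ages)
    assert cmp.difference == 0.0
    assert cmp.result.p_value == pytest.approx(1.0)
    with pytest.raises(InsufficientDataError):
        compare_mean_age([50.0], ages)

    # power check: mu 73 vs 58, sd 15, n 50 -> near-certain rejection
    reps, hits = 300, 0
    for _ in range(reps):
        a = rng.normal(73, 15, 50)
        b = rng.normal(58, 15, 50)
        if compare_mean_age(a, b).result.p_value < 0.05:
            hits += 1
    assert hits / reps >= 0.99


def test_three_group_binning_and_gap_exclusion():
    binning = AgeBinning("three_group")
    assert binning.assign(19 / 365.25) == "neonates"
    assert binning.assign(41.0) == "16-50"
    assert binning.assign(73.0) == "51-96"
    assert binning.assign(5.0) is None  # the study's recruitment gap
    df = frame_from_counts([(19 / 365.25, 2, 46), (41.0, 13, 166), (73.0, 37, 144), (5.0, 1, 3)])
    tab = tabulate(df, binning, "moderate")
    assert tab.n_excluded == 3
    assert tab.table.total == 356  # conservation of informative, binnable subjects
    assert tab.percentages == {"neonates": 4.3, "16-50": 7.8, "51-96": 25.7}


def test_five_group_pooling_consistent_with_three_group():
    rows = [(19 / 365.25, 2, 46), (25.0, 3, 61), (41.0, 10, 105), (60.0, 7, 65), (80.0, 30, 79)]
    df = frame_from_counts(rows)
    five = tabulate(df, AgeBinning("five_group"), "moderate")
    assert five.percentages == {
        "neonates": 4.3, "16-30": 4.9, "31-50": 9.5, "51-70": 10.8, "71-96": 38.0
    }
    three = tabulate(df, AgeBinning("three_group"), "moderate")
    pooled_k = five.table.counts[3, 0] + five.table.counts[4, 0]
    pooled_n = five.table.counts[3].sum() + five.table.counts[4].sum()
    assert (pooled_k, pooled_n) == (three.table.counts[2, 0], three.table.counts[2].sum())
    assert (pooled_k, pooled_n) == (37, 144)


def test_forty_split_uses_eligibility_window():
    binning = AgeBinning("forty_split")
    assert binning.assign(38.0) == "<=40"
    assert binning.assign(41.0) == ">40"
    assert binning.assign(90.0) is None  # outside the 16-83 window
    assert binning.assign(1.0) is None


def test_stage_table_percentages_and_heterogeneity():
    recs = []
    for stage, k, n in [("I", 7, 88), ("IIA", 2, 10), ("IIB", 1, 10), ("III", 2, 15), ("IV", 1, 11)]:
        for i in range(n):
            recs.append(
                {"stage": stage, "informative": True, "sxci_cr3": i < k, "sxci_cr10": False}
            )
    df = pd.DataFrame(recs)
    tab, pct, het = stage_table(df, "moderate")
    assert pct == {"I": 8.0, "IIA": 20.0, "IIB": 10.0, "III": 13.3, "IV": 9.1}
    assert tab.total == 134
    assert het.p_value > 0.05  # no stage heterogeneity in these counts
    with pytest.raises(InvalidParameterError):
        stage_table(df.assign(stage="V"), "moderate")
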