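"""Frequency tabulation and contingency-table inference for SXCI cohorts.

Counts of skewed / non-skewed subjects are cross-tabulated by age bin,
case-control group or tumour stage, and compared with the Pearson chi-square
test (optionally Yates-corrected), the likelihood-ratio G-test, or Fisher's
exact test; mean ages of skewed vs non-skewed subjects are compared with a
Welch two-sample t.  Percentages are rounded half-up to one decimal, the
convention used throughout the reported tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    InvalidParameterError,
)
from .population import NEONATE_MAX_AGE_YEARS

__all__ = [
    "AgeBinning",
    "ContingencyTable",
    "TestResult",
    "TabulationResult",
    "MeanAgeComparison",
    "percentage",
    "tabulate",
    "two_group_table",
    "pearson_chi_square",
    "fisher_exact",
    "g_test",
    "headline_test",
    "compare_mean_age",
    "stage_table",
]

SXCI_COLUMNS = {"moderate": "sxci_cr3", "stringent": "sxci_cr10"}


def percentage(k: int, n: int) -> Optional[float]:
    """100*k/n rounded half-up to one decimal; None for an empty bin."""
    if n == 0:
        return None
    q = (Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise InvalidParameterError("counts shape does not match labels")
        if (counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        if counts.sum() == 0:
            raise InvalidParameterError("grand total must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def _check_testable(self) -> None:
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise DegenerateTableError("need at least 2 rows and 2 columns")
        if (self.counts.sum(axis=0) == 0).any() or (self.counts.sum(axis=1) == 0).any():
            raise DegenerateTableError("table has a zero margin")


@dataclass(frozen=True)
class TestResult:
    method: str  # pearson | pearson_yates | fisher_exact | g_test | welch_t
    statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidParameterError("p-value outside [0, 1]")
        if self.df < 0:
            raise InvalidParameterError("df must be >= 0")


@dataclass(frozen=True)
class AgeBinning:
    """Maps an age in years to a named bin.

    Schemes: ``three_group`` (neonates <=28 d / 16-50 y / 51-96 y),
    ``five_group`` (neonates / 16-30 / 31-50 / 51-70 / 71-96) and
    ``forty_split`` (<=40 vs >40 inside an eligibility window, default
    16-83 years).  Ages in the study's recruitment gap (29 days - 15 years)
    or outside the window map to no bin and are excluded with a count.
    Adult five-group bins are half-open on integer boundaries
    ([16, 31) labelled "16-30", and so on).
    """

    scheme: str
    eligibility: Optional[tuple[float, float]] = None

    SCHEMES = ("three_group", "five_group", "forty_split")

    def __post_init__(self) -> None:
        if self.scheme not in self.SCHEMES:
            raise InvalidParameterError(f"unknown binning scheme {self.scheme!r}")
        if self.scheme == "forty_split" and self.eligibility is None:
            object.__setattr__(self, "eligibility", (16.0, 83.0))

    @property
    def labels(self) -> tuple[str, ...]:
        if self.scheme == "three_group":
            return ("neonates", "16-50", "51-96")
        if self.scheme == "five_group":
            return ("neonates", "16-30", "31-50", "51-70", "71-96")
        return ("<=40", ">40")

    def assign(self, age: float) -> Optional[str]:
        if self.scheme == "forty_split":
            lo, hi = self.eligibility
            if not (lo <= age <= hi):
                return None
            return "<=40" if age <= 40.0 else ">40"
        if age <= NEONATE_MAX_AGE_YEARS:
            return "neonates"
        if self.scheme == "three_group":
            if 16.0 <= age < 51.0:
                return "16-50"
            if 51.0 <= age <= 96.0:
                return "51-96"
            return None
        for lo, hi, label in (
            (16.0, 31.0, "16-30"),
            (31.0, 51.0, "31-50"),
            (51.0, 71.0, "51-70"),
            (71.0, 96.0 + 1e-9, "71-96"),
        ):
            if lo <= age < hi:
                return label
        return None


@dataclass(frozen=True)
class TabulationResult:
    """A bin x {SXCI, no SXCI} table plus the rounded per-bin percentages."""

    table: ContingencyTable
    percentages: dict[str, Optional[float]]
    threshold: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        # self-audit: every percentage re-derivable from the counts
        for i, label in enumerate(self.table.row_labels):
            k = int(self.table.counts[i, 0])
            n = int(self.table.counts[i].sum())
            if self.percentages[label] != percentage(k, n):
                raise InvalidParameterError(f"percentage audit failed for {label}")


def _sxci_column(threshold: str) -> str:
    if threshold not in SXCI_COLUMNS:
        raise InvalidParameterError(
            f"threshold must be one of {sorted(SXCI_COLUMNS)}, got {threshold!r}"
        )
    return SXCI_COLUMNS[threshold]


def tabulate(
    df: pd.DataFrame, binning: AgeBinning, threshold: str = "moderate"
) -> TabulationResult:
    """Cross-tabulate SXCI status by age bin over informative subjects.

    ``df`` needs columns ``age_years``, ``informative`` and the flag column
    for the requested threshold (``sxci_cr3`` / ``sxci_cr10``).  Subjects
    mapping to no bin are excluded and counted in ``n_excluded``.
    """
    col = _sxci_column(threshold)
    sub = df[df["informative"].astype(bool)]
    bins = sub["age_years"].map(binning.assign)
    excluded = int(bins.isna().sum())
    sub = sub[bins.notna()]
    bins = bins.dropna()
    counts = np.zeros((len(binning.labels), 2), dtype=np.int64)
    for i, label in enumerate(binning.labels):
        mask = bins == label
        flags = sub.loc[mask, col].astype(bool)
        counts[i, 0] = int(flags.sum())
        counts[i, 1] = int((~flags).sum())
    table = ContingencyTable(binning.labels, ("SXCI", "no SXCI"), counts)
    pct = {
        label: percentage(int(counts[i, 0]), int(counts[i].sum()))
        for i, label in enumerate(binning.labels)
    }
    return TabulationResult(table, pct, threshold, excluded)


def two_group_table(
    k1: int, n1: int, k2: int, n2: int, labels: tuple[str, str] = ("patients", "controls")
) -> ContingencyTable:
    """2x2 group x {SXCI, no SXCI} table from two (events, examined) pairs."""
    if min(k1, k2) < 0 or k1 > n1 or k2 > n2:
        raise InvalidParameterError("need 0 <= k <= n in each group")
    return ContingencyTable(
        labels, ("SXCI", "no SXCI"), np.array([[k1, n1 - k1], [k2, n2 - k2]])
    )


def pearson_chi_square(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence.

    The Yates continuity correction is applied only to 2x2 tables when
    requested; the p-value comes from the chi-square upper tail with
    (r-1)(c-1) degrees of freedom.
    """
    table._check_testable()
    if yates and table.counts.shape == (2, 2):
        # continuity correction with |O-E|-0.5 floored at 0
        expected = scipy.stats.contingency.expected_freq(table.counts)
        dev = np.maximum(np.abs(table.counts - expected) - 0.5, 0.0)
        stat = float((dev**2 / expected).sum())
        return TestResult("pearson_yates", stat, 1.0, float(scipy.stats.chi2.sf(stat, 1)))
    res = scipy.stats.chi2_contingency(table.counts, correction=False)
    return TestResult("pearson", float(res.statistic), float(res.dof), float(res.pvalue))


def g_test(table: ContingencyTable) -> TestResult:
    """Likelihood-ratio G-test: G = 2 sum O ln(O/E), chi-square reference."""
    table._check_testable()
    res = scipy.stats.chi2_contingency(
        table.counts, correction=False, lambda_="log-likelihood"
    )
    return TestResult("g_test", float(res.statistic), float(res.dof), float(res.pvalue))


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Fisher's exact test for a 2x2 table (two-sided).

    Statistic is the sample cross-product odds ratio, with 0 and infinity
    for empty off-/on-diagonals.
    """
    if table.counts.shape != (2, 2):
        raise InvalidParameterError("Fisher exact test needs a 2x2 table")
    (a, b), (c, d) = table.counts
    res = scipy.stats.fisher_exact(table.counts, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.float64(a * d) / np.float64(b * c)
    return TestResult("fisher_exact", float(odds), 0.0, float(res.pvalue))


def headline_test(table: ContingencyTable) -> TestResult:
    """Default 2x2 comparison: Fisher when any expected count is below 5,
    otherwise the uncorrected Pearson chi-square."""
    table._check_testable()
    expected = scipy.stats.contingency.expected_freq(table.counts)
    if table.counts.shape == (2, 2) and (expected < 5).any():
        return fisher_exact(table)
    return pearson_chi_square(table, yates=False)


@dataclass(frozen=True)
class MeanAgeComparison:
    result: TestResult
    mean_sxci: float
    mean_no_sxci: float

    @property
    def difference(self) -> float:
        return self.mean_sxci - self.mean_no_sxci


def compare_mean_age(
    ages_sxci: Sequence[float], ages_no_sxci: Sequence[float]
) -> MeanAgeComparison:
    """Welch two-sample comparison of mean age, skewed vs non-skewed."""
    a = np.asarray(ages_sxci, dtype=float)
    b = np.asarray(ages_no_sxci, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 ages per group")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    tr = TestResult("welch_t", float(res.statistic), float(res.df), float(res.pvalue))
    return MeanAgeComparison(tr, float(a.mean()), float(b.mean()))


def stage_table(
    df: pd.DataFrame, threshold: str = "moderate", stages: Sequence[str] | None = None
) -> tuple[ContingencyTable, dict[str, Optional[float]], TestResult]:
    """Per-tumour-stage SXCI frequencies plus a G-test of heterogeneity.

    ``df`` holds informative patients with a ``stage`` column; unknown stage
    labels are an error.
    """
    from .population import STAGES

    stages = tuple(stages) if stages is not None else STAGES
    col = _sxci_column(threshold)
    sub = df[df["informative"].astype(bool)]
    unknown = set(sub["stage"].dropna()) - set(stages)
    if unknown:
        raise InvalidParameterError(f"unknown stage labels: {sorted(unknown)}")
    counts = np.zeros((len(stages), 2), dtype=np.int64)
    for i, stage in enumerate(stages):
        flags = sub.loc[sub["stage"] == stage, col].astype(bool)
        counts[i, 0] = int(flags.sum())
        counts[i, 1] = int((~flags).sum())
    table = ContingencyTable(tuple(stages), ("SXCI", "no SXCI"), counts)
    pct = {
        stage: percentage(int(counts[i, 0]), int(counts[i].sum()))
        for i, stage in enumerate(stages)
    }
    return table, pct, g_test(table)
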