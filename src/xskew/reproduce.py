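"""Recompute the published SXCI tables from their bundled raw counts.

No simulation is involved: the inputs are the printed events/examined counts
(overall, three and five age groups, the case-control age strata and the
tumour stages), and the outputs are the percentages and test statistics a
reader finds in the published tables — a self-contained audit that the
tabulation and inference code reproduces them to the printed precision.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .io import load_printed_counts, load_printed_informativeness
from .stats import (
    ContingencyTable,
    fisher_exact,
    g_test,
    headline_test,
    pearson_chi_square,
    percentage,
    two_group_table,
)

__all__ = ["reproduce_printed_tables"]

_THRESHOLD_LABEL = {3: "CR >= 3", 10: "CR >= 10"}


def _sxci_table(rows: list[tuple[str, int, int]]) -> ContingencyTable:
    labels = tuple(label for label, _, _ in rows)
    counts = np.array([[k, n - k] for _, k, n in rows])
    return ContingencyTable(labels, ("SXCI", "no SXCI"), counts)


def reproduce_printed_tables() -> dict[str, Any]:
    """Rebuild every published percentage and headline test from raw counts."""
    counts = load_printed_counts()
    info = load_printed_informativeness()

    report: dict[str, Any] = {"frequencies": {}, "informativeness": {}, "tests": {}}

    for (table, thr), sub in counts.groupby(["table", "threshold"], sort=False):
        dest = report["frequencies"].setdefault(table, {})
        label = _THRESHOLD_LABEL[int(thr)]
        dest[label] = {
            row.group: {
                "k": int(row.k),
                "n": int(row.n),
                "percent": percentage(int(row.k), int(row.n)),
            }
            for row in sub.itertuples(index=False)
        }

    for row in info.itertuples(index=False):
        report["informativeness"][row.group] = {
            "k": int(row.k),
            "n": int(row.n),
            "percent": percentage(int(row.k), int(row.n)),
        }
    ik = report["informativeness"]
    ct = two_group_table(
        ik["patients"]["k"], ik["patients"]["n"], ik["controls"]["k"], ik["controls"]["n"]
    )
    # "informative vs not" 2x2; the published comparison is non-significant
    report["tests"]["informativeness_patients_vs_controls"] = _test_dict(
        pearson_chi_square(ct)
    )

    # age association: likelihood-ratio test over the three age groups
    for thr in (3, 10):
        rows = [
            (g, d["k"], d["n"])
            for g, d in report["frequencies"]["three_group"][_THRESHOLD_LABEL[thr]].items()
        ]
        report["tests"][f"age_association_three_group_cr{thr}"] = _test_dict(
            g_test(_sxci_table(rows))
        )

    # case-control strata of the published Table: Pearson, Yates and Fisher,
    # with the headline rule (Fisher when any expected count < 5)
    for thr in (3, 10):
        t1 = report["frequencies"]["table1"][_THRESHOLD_LABEL[thr]]
        for stratum in ("le40", "gt40", "all"):
            pat, con = t1[f"patients_{stratum}"], t1[f"controls_{stratum}"]
            table = two_group_table(pat["k"], pat["n"], con["k"], con["n"])
            entry = {
                "pearson": _test_dict(pearson_chi_square(table)),
                "pearson_yates": _test_dict(pearson_chi_square(table, yates=True)),
                "fisher_exact": _test_dict(fisher_exact(table)),
                "headline": _test_dict(headline_test(table)),
            }
            report["tests"][f"patients_vs_controls_{stratum}_cr{thr}"] = entry

    # tumour-stage heterogeneity
    stage_rows = [
        (g, d["k"], d["n"])
        for g, d in report["frequencies"]["stage"]["CR >= 3"].items()
    ]
    report["tests"]["stage_heterogeneity_cr3"] = _test_dict(g_test(_sxci_table(stage_rows)))

    _check_consistency(report)
    return report


def _test_dict(result) -> dict[str, float]:
    return {
        "method": result.method,
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
    }


def _check_consistency(report: dict[str, Any]) -> None:
    """Integer cross-checks tying the tables together."""
    freq = report["frequencies"]
    three = freq["three_group"]["CR >= 3"]
    five = freq["five_group"]["CR >= 3"]
    checks = {
        "five_group elderly bins pool to the three_group elderly cell": (
            five["51-70"]["k"] + five["71-96"]["k"] == three["51-96"]["k"]
            and five["51-70"]["n"] + five["71-96"]["n"] == three["51-96"]["n"]
        ),
        "three_group events sum to the overall events": (
            sum(d["k"] for d in three.values()) == freq["overall"]["CR >= 3"]["informative"]["k"]
        ),
        "stage denominators sum to the informative patients": (
            sum(d["n"] for d in freq["stage"]["CR >= 3"].values())
            == freq["table1"]["CR >= 3"]["patients_all"]["n"]
        ),
    }
    failed = [name for name, ok in checks.items() if not ok]
    if failed:
        raise InvalidParameterError(f"printed-count consistency failed: {failed}")
    report["consistency"] = {name: "ok" for name in checks}
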