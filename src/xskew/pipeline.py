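"""End-to-end orchestration: simulate -> assay -> call -> tabulate -> test.

`run_pipeline` executes the whole in-silico study from a :class:`RunConfig`:
it generates the configured cohorts, runs the simulated HUMARA assay, calls
SXCI from corrected ratios, builds the frequency tables and inferential
tests, and writes every intermediate artefact (cohort, intensity and call
CSVs, frequency TSVs, report JSON).  The run is deterministic for fixed
seeds, and every percentage written to the report is re-derived from its own
counts before the bundle is returned (self-consistency audit).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .assay import simulate_assays
from .cr import DISPLAY_CAP, call_assays
from .errors import InvalidParameterError
from .io import RunConfig, write_calls_csv, write_cohort_csv, write_intensity_csv
from .population import Subject, simulate_cohort
from .stats import (
    AgeBinning,
    TabulationResult,
    compare_mean_age,
    g_test,
    headline_test,
    percentage,
    stage_table,
    tabulate,
    two_group_table,
)

__all__ = ["run_pipeline", "join_calls", "audit_report"]

log = logging.getLogger("xskew")


def join_calls(subjects: list[Subject], calls) -> pd.DataFrame:
    """Subject-level analysis frame: demographics joined to CR calls."""
    subj = pd.DataFrame(
        {
            "subject_id": [s.id for s in subjects],
            "age_years": [s.age_years for s in subjects],
            "cohort": [s.cohort for s in subjects],
            "stage": [s.stage for s in subjects],
            "p_inactive_a": [s.p_inactive_a for s in subjects],
        }
    )
    call = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in calls],
            "informative": [c.informative for c in calls],
            "cr": [c.cr if c.cr is not None else np.nan for c in calls],
            "sxci_cr3": [bool(c.sxci_moderate) for c in calls],
            "sxci_cr10": [bool(c.sxci_stringent) for c in calls],
        }
    )
    return subj.merge(call, on="subject_id", validate="one_to_one")


def _fmt_cell(k: int, n: int) -> str:
    return f"{k} ({percentage(k, n)})"


def _tab_to_report(tab: TabulationResult, cr_label: str) -> dict[str, Any]:
    rows: dict[str, Any] = {}
    for i, label in enumerate(tab.table.row_labels):
        k = int(tab.table.counts[i, 0])
        n = int(tab.table.counts[i].sum())
        rows[label] = {
            "Numbers examined": n,
            f"Numbers with {cr_label}(%)": _fmt_cell(k, n),
        }
    return rows


def _tab_tsv(tab: TabulationResult, cr_label: str, path: Path) -> None:
    frame = tab.table.to_frame()
    frame["Numbers examined"] = frame.sum(axis=1)
    frame[f"Numbers with {cr_label}(%)"] = [
        _fmt_cell(int(tab.table.counts[i, 0]), int(tab.table.counts[i].sum()))
        for i in range(len(tab.table.row_labels))
    ]
    frame[["Numbers examined", f"Numbers with {cr_label}(%)"]].to_csv(path, sep="\t")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr_labels = {
        "moderate": f"CR >= {config.thresholds[0]:g}",
        "stringent": f"CR >= {config.thresholds[1]:g}",
    }

    report: dict[str, Any] = {
        "thresholds": {"moderate": config.thresholds[0], "stringent": config.thresholds[1]},
        "display_cap": DISPLAY_CAP,
        "attrition": {},
        "frequency_tables": {},
        "tests": {},
        "mean_age": {},
    }

    frames: dict[str, pd.DataFrame] = {}
    assay_rng = np.random.default_rng(config.assay.seed)
    for name in sorted(config.population):  # fixed order -> deterministic stream
        pop_cfg = config.population[name]
        subjects = simulate_cohort(pop_cfg)
        results = simulate_assays(subjects, config.assay, rng=assay_rng)
        calls = call_assays(results, thresholds=config.thresholds)
        df = join_calls(subjects, calls)
        frames[name] = df
        n_inf = int(df["informative"].sum())
        report["attrition"][name] = {
            "recruited": len(df),
            "informative": n_inf,
            "called": n_inf,
        }
        log.info(
            "%s cohort: recruited %d -> informative %d -> called %d",
            name, len(df), n_inf, n_inf,
        )
        write_cohort_csv(subjects, outdir / f"cohort_{name}.csv")
        write_intensity_csv(results, outdir / f"intensities_{name}.csv")
        write_calls_csv(calls, outdir / f"calls_{name}.csv")

    control = frames.get("control")
    patient = frames.get("patient")

    if control is not None:
        for scheme in ("three_group", "five_group"):
            binning = AgeBinning(scheme)
            report["frequency_tables"][scheme] = {}
            for threshold, cr_label in thr_labels.items():
                tab = tabulate(control, binning, threshold)
                if tab.n_excluded:
                    log.warning(
                        "%s/%s: %d subjects outside every age bin excluded",
                        scheme, threshold, tab.n_excluded,
                    )
                report["frequency_tables"][scheme][cr_label] = _tab_to_report(tab, cr_label)
                _tab_tsv(tab, cr_label, outdir / f"table_{scheme}_{threshold}.tsv")
                try:
                    report["tests"][f"age_association_{scheme}_{threshold}"] = _test_dict(
                        g_test(tab.table)
                    )
                except Exception as exc:  # degenerate bins stay out of the tests
                    log.warning("%s/%s age test skipped: %s", scheme, threshold, exc)

        for threshold in ("moderate", "stringent"):
            col = {"moderate": "sxci_cr3", "stringent": "sxci_cr10"}[threshold]
            inf = control[control["informative"]]
            sxci_ages = inf.loc[inf[col], "age_years"]
            other_ages = inf.loc[~inf[col], "age_years"]
            if len(sxci_ages) >= 2 and len(other_ages) >= 2:
                cmp = compare_mean_age(sxci_ages, other_ages)
                report["mean_age"][f"control_{threshold}"] = {
                    "mean_age_sxci": cmp.mean_sxci,
                    "mean_age_no_sxci": cmp.mean_no_sxci,
                    "difference": cmp.difference,
                    **_test_dict(cmp.result),
                }

    if patient is not None and control is not None:
        binning = AgeBinning("forty_split", tuple(config.eligibility_window))
        report["frequency_tables"]["forty_split"] = {}
        for threshold, cr_label in thr_labels.items():
            tp = tabulate(patient, binning, threshold)
            tc = tabulate(control, binning, threshold)
            strata: dict[str, Any] = {}
            for i, stratum in enumerate(binning.labels):
                kp, np_ = int(tp.table.counts[i, 0]), int(tp.table.counts[i].sum())
                kc, nc = int(tc.table.counts[i, 0]), int(tc.table.counts[i].sum())
                strata[stratum] = {
                    "patients": {"Numbers examined": np_, f"Numbers with {cr_label}(%)": _fmt_cell(kp, np_)},
                    "controls": {"Numbers examined": nc, f"Numbers with {cr_label}(%)": _fmt_cell(kc, nc)},
                }
                if min(np_, nc) > 0:
                    table = two_group_table(kp, np_, kc, nc)
                    try:
                        strata[stratum]["P-value"] = _test_dict(headline_test(table))
                    except Exception as exc:
                        log.warning("forty_split %s test skipped: %s", stratum, exc)
            report["frequency_tables"]["forty_split"][cr_label] = strata

    if patient is not None:
        staged = patient[patient["stage"].notna()]
        if len(staged):
            try:
                table, pct, het = stage_table(staged, "moderate")
                report["frequency_tables"]["stage"] = {
                    thr_labels["moderate"]: {
                        stage: {
                            "Numbers examined": int(table.counts[i].sum()),
                            f"Numbers with {thr_labels['moderate']}(%)": _fmt_cell(
                                int(table.counts[i, 0]), int(table.counts[i].sum())
                            ),
                        }
                        for i, stage in enumerate(table.row_labels)
                    }
                }
                report["tests"]["stage_heterogeneity_moderate"] = _test_dict(het)
            except Exception as exc:
                log.warning("stage table skipped: %s", exc)

    audit_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _test_dict(result) -> dict[str, Any]:
    return {
        "method": result.method,
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
    }


_CELL_RE = re.compile(r"^(\d+) \((\d+(?:\.\d+)?|None)\)$")


def audit_report(report: dict[str, Any]) -> None:
    """Verify that every "k (percent)" cell matches its own "Numbers examined".

    Walks the report recursively; any dict carrying both a count cell and a
    denominator is re-derived through :func:`xskew.stats.percentage`.
    """

    def walk(node: Any) -> None:
        if not isinstance(node, dict):
            return
        n = node.get("Numbers examined")
        if n is not None:
            for key, value in node.items():
                if isinstance(value, str) and key.startswith("Numbers with"):
                    m = _CELL_RE.match(value)
                    if not m:
                        raise InvalidParameterError(f"unparseable report cell {value!r}")
                    k = int(m.group(1))
                    pct = None if m.group(2) == "None" else float(m.group(2))
                    if percentage(k, int(n)) != pct:
                        raise InvalidParameterError(
                            f"report audit failed: {value!r} vs n={n}"
                        )
        for value in node.values():
            walk(value)

    walk(report)
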