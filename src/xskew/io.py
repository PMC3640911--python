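"""CSV/JSON formats: cohort tables, band-intensity tables, calls, run config.

The band-intensity CSV (``subject_id,allele_a_pre,allele_b_pre,allele_a_post,
allele_b_post[,homozygous]``) is the pipeline's lingua franca — real
densitometry exports can be coerced to it.  All files are RFC-4180 CSV with a
mandatory header, UTF-8, decimal point; lines starting with ``#`` are
comments.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import zlib
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .assay import AssayConfig, AssayResult
from .cr import CRCall
from .errors import InputValidationError, InvalidParameterError
from .population import AgeBand, PopulationConfig, Subject

__all__ = [
    "RunConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_intensity_table",
    "write_intensity_csv",
    "read_calls_csv",
    "write_calls_csv",
    "load_printed_counts",
    "load_printed_informativeness",
]

INTENSITY_COLUMNS = (
    "subject_id",
    "allele_a_pre",
    "allele_b_pre",
    "allele_a_post",
    "allele_b_post",
)

COHORT_COLUMNS = ("id", "age_years", "cohort", "allele_a", "allele_b")


# ---------------------------------------------------------------- cohort CSV


def write_cohort_csv(
    subjects: Iterable[Subject], path: str | Path, include_truth: bool = True
) -> None:
    """Write a cohort table; ``include_truth=False`` hides the latent
    inactivation fraction, for blinded fixtures."""
    header = list(COHORT_COLUMNS) + (["p_inactive_a"] if include_truth else []) + ["stage"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in subjects:
            row = [s.id, f"{s.age_years:.6f}", s.cohort, s.allele_a_repeats, s.allele_b_repeats]
            if include_truth:
                row.append(f"{s.p_inactive_a:.10f}")
            row.append(s.stage or "")
            w.writerow(row)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InputValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise InputValidationError(f"{path}: duplicate subject id {dup!r}")
    if "stage" in df.columns:
        df["stage"] = df["stage"].replace("", np.nan)
    return df


def cohort_to_subjects(df: pd.DataFrame) -> list[Subject]:
    if "p_inactive_a" not in df.columns:
        raise InputValidationError(
            "cohort table is blinded (no p_inactive_a); cannot simulate the assay"
        )
    out = []
    for row in df.itertuples(index=False):
        stage = getattr(row, "stage", None)
        if stage is not None and (pd.isna(stage) or stage == ""):
            stage = None
        out.append(
            Subject(
                id=str(row.id),
                age_years=float(row.age_years),
                cohort=str(row.cohort),
                allele_a_repeats=int(row.allele_a),
                allele_b_repeats=int(row.allele_b),
                p_inactive_a=float(row.p_inactive_a),
                stage=stage,
            )
        )
    return out


# ------------------------------------------------------------- intensity CSV


def write_intensity_csv(results: Iterable[AssayResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(INTENSITY_COLUMNS) + ["homozygous"])
        for r in results:
            # shortest round-tripping float repr: read(write(x)) is identity
            w.writerow(
                [
                    r.subject_id,
                    repr(r.i_a_pre),
                    repr(r.i_b_pre),
                    repr(r.i_a_post),
                    repr(r.i_b_post),
                    int(r.homozygous),
                ]
            )


def read_intensity_table(path: str | Path) -> list[AssayResult]:
    """Read and validate a band-intensity CSV.

    Raises :class:`InputValidationError` with the offending line number for a
    missing column, a non-numeric or negative intensity, or a duplicate
    subject id.  A missing ``homozygous`` column is inferred from an absent
    allele-b pre-digestion band.
    """
    results: list[AssayResult] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        # filter comment lines but keep line numbers aligned
        reader = csv.reader(fh)
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = [h.strip() for h in row]
                missing = set(INTENSITY_COLUMNS) - set(header)
                if missing:
                    raise InputValidationError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}"
                    )
                continue
            rec = dict(zip(header, row))
            sid = rec.get("subject_id", "").strip()
            if not sid:
                raise InputValidationError(f"{path}:{lineno}: empty subject_id")
            if sid in seen:
                raise InputValidationError(f"{path}:{lineno}: duplicate subject id {sid!r}")
            seen.add(sid)
            vals = {}
            for col in INTENSITY_COLUMNS[1:]:
                try:
                    v = float(rec[col])
                except (KeyError, ValueError):
                    raise InputValidationError(
                        f"{path}:{lineno}: non-numeric value in column {col!r}"
                    ) from None
                if not np.isfinite(v):
                    raise InputValidationError(
                        f"{path}:{lineno}: non-finite value in column {col!r}"
                    )
                if v < 0:
                    raise InputValidationError(
                        f"{path}:{lineno}: negative intensity in column {col!r}"
                    )
                vals[col] = v
            hz_raw = rec.get("homozygous")
            homozygous = (
                bool(int(hz_raw)) if hz_raw not in (None, "") else vals["allele_b_pre"] == 0.0
            )
            results.append(
                AssayResult(
                    subject_id=sid,
                    i_a_pre=vals["allele_a_pre"],
                    i_b_pre=vals["allele_b_pre"],
                    i_a_post=vals["allele_a_post"],
                    i_b_post=vals["allele_b_post"],
                    homozygous=homozygous,
                )
            )
    if header is None:
        raise InputValidationError(f"{path}: empty file")
    return results


# ------------------------------------------------------------------ calls CSV


def write_calls_csv(calls: Iterable[CRCall], path: str | Path) -> None:
    def flag(v: Optional[bool]) -> str:
        return "" if v is None else str(int(v))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "informative", "cr", "sxci_cr3", "sxci_cr10"])
        for c in calls:
            cr = "" if c.cr is None else (f"{c.cr:.6f}" if np.isfinite(c.cr) else "inf")
            w.writerow([c.subject_id, int(c.informative), cr, flag(c.sxci_moderate), flag(c.sxci_stringent)])


def read_calls_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "informative", "cr", "sxci_cr3", "sxci_cr10"}
    missing = required - set(df.columns)
    if missing:
        raise InputValidationError(f"{path}: missing columns {sorted(missing)}")
    df["informative"] = df["informative"].astype(bool)
    for col in ("sxci_cr3", "sxci_cr10"):
        df[col] = df[col].map(lambda v: bool(v) if pd.notna(v) else False)
    return df


# ------------------------------------------------------------------ fixtures


def load_printed_counts() -> pd.DataFrame:
    """Bundled published cross-tabulation counts (k events out of n)."""
    with resources.files("xskew.data").joinpath("printed_counts.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_printed_informativeness() -> pd.DataFrame:
    with resources.files("xskew.data").joinpath("printed_informativeness.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


# ----------------------------------------------------------------- run config


@dataclasses.dataclass
class RunConfig:
    """Full pipeline configuration (see ``xskew report --config``).

    JSON layout::

        {
          "seed": 1,
          "output_dir": "out",
          "thresholds": {"moderate": 3.0, "stringent": 10.0},
          "binning": "three_group",
          "eligibility_window": [16, 83],
          "population": {"control": {...}, "patient": {...}},
          "assay": {...}
        }

    Population blocks take the :class:`PopulationConfig` field names, with
    ``age_distribution`` as ``[[lo, hi, weight], ...]``; the assay block
    takes :class:`AssayConfig` field names.
    """

    population: dict[str, PopulationConfig]
    assay: AssayConfig
    thresholds: tuple[float, float] = (3.0, 10.0)
    binning: str = "three_group"
    eligibility_window: tuple[float, float] = (16.0, 83.0)
    output_dir: Path = Path("xskew-out")
    seed: Optional[int] = None
    log_level: str = "INFO"

    def validate(self) -> None:
        moderate, stringent = self.thresholds
        if not (0 < moderate < stringent):
            raise InvalidParameterError("thresholds must satisfy moderate < stringent")
        if not self.population:
            raise InvalidParameterError("at least one population block is required")
        for cfg in self.population.values():
            cfg.validate()
        self.assay.validate()

    @classmethod
    def from_json(cls, path: str | Path, seed_override: Optional[int] = None) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw, seed_override=seed_override)

    @classmethod
    def from_dict(cls, raw: dict, seed_override: Optional[int] = None) -> "RunConfig":
        seed = seed_override if seed_override is not None else raw.get("seed")
        if seed is None and "population" in raw:
            raise InvalidParameterError("a seed is required for any simulation step")
        pop = {}
        for name, block in raw.get("population", {}).items():
            block = dict(block)
            if "age_distribution" in block:
                block["age_distribution"] = [
                    (AgeBand(lo, hi), w) for lo, hi, w in block["age_distribution"]
                ]
            block.setdefault("cohort", name)
            block.setdefault("seed", _derive_seed(seed, name))
            pop[name] = PopulationConfig(**block)
        assay_block = dict(raw.get("assay", {}))
        if "amp_bias_range" in assay_block:
            assay_block["amp_bias_range"] = tuple(assay_block["amp_bias_range"])
        assay_block.setdefault("seed", _derive_seed(seed, "assay"))
        thresholds = raw.get("thresholds", {"moderate": 3.0, "stringent": 10.0})
        cfg = cls(
            population=pop,
            assay=AssayConfig(**assay_block),
            thresholds=(float(thresholds["moderate"]), float(thresholds["stringent"])),
            binning=raw.get("binning", "three_group"),
            eligibility_window=tuple(raw.get("eligibility_window", (16.0, 83.0))),
            output_dir=Path(raw.get("output_dir", "xskew-out")),
            seed=seed,
            log_level=raw.get("log_level", "INFO"),
        )
        cfg.validate()
        return cfg


def _derive_seed(seed: Optional[int], stream: str) -> int:
    """Derive an independent per-stream seed below 2**31 from the run seed."""
    if seed is None:
        return 0
    stream_key = zlib.crc32(stream.encode("utf-8"))  # stable across processes
    ss = np.random.SeedSequence([int(seed), stream_key])
    return int(ss.generate_state(1)[0] % (2**31))
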