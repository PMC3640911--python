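"""Synthetic female cohorts with realistic X-inactivation (Lyonization) structure.

In early female embryogenesis each cell of a small precursor pool independently
and permanently silences one of its two X chromosomes; all descendant blood
cells inherit that choice.  The fraction ``p`` of blood cells in which a given
X is the inactive one is therefore ``K/N`` for ``K ~ Binomial(N, 1/2)`` with
``N`` the precursor-pool size — *inborn* skewing is simply the tail of this
binomial.  On top of that, clonal selection and drift in the haematopoietic
compartment push ``p`` away from its inborn value over decades of adult life
(*acquired* skewing), which is modelled here as a Gaussian random walk on the
logit of ``p`` whose variance grows linearly with years past an onset age.

Subjects also carry a CAG short-tandem-repeat genotype at the androgen
receptor (AR) locus; only heterozygous ("informative") subjects can be scored
by the downstream assay, with population heterozygosity around 90%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import InvalidParameterError

__all__ = [
    "AgeBand",
    "PopulationConfig",
    "Subject",
    "NEONATE_MAX_AGE_YEARS",
    "DEFAULT_DRIFT_SD",
    "DEFAULT_DRIFT_ONSET_AGE",
    "STAGES",
    "apply_age_drift",
    "default_control_age_distribution",
    "default_patient_age_distribution",
    "sample_genotype",
    "sample_inborn_skew",
    "simulate_cohort",
]

DAYS_PER_YEAR = 365.25

#: Oldest age (in years) still counted as a neonate: 28 days.
NEONATE_MAX_AGE_YEARS = 28.0 / DAYS_PER_YEAR

#: Default acquired-drift scale, in logit units per sqrt(year), produced by
#: :func:`xskew.calibrate.calibrate_drift_sd` so that a 51-96-year-old cohort
#: with a 16-cell precursor pool reaches ~25.7% SXCI at the moderate (CR >= 3)
#: threshold.  See docs/methods.md for the calibration procedure.
DEFAULT_DRIFT_SD = 0.1068

#: Age (years) at which acquired drift switches on; below it p stays inborn.
DEFAULT_DRIFT_ONSET_AGE = 15.0

STAGES = ("I", "IIA", "IIB", "III", "IV")

# Recruitment-weight defaults for patient tumour stages (AJCC I..IV).
_STAGE_WEIGHTS = (92, 13, 10, 16, 12)


@dataclass(frozen=True)
class AgeBand:
    """A closed age interval [lo, hi] in years; ages are drawn uniformly."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi):
            raise InvalidParameterError(f"invalid age band [{self.lo}, {self.hi}]")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


def default_control_age_distribution() -> list[tuple[AgeBand, float]]:
    """Recruitment age structure of the reference cohort.

    Three strata — neonates (2-28 days), younger adults (16-50 y) and the
    elderly (51-96 y) — weighted so that after ~90% informativeness the
    expected informative counts are about 46 / 166 / 144 out of 401 recruited.
    The 29 day - 15 year range is deliberately empty: the study design has no
    such subjects.
    """
    return [
        (AgeBand(2.0 / DAYS_PER_YEAR, NEONATE_MAX_AGE_YEARS), 52.0),
        (AgeBand(16.0, 50.0), 187.0),
        (AgeBand(51.0, 96.0), 162.0),
    ]


def default_patient_age_distribution() -> list[tuple[AgeBand, float]]:
    """Patients are adults aged 35-83 at diagnosis."""
    return [(AgeBand(35.0, 83.0), 1.0)]


@dataclass(frozen=True)
class Subject:
    """One simulated female.

    ``p_inactive_a`` is the fraction of her blood cells in which the X
    carrying CAG allele *a* is the inactive (methylated) one; 0.5 means
    perfectly balanced Lyonization.
    """

    id: str
    age_years: float
    cohort: str  # "control" | "patient"
    allele_a_repeats: int
    allele_b_repeats: int
    p_inactive_a: float
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise InvalidParameterError(f"{self.id}: negative age")
        if self.cohort not in ("control", "patient"):
            raise InvalidParameterError(f"{self.id}: unknown cohort {self.cohort!r}")
        if not (0.0 <= self.p_inactive_a <= 1.0):
            raise InvalidParameterError(f"{self.id}: p_inactive_a outside [0, 1]")
        if self.allele_a_repeats < 1 or self.allele_b_repeats < 1:
            raise InvalidParameterError(f"{self.id}: repeat counts must be positive")
        if self.stage is not None:
            if self.cohort != "patient":
                raise InvalidParameterError(f"{self.id}: stage on a non-patient")
            if self.stage not in STAGES:
                raise InvalidParameterError(f"{self.id}: unknown stage {self.stage!r}")

    @property
    def heterozygous(self) -> bool:
        return self.allele_a_repeats != self.allele_b_repeats


@dataclass
class PopulationConfig:
    """Parameters of the cohort generator.

    Parameters
    ----------
    n_subjects : int
        Number of subjects to recruit (before informativeness attrition).
    heterozygosity : float
        Probability that a subject carries two distinct CAG alleles
        (population value for the AR CAG STR is ~0.90).
    precursor_pool_size : int
        Number N of embryonic precursor cells committing to X inactivation;
        the inborn skew is K/N with K ~ Binomial(N, 1/2).
    drift_sd_per_sqrt_year : float
        Scale sigma of the acquired-drift random walk on logit(p); the logit
        perturbation after ``t`` years past onset is Normal(0, sigma^2 * t).
    drift_onset_age : float
        Age a0 (years) at which acquired drift begins.
    age_distribution : list of (AgeBand, weight)
        Recruitment age structure; weights need not be normalised.
    cohort : str
        "control" or "patient"; patients additionally receive a tumour stage.
    seed : int
        Seed of the population RNG stream (independent of the assay stream).
    cag_min, cag_max : int
        Inclusive range of CAG repeat counts.
    """

    n_subjects: int
    heterozygosity: float = 0.90
    precursor_pool_size: int = 16
    drift_sd_per_sqrt_year: float = DEFAULT_DRIFT_SD
    drift_onset_age: float = DEFAULT_DRIFT_ONSET_AGE
    age_distribution: list[tuple[AgeBand, float]] = field(
        default_factory=default_control_age_distribution
    )
    cohort: str = "control"
    seed: int = 0
    cag_min: int = 10
    cag_max: int = 35

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if not (0.0 <= self.heterozygosity <= 1.0):
            raise InvalidParameterError("heterozygosity must be in [0, 1]")
        if self.precursor_pool_size < 1:
            raise InvalidParameterError("precursor_pool_size must be >= 1")
        if self.drift_sd_per_sqrt_year < 0:
            raise InvalidParameterError("drift_sd_per_sqrt_year must be >= 0")
        if self.drift_onset_age < 0:
            raise InvalidParameterError("drift_onset_age must be >= 0")
        if self.cohort not in ("control", "patient"):
            raise InvalidParameterError(f"unknown cohort {self.cohort!r}")
        if not (1 <= self.cag_min <= self.cag_max):
            raise InvalidParameterError("need 1 <= cag_min <= cag_max")
        if not self.age_distribution:
            raise InvalidParameterError("age_distribution is empty")
        weights = [w for _, w in self.age_distribution]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise InvalidParameterError(
                "age weights must be non-negative and not all zero"
            )

    def with_seed(self, seed: int) -> "PopulationConfig":
        return replace(self, seed=seed)


def sample_genotype(
    config: PopulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw a CAG genotype: heterozygous with probability ``heterozygosity``.

    Repeat counts are uniform over ``[cag_min, cag_max]``; a heterozygote's
    second allele is redrawn until distinct.
    """
    a = int(rng.integers(config.cag_min, config.cag_max + 1))
    if rng.random() < config.heterozygosity:
        if config.cag_min == config.cag_max:
            raise InvalidParameterError(
                "cannot draw a heterozygote from a single-value CAG range"
            )
        b = a
        while b == a:
            b = int(rng.integers(config.cag_min, config.cag_max + 1))
    else:
        b = a
    return a, b


def sample_inborn_skew(
    pool_size: int, rng: np.random.Generator, size: int | None = None
):
    """Inborn inactivation fraction p0 = K/N, K ~ Binomial(N, 1/2).

    Each of the N embryonic precursor cells independently inactivates either
    X; a small pool cannot average out the coin flips, which is the entire
    inborn-skewing mechanism.  With ``size`` given, returns an array.
    """
    if pool_size < 1:
        raise InvalidParameterError("pool_size must be >= 1")
    k = rng.binomial(pool_size, 0.5, size=size)
    return k / pool_size


def apply_age_drift(
    p0,
    age_years: float,
    sd_per_sqrt_year: float,
    onset_age: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Perturb an inborn fraction by age-acquired clonal drift.

    The perturbation acts on the logit scale — logit(p) gains an independent
    Normal(0, sigma^2 * max(0, age - a0)) increment — so p stays inside (0, 1)
    and the skew-tail mass increases monotonically with age.  Degenerate
    fractions 0 and 1 (fully one-sided pools) are fixed points and are
    returned unchanged.
    """
    if sd_per_sqrt_year < 0:
        raise InvalidParameterError("sd_per_sqrt_year must be >= 0")
    if age_years < 0:
        raise InvalidParameterError("age_years must be >= 0")
    t = max(0.0, age_years - onset_age)
    if size is None:
        p0 = float(p0)
        if p0 <= 0.0 or p0 >= 1.0 or t == 0.0 or sd_per_sqrt_year == 0.0:
            return p0
        z = rng.normal(0.0, sd_per_sqrt_year * math.sqrt(t))
        return float(expit(logit(p0) + z))
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), (size,)).copy()
    if t == 0.0 or sd_per_sqrt_year == 0.0:
        return p0
    inner = (p0 > 0.0) & (p0 < 1.0)
    z = rng.normal(0.0, sd_per_sqrt_year * math.sqrt(t), size=size)
    p0[inner] = expit(logit(p0[inner]) + z[inner])
    return p0


def _sample_stage(rng: np.random.Generator) -> str:
    w = np.asarray(_STAGE_WEIGHTS, dtype=float)
    return STAGES[int(rng.choice(len(STAGES), p=w / w.sum()))]


def simulate_cohort(config: PopulationConfig) -> list[Subject]:
    """Generate a seeded, reproducible cohort of Subjects.

    Composition: draw an age from the configured bands, a CAG genotype, an
    inborn skew from the precursor pool, then apply acquired drift for the
    subject's age.  Deterministic for a fixed config (same seed twice gives
    identical cohorts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bands = [band for band, _ in config.age_distribution]
    weights = np.asarray([w for _, w in config.age_distribution], dtype=float)
    probs = weights / weights.sum()
    prefix = "C" if config.cohort == "control" else "P"
    subjects: list[Subject] = []
    for i in range(config.n_subjects):
        band = bands[int(rng.choice(len(bands), p=probs))]
        age = band.sample(rng)
        a, b = sample_genotype(config, rng)
        p0 = sample_inborn_skew(config.precursor_pool_size, rng)
        p = apply_age_drift(
            p0, age, config.drift_sd_per_sqrt_year, config.drift_onset_age, rng
        )
        stage = _sample_stage(rng) if config.cohort == "patient" else None
        subjects.append(
            Subject(
                id=f"{prefix}{i + 1:04d}",
                age_years=age,
                cohort=config.cohort,
                allele_a_repeats=a,
                allele_b_repeats=b,
                p_inactive_a=p,
                stage=stage,
            )
        )
    return subjects
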