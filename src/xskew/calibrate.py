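"""Deterministic calibration of the acquired-drift scale.

The generator has one free parameter with no direct literature value: the
drift scale sigma of the logit random walk.  It is pinned by requiring that an
elderly stratum (ages uniform on 51-96 years) reaches a target SXCI frequency
at the moderate threshold (majority-allele cell fraction >= 0.75, i.e.
corrected ratio >= 3).  The expected frequency has a closed form up to a
one-dimensional age integral:

    P(skewed | age) = sum_K  Binom(K; N, 1/2) * P(|logit(K/N) + s*Z| >= logit(f*))

with Z standard normal, s = sigma * sqrt(age - a0), f* the threshold
fraction — so no Monte Carlo is involved and the calibration is exactly
reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import logit
from scipy.stats import binom, norm

from .errors import InvalidParameterError
from .population import DEFAULT_DRIFT_ONSET_AGE

__all__ = ["expected_sxci_frequency", "calibrate_drift_sd"]


def expected_sxci_frequency(
    drift_sd: float,
    *,
    pool_size: int = 16,
    onset_age: float = DEFAULT_DRIFT_ONSET_AGE,
    age_band: tuple[float, float] = (51.0, 96.0),
    threshold_fraction: float = 0.75,
    n_age_grid: int = 481,
) -> float:
    """Expected fraction of subjects whose majority-allele cell fraction
    reaches ``threshold_fraction``, for ages uniform on ``age_band``.

    Exact over the binomial precursor pool and the Gaussian drift; the age
    integral uses a midpoint rule on ``n_age_grid`` points.
    """
    if drift_sd < 0:
        raise InvalidParameterError("drift_sd must be >= 0")
    if pool_size < 1:
        raise InvalidParameterError("pool_size must be >= 1")
    cut = float(logit(threshold_fraction))
    ks = np.arange(pool_size + 1)
    wk = binom.pmf(ks, pool_size, 0.5)
    p0 = ks / pool_size
    m = np.full(pool_size + 1, np.inf)
    inner = (p0 > 0) & (p0 < 1)
    m[inner] = logit(p0[inner])

    lo, hi = age_band
    if not (0 <= lo <= hi):
        raise InvalidParameterError("invalid age band")
    edges = np.linspace(lo, hi, n_age_grid + 1)
    ages = 0.5 * (edges[:-1] + edges[1:])

    total = 0.0
    for age in ages:
        t = max(0.0, age - onset_age)
        s = drift_sd * math.sqrt(t)
        if s == 0.0:
            prob = (np.abs(m) >= cut).astype(float)
        else:
            prob = np.where(
                np.isinf(m),
                1.0,  # fully one-sided pools stay skewed
                norm.sf((cut - m) / s) + norm.cdf((-cut - m) / s),
            )
        total += float(wk @ prob)
    return total / len(ages)


def calibrate_drift_sd(
    target_frequency: float = 0.257,
    *,
    pool_size: int = 16,
    onset_age: float = DEFAULT_DRIFT_ONSET_AGE,
    age_band: tuple[float, float] = (51.0, 96.0),
    threshold_fraction: float = 0.75,
) -> float:
    """Solve for the drift scale that hits ``target_frequency`` in the
    elderly stratum.  Root-finding on the closed-form expectation above.
    """
    if not (0.0 < target_frequency < 1.0):
        raise InvalidParameterError("target_frequency must be in (0, 1)")
    floor = expected_sxci_frequency(
        0.0,
        pool_size=pool_size,
        onset_age=onset_age,
        age_band=age_band,
        threshold_fraction=threshold_fraction,
    )
    if target_frequency <= floor:
        raise InvalidParameterError(
            f"target {target_frequency} not above the inborn floor {floor:.4f}"
        )

    def f(s: float) -> float:
        return (
            expected_sxci_frequency(
                s,
                pool_size=pool_size,
                onset_age=onset_age,
                age_band=age_band,
                threshold_fraction=threshold_fraction,
            )
            - target_frequency
        )

    return float(brentq(f, 1e-9, 3.0, xtol=1e-8))
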