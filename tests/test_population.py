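"""Cohort generator: genotypes, inborn binomial skew, age-acquired drift."""

import math

import numpy as np
import pytest

from xskew.calibrate import calibrate_drift_sd, expected_sxci_frequency
from xskew.errors import InvalidParameterError
from xskew.population import (
    DEFAULT_DRIFT_SD,
    AgeBand,
    PopulationConfig,
    apply_age_drift,
    sample_genotype,
    sample_inborn_skew,
    simulate_cohort,
)


def exact_skew_tail(pool_size: int, threshold: float = 0.75) -> float:
    """Independent oracle: P(max(K/N, 1-K/N) >= threshold) by enumeration."""
    total = 0
    for k in range(pool_size + 1):
        p = k / pool_size
        if max(p, 1 - p) >= threshold:
            total += math.comb(pool_size, k)
    return total / 2**pool_size


@pytest.mark.parametrize("het,expect_mixed", [(1.0, True), (0.0, False)])
def test_genotype_extreme_heterozygosity_is_forced(rng, het, expect_mixed):
    cfg = PopulationConfig(n_subjects=1, heterozygosity=het)
    pairs = [sample_genotype(cfg, rng) for _ in range(300)]
    assert all((a != b) == expect_mixed for a, b in pairs)
    assert all(10 <= a <= 35 and 10 <= b <= 35 for a, b in pairs)


def test_genotype_heterozygote_fraction_matches_rate(rng):
    cfg = PopulationConfig(n_subjects=1, heterozygosity=0.9)
    draws = 10_000
    frac = sum(a != b for a, b in (sample_genotype(cfg, rng) for _ in range(draws))) / draws
    assert frac == pytest.approx(0.90, abs=0.01)


def test_inborn_skew_two_cell_pool_enumeration(rng):
    # N=2: four equally likely precursor outcomes -> p0 in {0, .5, 1}
    draws = sample_inborn_skew(2, rng, size=40_000)
    values, counts = np.unique(draws, return_counts=True)
    assert set(values) == {0.0, 0.5, 1.0}
    freq = dict(zip(values, counts / len(draws)))
    assert freq[0.0] == pytest.approx(0.25, abs=0.01)
    assert freq[0.5] == pytest.approx(0.50, abs=0.01)
    assert freq[1.0] == pytest.approx(0.25, abs=0.01)


def test_inborn_skew_tail_matches_exact_binomial(rng):
    assert exact_skew_tail(16) == 5034 / 65536
    n = 100_000
    draws = sample_inborn_skew(16, rng, size=n)
    tail = float(np.mean(np.maximum(draws, 1 - draws) >= 0.75))
    q = 5034 / 65536
    se = math.sqrt(q * (1 - q) / n)
    assert abs(tail - q) <= 3 * se


def test_inborn_skew_huge_pool_never_skews(rng):
    draws = sample_inborn_skew(10**6, rng, size=2_000)
    assert np.max(np.maximum(draws, 1 - draws)) < 0.75


def test_inborn_skew_rejects_empty_pool(rng):
    with pytest.raises(InvalidParameterError):
        sample_inborn_skew(0, rng)


def test_drift_is_identity_before_onset_and_at_zero_sigma(rng):
    assert apply_age_drift(0.3, 0.0, 0.2, 15.0, rng) == 0.3
    assert apply_age_drift(0.3, 10.0, 0.2, 15.0, rng) == 0.3
    assert apply_age_drift(0.3, 80.0, 0.0, 15.0, rng) == 0.3
    # degenerate fractions are fixed points
    assert apply_age_drift(0.0, 80.0, 0.2, 15.0, rng) == 0.0
    assert apply_age_drift(1.0, 80.0, 0.2, 15.0, rng) == 1.0


def test_drift_rejects_negative_sigma(rng):
    with pytest.raises(InvalidParameterError):
        apply_age_drift(0.5, 50.0, -0.1, 15.0, rng)


def test_drift_variance_matches_random_walk(rng):
    # logit-p after t years is Normal(logit p0, sigma^2 t): check the variance
    sigma, age, onset = 0.15, 79.0, 15.0
    t = age - onset
    n = 100_000
    p = apply_age_drift(0.5, age, sigma, onset, rng, size=n)
    logits = np.log(p / (1 - p))
    target = sigma**2 * t
    mc_se = target * math.sqrt(2.0 / (n - 1))
    assert abs(np.var(logits, ddof=1) - target) <= 3 * mc_se


def test_inactivation_fraction_symmetric_about_half(rng):
    # maternal/paternal labels are exchangeable -> E[p] = 1/2
    n = 100_000
    p0 = sample_inborn_skew(16, rng, size=n)
    p = apply_age_drift(p0, 70.0, DEFAULT_DRIFT_SD, 15.0, rng, size=n)
    se = np.std(p, ddof=1) / math.sqrt(n)
    assert abs(float(np.mean(p)) - 0.5) <= 3 * se


def test_skew_tail_monotone_in_age_and_sigma(rng):
    def tail(age, sigma, n=40_000):
        p0 = sample_inborn_skew(16, rng, size=n)
        p = apply_age_drift(p0, age, sigma, 15.0, rng, size=n)
        return float(np.mean(np.maximum(p, 1 - p) >= 0.75))

    by_age = [tail(a, DEFAULT_DRIFT_SD) for a in (0.0, 30.0, 50.0, 70.0, 90.0)]
    assert all(b >= a - 0.01 for a, b in zip(by_age, by_age[1:]))
    by_sigma = [tail(70.0, s) for s in (0.0, 0.05, 0.10, 0.20)]
    assert all(b >= a - 0.01 for a, b in zip(by_sigma, by_sigma[1:]))


def test_cohort_is_deterministic_for_fixed_seed():
    cfg = PopulationConfig(n_subjects=100, seed=42)
    assert simulate_cohort(cfg) == simulate_cohort(cfg)


def test_cohort_respects_age_bands_and_stages():
    cfg = PopulationConfig(
        n_subjects=200,
        cohort="patient",
        age_distribution=[(AgeBand(35.0, 83.0), 1.0)],
        seed=7,
    )
    subjects = simulate_cohort(cfg)
    assert all(35.0 <= s.age_years <= 83.0 for s in subjects)
    assert all(s.stage is not None for s in subjects)
    control = simulate_cohort(PopulationConfig(n_subjects=50, seed=7))
    assert all(s.stage is None for s in control)


def test_cohort_rejects_invalid_config():
    with pytest.raises(InvalidParameterError):
        simulate_cohort(PopulationConfig(n_subjects=10, age_distribution=[]))
    with pytest.raises(InvalidParameterError):
        simulate_cohort(
            PopulationConfig(
                n_subjects=10, age_distribution=[(AgeBand(0, 10), 0.0)]
            )
        )
    with pytest.raises(InvalidParameterError):
        simulate_cohort(PopulationConfig(n_subjects=10, heterozygosity=1.5))


def test_calibration_closed_form_and_default_sigma():
    # with no drift the closed form collapses to the exact binomial tail
    assert expected_sxci_frequency(0.0) == pytest.approx(5034 / 65536, abs=1e-12)
    sigma = calibrate_drift_sd(0.257)
    assert sigma == pytest.approx(DEFAULT_DRIFT_SD, abs=5e-4)
    assert expected_sxci_frequency(DEFAULT_DRIFT_SD) == pytest.approx(0.257, abs=0.002)
    with pytest.raises(InvalidParameterError):
        calibrate_drift_sd(0.01)  # below the inborn floor
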