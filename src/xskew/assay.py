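"""In-silico HUMARA assay: from a subject's true inactivation fraction to
four gel band intensities.

The real assay amplifies AR exon 1 across the CAG repeat before and after
digestion with the methylation-sensitive enzyme HpaII.  On the inactive X the
restriction sites are methylated, so that template survives digestion and is
amplified; the active-X template is cut and lost.  For a subject whose
allele-a X is inactive in a fraction ``p`` of blood cells the noiseless
template amounts are

    pre-digestion:   T_a = beta,                       T_b = 1
    post-digestion:  T_a = beta * [p + (1-d)(1-p)],    T_b = (1-p) + (1-d) p

where ``beta`` is the allele-preferential amplification factor and ``d`` the
digestion efficiency (incomplete digestion lets a fraction 1-d of active
templates through, pulling the corrected ratio toward 1 — the reason the wet
assay carries no-enzyme negative controls).  Band intensities are the
template amounts times a shared per-lane scale and independent multiplicative
lognormal densitometry noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .population import Subject

__all__ = ["AssayConfig", "AssayResult", "is_informative", "simulate_assay", "simulate_assays"]


@dataclass
class AssayConfig:
    """Parameters of the simulated assay.

    amp_bias : float or None
        Fixed amplification efficiency of allele a relative to allele b;
        ``None`` (default) draws it per subject log-uniformly from
        ``amp_bias_range``, mimicking fragment-length-dependent PCR bias.
    digestion_efficiency : float in [0, 1]
        Fraction of active-X templates actually cut; 1.0 (default) reflects
        the complete digestion the negative controls certify.
    noise_cv : float
        Coefficient of variation of the per-band lognormal densitometry
        noise (silver-stain densitometry is scale-dependent, so the noise is
        multiplicative).  Default 0.10.
    min_repeat_diff : int
        Smallest CAG-repeat difference the gel resolves; closer alleles
        co-migrate into a single band and the subject is uninformative.
    base_intensity : float
        Arbitrary densitometry scale of a lane; cancels in the corrected
        ratio.
    seed : int
        Seed of the assay RNG stream (independent of the population stream).
    """

    amp_bias: float | None = None
    amp_bias_range: tuple[float, float] = (0.7, 1.4)
    digestion_efficiency: float = 1.0
    noise_cv: float = 0.10
    min_repeat_diff: int = 1
    base_intensity: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.amp_bias is not None and self.amp_bias <= 0:
            raise InvalidParameterError("amp_bias must be positive")
        lo, hi = self.amp_bias_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("invalid amp_bias_range")
        if not (0.0 <= self.digestion_efficiency <= 1.0):
            raise InvalidParameterError("digestion_efficiency must be in [0, 1]")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.min_repeat_diff < 1:
            raise InvalidParameterError("min_repeat_diff must be >= 1")
        if self.base_intensity <= 0:
            raise InvalidParameterError("base_intensity must be positive")


@dataclass(frozen=True)
class AssayResult:
    """Densitometry readings for one subject: two alleles x pre/post lanes.

    For subjects whose alleles are not gel-resolvable the two products
    co-migrate: the merged band is recorded under allele a, the b columns are
    zero and ``homozygous`` is set.
    """

    subject_id: str
    i_a_pre: float
    i_b_pre: float
    i_a_post: float
    i_b_post: float
    homozygous: bool = False

    def __post_init__(self) -> None:
        for name in ("i_a_pre", "i_b_pre", "i_a_post", "i_b_post"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{self.subject_id}: negative {name}")


def is_informative(subject: Subject, config: AssayConfig) -> bool:
    """True iff the two CAG alleles are distinct and gel-resolvable."""
    return abs(subject.allele_a_repeats - subject.allele_b_repeats) >= config.min_repeat_diff


def _noise(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal factor with coefficient of variation ``cv``."""
    if cv == 0.0:
        return 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * s * s, s))


def simulate_assay(
    subject: Subject, config: AssayConfig, rng: np.random.Generator
) -> AssayResult:
    """Simulate the four band intensities for one subject.

    With ``noise_cv=0`` and complete digestion the downstream corrected ratio
    is exactly ``max(p, 1-p) / min(p, 1-p)`` regardless of ``amp_bias``.
    """
    config.validate()
    p = subject.p_inactive_a
    d = config.digestion_efficiency
    if config.amp_bias is not None:
        beta = config.amp_bias
    else:
        lo, hi = config.amp_bias_range
        beta = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    t_a_pre, t_b_pre = beta, 1.0
    t_a_post = beta * (p + (1.0 - d) * (1.0 - p))
    t_b_post = (1.0 - p) + (1.0 - d) * p

    scale = config.base_intensity
    if not is_informative(subject, config):
        # co-migrating alleles: one merged band per lane
        return AssayResult(
            subject_id=subject.id,
            i_a_pre=(t_a_pre + t_b_pre) * scale * _noise(rng, config.noise_cv),
            i_b_pre=0.0,
            i_a_post=(t_a_post + t_b_post) * scale * _noise(rng, config.noise_cv),
            i_b_post=0.0,
            homozygous=True,
        )
    return AssayResult(
        subject_id=subject.id,
        i_a_pre=t_a_pre * scale * _noise(rng, config.noise_cv),
        i_b_pre=t_b_pre * scale * _noise(rng, config.noise_cv),
        i_a_post=t_a_post * scale * _noise(rng, config.noise_cv),
        i_b_post=t_b_post * scale * _noise(rng, config.noise_cv),
    )


def simulate_assays(
    subjects: list[Subject], config: AssayConfig, rng: np.random.Generator | None = None
) -> list[AssayResult]:
    """Run the assay over a cohort with the config's own RNG stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [simulate_assay(s, config, rng) for s in subjects]
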