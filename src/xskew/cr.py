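"""The corrected ratio (CR) and the skewed-inactivation calls built on it.

The CR divides the post-digestion allele band ratio by the pre-digestion
ratio of the same sample, so any allele-preferential amplification bias —
identical in the two lanes — cancels.  A CR below 1 is replaced by its
reciprocal, making CR a fold-deviation from balanced inactivation: CR >= 3
(the moderate criterion) means the majority allele is inactive in at least
75% of cells, CR >= 10 (the stringent criterion) in about 91%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .assay import AssayResult
from .errors import AssayFailureError, InvalidParameterError, OverDigestionError

__all__ = [
    "CRCall",
    "DISPLAY_CAP",
    "classify_sxci",
    "compute_cr",
    "cr_to_cell_fraction",
    "fraction_to_cr",
    "call_assay",
    "call_assays",
]

#: Display cap used when reporting a CR of +infinity (one post-digestion
#: band completely absent — biologically meaningful total skewing).
DISPLAY_CAP = 100.0

MODERATE_THRESHOLD = 3.0
STRINGENT_THRESHOLD = 10.0


@dataclass(frozen=True)
class CRCall:
    """Per-subject call: corrected ratio plus SXCI flags at both thresholds.

    Uninformative subjects carry no CR and no flags (``None``); the
    stringent flag always implies the moderate one.
    """

    subject_id: str
    informative: bool
    cr: Optional[float]  # >= 1, may be +inf; None when uninformative
    sxci_moderate: Optional[bool]
    sxci_stringent: Optional[bool]

    def __post_init__(self) -> None:
        if not self.informative:
            if self.cr is not None or self.sxci_moderate is not None:
                raise InvalidParameterError(
                    f"{self.subject_id}: uninformative call must carry no CR"
                )
        else:
            if self.cr is None or self.cr < 1.0:
                raise InvalidParameterError(
                    f"{self.subject_id}: CR must be >= 1 (reciprocal rule)"
                )
            if self.sxci_stringent and not self.sxci_moderate:
                raise InvalidParameterError(
                    f"{self.subject_id}: stringent call without moderate call"
                )


def compute_cr(result: AssayResult) -> float:
    """Corrected ratio of an informative assay result.

    r_pre = a/b before digestion, r_post = a/b after; CR = r_post / r_pre,
    with the reciprocal taken when below 1 so CR >= 1 always.  Exactly one
    absent post-digestion band yields +infinity (complete skewing); an
    absent pre-digestion band or two absent post bands are assay failures.
    """
    if result.homozygous:
        raise AssayFailureError(
            f"{result.subject_id}: uninformative (merged band); CR undefined"
        )
    if result.i_a_pre <= 0 or result.i_b_pre <= 0:
        raise AssayFailureError(
            f"{result.subject_id}: pre-digestion band absent; amplification failed"
        )
    if result.i_a_post == 0 and result.i_b_post == 0:
        raise OverDigestionError(
            f"{result.subject_id}: both post-digestion bands absent"
        )
    if result.i_a_post == 0 or result.i_b_post == 0:
        return math.inf
    r_pre = result.i_a_pre / result.i_b_pre
    r_post = result.i_a_post / result.i_b_post
    cr_raw = r_post / r_pre
    return max(cr_raw, 1.0 / cr_raw)


def classify_sxci(
    cr: float,
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, STRINGENT_THRESHOLD),
) -> tuple[bool, bool]:
    """Flags at the moderate and stringent thresholds (inclusive >=)."""
    moderate, stringent = thresholds
    if not (0 < moderate < stringent):
        raise InvalidParameterError("need 0 < moderate < stringent threshold")
    if not (cr >= 1.0):  # also rejects NaN
        raise InvalidParameterError(
            f"CR {cr} < 1: reciprocal rule not applied upstream"
        )
    return cr >= moderate, cr >= stringent


def cr_to_cell_fraction(cr: float) -> float:
    """Majority-allele cell fraction implied by a corrected ratio.

    f = CR / (1 + CR): CR 1 -> 0.5 (balanced), CR 3 -> 0.75, CR 10 -> ~0.909.
    """
    if not (cr >= 1.0):
        raise InvalidParameterError(f"CR {cr} < 1")
    if math.isinf(cr):
        return 1.0
    return cr / (1.0 + cr)


def fraction_to_cr(fraction: float) -> float:
    """Inverse of :func:`cr_to_cell_fraction`: CR = f / (1 - f)."""
    if not (0.5 <= fraction <= 1.0):
        raise InvalidParameterError("majority fraction must be in [0.5, 1]")
    if fraction == 1.0:
        return math.inf
    return fraction / (1.0 - fraction)


def call_assay(
    result: AssayResult,
    informative: bool | None = None,
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, STRINGENT_THRESHOLD),
) -> CRCall:
    """Produce the CRCall for one assay result.

    ``informative`` defaults to the result's own band structure (merged band
    means uninformative); pass it explicitly when genotype information says
    otherwise.
    """
    if informative is None:
        informative = not result.homozygous
    if not informative:
        return CRCall(result.subject_id, False, None, None, None)
    cr = compute_cr(result)
    moderate, stringent = classify_sxci(cr, thresholds)
    return CRCall(result.subject_id, True, cr, moderate, stringent)


def call_assays(
    results: list[AssayResult],
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, STRINGENT_THRESHOLD),
) -> list[CRCall]:
    return [call_assay(r, thresholds=thresholds) for r in results]
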