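"""Closed-form estimators for cellular-barcoding experiments.

Covers the Poisson arithmetic of lentiviral transduction (MOI vs infected
fraction), barcode-library complexity estimates, the Lincoln-Petersen
mark-recapture estimate of library diversity, reprogramming efficiency, and
the expected number of barcodes shared between split dishes under purely
stochastic (non-heritable) reprogramming.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


def moi_from_fraction(f_gfp: float) -> float:
    """Multiplicity of infection from the fraction of transduced (GFP+) cells.

    Under Poisson infection statistics the fraction of cells with at least
    one integration is ``1 - exp(-m)``, so ``m = -ln(1 - f_gfp)``.
    """
    if not (0.0 <= f_gfp < 1.0):
        raise ValueError(f"f_gfp must be in [0, 1), got {f_gfp}")
    return -math.log1p(-f_gfp)


def infected_fraction(m: float) -> float:
    """Fraction of cells infected with at least one viral particle at MOI m."""
    if m < 0:
        raise ValueError(f"MOI must be non-negative, got {m}")
    return -math.expm1(-m)


def theoretical_diversity(length: int, alphabet_size: int = 4) -> int:
    """Number of distinct random barcodes of the given length (exact integer)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return alphabet_size ** length


def plating_complexity(colonies: int, plated_fraction: float) -> float:
    """Library complexity inferred from colony counts on a plated aliquot.

    Plating a fraction ``p`` of a transformation mix and counting ``c``
    colonies implies roughly ``c / p`` independent transformants overall.
    """
    if not (0.0 < plated_fraction <= 1.0):
        raise ValueError("plated_fraction must be in (0, 1]")
    if colonies < 0:
        raise ValueError("colonies must be non-negative")
    return colonies / plated_fraction


@dataclass(frozen=True)
class DiversityEstimate:
    """Mark-recapture estimate of barcode-library diversity."""

    estimate: float
    n1: int
    n2: int
    shared: int
    lower_bound: bool = False  # True when shared == 0 and only a bound is known

    def __post_init__(self):
        if self.shared >= 1 and self.estimate < max(self.n1, self.n2):
            raise ValueError("diversity estimate below observed sample size")


def diversity_pairwise(n1: int, n2: int, shared: int) -> DiversityEstimate:
    """Estimate library diversity from barcodes shared between two infections.

    Two independent infections with the same virus batch sample ``n1`` and
    ``n2`` barcodes from a pool of unknown size D; barcodes recurring in both
    runs play the role of recaptures, giving the Lincoln-Petersen estimate
    ``D = n1 * n2 / shared``.  With no shared barcode, ``n1 * n2`` is
    reported as a lower bound.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if shared < 0:
        raise ValueError("shared count must be non-negative")
    if shared > min(n1, n2):
        raise ValueError("shared count cannot exceed either sample size")
    if shared == 0:
        return DiversityEstimate(float(n1 * n2), n1, n2, 0, lower_bound=True)
    return DiversityEstimate(n1 * n2 / shared, n1, n2, shared)


def reprogramming_efficiency(n_unique_barcodes: int, n_seeded: int, m: float) -> float:
    """Reprogramming efficiency: recovered barcodes per barcode-carrying cell.

    Each recovered barcode marks at least one reprogrammed lineage; only the
    ``n_seeded * (1 - exp(-m))`` cells that received a barcoded virus could
    have contributed, so the estimate is a minimum.
    """
    if n_unique_barcodes < 0:
        raise ValueError("barcode count must be non-negative")
    if m <= 0:
        raise ValueError("MOI must be positive")
    effective = n_seeded * infected_fraction(m)
    if effective <= 0:
        raise ValueError("no effective (barcode-carrying) cells")
    return n_unique_barcodes / effective


def expected_shared(n_transduced: float, c_split: float, efficiency: float) -> float:
    """Expected barcodes shared between dishes under stochastic reprogramming.

    ``T = N * C * E**2``: each of N transduced cells doubles once before the
    split; with probability C the two sisters land in different dishes and
    each is independently reprogrammed with probability E, in which case the
    clone's barcode is recovered from two dishes.  Report ``round()`` of this
    for integer comparisons.
    """
    if not (0.0 <= c_split <= 1.0):
        raise ValueError("c_split must be in [0, 1]")
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must be in [0, 1]")
    if n_transduced < 0:
        raise ValueError("n_transduced must be non-negative")
    return n_transduced * c_split * efficiency**2


def sister_split_probability(n_dishes: int, n_sisters: int = 2) -> float:
    """Probability that all sisters land in distinct dishes under uniform plating."""
    if n_dishes < 1:
        raise ValueError("n_dishes must be >= 1")
    if n_sisters < 1:
        raise ValueError("n_sisters must be >= 1")
    if n_sisters > n_dishes:
        return 0.0
    p = 1.0
    for i in range(n_sisters):
        p *= (n_dishes - i) / n_dishes
    return p
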