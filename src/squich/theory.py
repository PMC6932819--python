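"""Analytic sample-complexity bounds and SRS detection power.

For two species at abundances x1*10**y1 and x2*10**y2 (y1 < y2) and failure
probability p, a suitably scheduled depletion/enrichment protocol detects
the rarer species with probability at least 1-p using

    ((y2 + 1) / y1) * log(1/p)

samples, whereas simple random sampling needs at least

    10**(y2 - y1 - 1) * log(1/p)

samples — i.e. the required depth is logarithmic in the abundance ratio
instead of linear.  The log is natural (the base only rescales both bounds
identically).  The leading digits x1, x2 are carried for completeness but do
not enter these bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PowerQuery",
    "squich_sample_bound",
    "srs_sample_bound",
    "srs_detection_prob",
]


@dataclass(frozen=True)
class PowerQuery:
    """Two-species detection-power query.

    y1, y2: decade exponents of the rare and abundant species (y1 < y2);
    x1, x2: leading digits in 1..9; p: allowed failure probability.
    """

    y1: int
    y2: int
    p: float
    x1: int = 1
    x2: int = 1

    def __post_init__(self) -> None:
        if not self.y1 < self.y2:
            raise ValueError("y1 < y2 is required")
        if self.y1 < 0:
            raise ValueError("decade exponents must be non-negative")
        if not (0 < self.p < 1):
            raise ValueError("p must lie in (0, 1)")
        if not (1 <= self.x1 <= 9 and 1 <= self.x2 <= 9):
            raise ValueError("leading digits must lie in 1..9")


def squich_sample_bound(q: PowerQuery) -> float:
    """Samples sufficient for detection at failure probability p."""
    if q.y1 == 0:
        raise ValueError("the bound requires y1 >= 1")
    return (q.y2 + 1) / q.y1 * math.log(1 / q.p)


def srs_sample_bound(q: PowerQuery) -> float:
    """Samples required by simple random sampling for the same power."""
    return 10.0 ** (q.y2 - q.y1 - 1) * math.log(1 / q.p)


def srs_detection_prob(abundance: int, total: int, depth: float) -> float:
    """P(at least one read of a species) under SRS, Poisson closed form.

    1 - exp(-depth * abundance / total); exact in the small-sampling-fraction
    limit and the validation yardstick for the empirical SRS sampler.
    """
    if not (0 <= abundance <= total):
        raise ValueError("need 0 <= abundance <= total")
    if total == 0:
        return 0.0
    return -math.expm1(-depth * abundance / total)
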