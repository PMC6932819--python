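"""Abundance estimation from round-stratified counts.

The round in which a species was last tagged brackets its abundance between
consecutive cumulative capacities: if the last observed round is r*, the
original abundance lies in the half-open interval (T_{r*-1}, T_{r*}].  The
point estimator sharpens the interval using round occupancy: within the last
round, the fraction of that round's capacity the species consumed is
estimated from its read count relative to the full-occupancy read level
q_r (calibrated from species that saturated the round, i.e. that were still
being tagged in the next round), giving

    n_hat = T_{r*-1} + K_{r*} * min(1, c_{i,r*} / q_{r*}).

This reduces exactly to the interval logic of the deterministic protocol and
to exact recovery in the noise-free limit.  The estimator is a named
reconstruction ("sem" strategy) and is deliberately pluggable.

Also here: the enrichment caller for fold-change screens (Poisson tail with
Bonferroni control over the species family) and the raw-count SRS estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ProbeSchedule, RoundCountMatrix

__all__ = [
    "AbundanceEstimate",
    "EnrichmentCall",
    "last_coded_round",
    "sem_interval",
    "sem_point",
    "call_enriched",
    "srs_point",
]

#: Final-round occupancy at or above which an estimate is right-censored.
CENSOR_OCCUPANCY = 0.99


@dataclass
class AbundanceEstimate:
    """Per-species point estimates and half-open abundance intervals.

    Undetected species carry point 0 and the degenerate interval (0, 0];
    species saturating the final round are right-censored: (T_{R-1}, inf).
    """

    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    detected: np.ndarray
    censored: np.ndarray

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "species_id": np.arange(self.point.size),
                "point": self.point,
                "lo": self.lo,
                "hi": self.hi,
                "detected": self.detected.astype(int),
                "censored": self.censored.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentCall:
    called: np.ndarray  # species ids
    score: np.ndarray  # final-round count per species
    threshold: int


def last_coded_round(counts: RoundCountMatrix, tau_reads: int = 1) -> np.ndarray:
    """1-based index of the last round with >= tau_reads reads; 0 if none."""
    qualifying = counts.counts >= tau_reads
    any_q = qualifying.any(axis=1)
    r_star = np.where(any_q, counts.rounds - np.argmax(qualifying[:, ::-1], axis=1), 0)
    return r_star.astype(np.int64)


def _cumulative(sched: ProbeSchedule) -> np.ndarray:
    T = sched.T
    if T.ndim == 2:  # per-species schedules: use the per-round scalar reduction
        raise NotImplementedError(
            "interval estimation with per-species schedules is not supported"
        )
    return T


def sem_interval(r_star, sched: ProbeSchedule):
    """Half-open abundance interval (T_{r*-1}, T_{r*}] from the last round.

    ``r_star`` is 1-based; 0 (or None) means not detected and returns the
    sentinel (0, 0].  A species last seen in the final round may still have
    unreacted molecules; its interval is still reported as
    (T_{R-1}, T_R] but downstream estimates flag it as censored, meaning the
    truth may exceed the upper bound.  Returns (lo, hi) arrays.
    """
    if r_star is None:
        r_star = 0
    r = np.atleast_1d(np.asarray(r_star, dtype=np.int64))
    R = sched.rounds
    if np.any(r < 0) or np.any(r > R):
        raise ValueError("round index outside the schedule")
    T = _cumulative(sched)
    T_full = np.concatenate([[0.0], T])
    lo = T_full[np.maximum(r - 1, 0)] * (r > 0)
    hi = T_full[r]
    if np.isscalar(r_star) or np.asarray(r_star).ndim == 0:
        return float(lo[0]), float(hi[0])
    return lo, hi


def _occupancy_levels(
    counts: np.ndarray, tau_reads: int, encoder_amounts: np.ndarray | None = None
) -> np.ndarray:
    """Per-round full-occupancy read level q_r.

    For each round r, the median count among species that were still being
    tagged in round r+1 (those necessarily consumed all of round r's
    capacity).  Rounds without such calibrator species (typically the last
    informative round) inherit the calibrated per-encoder read level scaled
    by their encoder amount — at full occupancy a round yields reads in
    proportion to the encoders offered, independent of the competitor
    amount.  Remaining fallbacks: the max count over all species, then 1.
    """
    S, R = counts.shape
    q = np.full(R, np.nan)
    for r in range(R - 1):
        saturated = counts[:, r + 1] >= tau_reads
        if saturated.any():
            med = float(np.median(counts[saturated, r]))
            if med > 0:
                q[r] = med
    calibrated = np.isfinite(q)
    if encoder_amounts is not None and calibrated.any():
        E = np.asarray(encoder_amounts, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_encoder = np.where(calibrated & (E > 0), q / E, np.nan)
        scale = np.nanmedian(per_encoder)
        if np.isfinite(scale):
            fill = ~calibrated & (E > 0)
            q[fill] = scale * E[fill]
    for r in range(R):
        if not np.isfinite(q[r]) or q[r] <= 0:
            q[r] = float(counts[:, r].max())
        q[r] = max(q[r], 1.0)
    return q


def sem_point(
    counts: RoundCountMatrix, sched: ProbeSchedule, tau_reads: int = 1
) -> AbundanceEstimate:
    """Point + interval abundance estimates from a round count matrix.

    ``tau_reads`` is the noise floor: rounds with fewer reads than this do
    not count as evidence (default 1, i.e. any read counts).
    """
    if counts.rounds != sched.rounds:
        raise ValueError("count matrix and schedule disagree on round count")
    c = counts.counts
    S, R = c.shape
    r_star = last_coded_round(counts, tau_reads)
    lo, hi = sem_interval(r_star, sched)
    detected = r_star > 0

    T = _cumulative(sched)
    T_full = np.concatenate([[0.0], T])
    K = np.asarray(sched.K, dtype=float)
    E = np.asarray(sched.E, dtype=float)
    q = _occupancy_levels(c, tau_reads, E if E.ndim == 1 else None)

    last_counts = np.where(detected, c[np.arange(S), np.maximum(r_star - 1, 0)], 0)
    occ = np.minimum(1.0, last_counts / q[np.maximum(r_star - 1, 0)])
    point = np.where(detected, T_full[np.maximum(r_star - 1, 0)] + K[np.maximum(r_star - 1, 0)] * occ, 0.0)
    censored = detected & (r_star == R) & (occ >= CENSOR_OCCUPANCY)
    return AbundanceEstimate(
        point=point, lo=lo, hi=hi, detected=detected, censored=censored
    )


def call_enriched(
    counts: RoundCountMatrix,
    sched: ProbeSchedule,
    alpha: float = 0.05,
    background_level: float | None = None,
) -> EnrichmentCall:
    """Call species enriched above a uniform background.

    Assumes the schedule was designed so the cumulative capacity before the
    final round exhausts the background level: only species above background
    still have molecules to tag in the final round.  The final-round count is
    the evidence statistic.  Background leakage into the final round
    (unreacted carry-over) is modeled as Poisson with mean ``mu`` estimated
    by the upper-quartile mean of final-round counts over all species; the
    call threshold is the smallest integer k with
    ``S * P(Poisson(mu) >= k) <= alpha`` (Bonferroni over the family).
    """
    T = _cumulative(sched)
    if background_level is not None and sched.rounds >= 2 and T[-2] < background_level:
        warnings.warn(
            "cumulative capacity before the final round does not exhaust the "
            "background level; enrichment calls may be unreliable",
            stacklevel=2,
        )
    score = counts.counts[:, -1].astype(np.int64)
    S = score.size
    k_top = max(1, S // 4)
    top = np.partition(score, S - k_top)[S - k_top:]
    mu = float(top.mean())
    if mu <= 0:
        tau = 1
    else:
        # smallest k with S * P(Pois(mu) >= k) <= alpha
        tau = int(stats.poisson.isf(alpha / S, mu)) + 1
        while tau > 1 and S * stats.poisson.sf(tau - 2, mu) <= alpha:
            tau -= 1
    called = np.flatnonzero(score >= tau)
    return EnrichmentCall(called=called, score=score, threshold=tau)


def srs_point(counts: np.ndarray) -> AbundanceEstimate:
    """Raw-count estimator for SRS: the total count is the point estimate."""
    counts = np.asarray(counts, dtype=np.int64)
    detected = counts >= 1
    return AbundanceEstimate(
        point=counts.astype(float),
        lo=np.zeros(counts.size),
        hi=np.where(detected, np.inf, 0.0),
        detected=detected,
        censored=np.zeros(counts.size, dtype=bool),
    )
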