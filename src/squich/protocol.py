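"""Full multi-round protocol, finite-depth sequencing, and the SRS baseline.

The protocol threads free molecules through successive rounds of
encoder/competitor exposure, producing a *coded pool*: per-species,
per-round counts of tagged molecules.  Only the coded pool is sequenced.
Sequencing draws reads without replacement from the pool (it is a finite
physical library); simple random sampling (SRS), the conventional-sequencing
baseline, draws with replacement from the original population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemistry import ChemistryParams, run_round
from .populations import SpeciesPopulation

__all__ = [
    "ProbeSchedule",
    "CodedPool",
    "RoundCountMatrix",
    "run_protocol",
    "sequence_pool",
    "srs_sample",
]

#: Above this requested depth (or above float64's exact-integer range of
#: population totals) the SRS sampler switches from an exact multinomial to
#: independent per-species Poisson draws.
SRS_POISSON_DEPTH = 10**7
_EXACT_FLOAT = 2**53


@dataclass(frozen=True)
class ProbeSchedule:
    """Per-round encoder amounts E_r and competitor amounts C_r.

    Amounts are per round and either scalar (same for every species) or a
    per-species vector.  Derived quantities: per-round capacity
    ``K_r = E_r + C_r`` and cumulative capacity ``T_r = sum_{j<=r} K_j`` —
    the yardstick against which abundance is bracketed.
    """

    E: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        E = np.atleast_1d(np.asarray(self.E, dtype=float))
        C = np.atleast_1d(np.asarray(self.C, dtype=float))
        if E.shape != C.shape:
            raise ValueError("E and C must have matching shapes")
        if E.ndim not in (1, 2) or E.shape[0] < 1:
            raise ValueError("schedule needs at least one round")
        if np.any(E < 0) or np.any(C < 0):
            raise ValueError("probe amounts must be non-negative")
        if not np.any(E > 0):
            raise ValueError("at least one round must add encoders")
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "C", C)

    @property
    def rounds(self) -> int:
        return self.E.shape[0]

    @property
    def K(self) -> np.ndarray:
        """Per-round capacity (scalar per round, or per species)."""
        return self.E + self.C

    @property
    def T(self) -> np.ndarray:
        """Cumulative capacity after each round."""
        return np.cumsum(self.K, axis=0)

    def per_species(self, r: int, n_species: int):
        """(E, C) amounts for round ``r`` broadcast to ``n_species``."""
        E_r = np.broadcast_to(np.asarray(self.E[r], dtype=float), (n_species,))
        C_r = np.broadcast_to(np.asarray(self.C[r], dtype=float), (n_species,))
        return E_r, C_r

    @classmethod
    def geometric(
        cls,
        rounds: int,
        encoder: float = 10.0,
        growth: float = 10.0,
        first_capacity: float | None = None,
    ) -> "ProbeSchedule":
        """Constant encoders with competitors growing the total capacity.

        Round-r capacity is ``first_capacity * growth**(r-1)`` (default
        first_capacity = encoder, so round 1 has no competitors); the
        competitor amount makes up the difference.  A 10-fold growth per round
        brackets one abundance decade per round.
        """
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        if first_capacity is None:
            first_capacity = encoder
        K = first_capacity * np.power(float(growth), np.arange(rounds))
        if np.any(K < encoder):
            raise ValueError("capacity must be at least the encoder amount")
        E = np.full(rounds, float(encoder))
        return cls(E=E, C=K - E)

    @classmethod
    def from_amounts(cls, E: Sequence[float], C: Sequence[float]) -> "ProbeSchedule":
        return cls(E=np.asarray(E, dtype=float), C=np.asarray(C, dtype=float))


@dataclass
class CodedPool:
    """Tagged molecules accumulated over rounds, before sequencing.

    ``counts[i, r]`` is the number of molecules of species i coded (tagged)
    in round r; ``residual_free`` is what remains unreacted after the last
    round, and ``destroyed`` what competitors removed.
    """

    counts: np.ndarray
    residual_free: np.ndarray
    destroyed: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        _long_format(self.counts).to_csv(path, sep="\t", index=False)


@dataclass
class RoundCountMatrix:
    """Observed read counts per (species, round) after sequencing."""

    counts: np.ndarray

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def rounds(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path) -> None:
        _long_format(self.counts).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RoundCountMatrix":
        df = pd.read_csv(path, sep="\t")
        S = int(df["species_id"].max()) + 1
        R = int(df["round"].max())
        m = np.zeros((S, R), dtype=np.int64)
        m[df["species_id"], df["round"] - 1] = df["count"]
        return cls(m)


def _long_format(counts: np.ndarray) -> pd.DataFrame:
    S, R = counts.shape
    ii, rr = np.nonzero(counts)
    return pd.DataFrame(
        {"species_id": ii, "round": rr + 1, "count": counts[ii, rr]}
    )


def run_protocol(
    pop: SpeciesPopulation,
    sched: ProbeSchedule,
    params: ChemistryParams,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> CodedPool:
    """Run all rounds of the schedule over a population."""
    S = pop.n_species
    if sched.E.ndim == 2 and sched.E.shape[1] != S:
        raise ValueError("per-species schedule does not match population size")
    free = pop.abundances.copy()
    coded = np.zeros((S, sched.rounds), dtype=np.int64)
    destroyed = np.zeros(S, dtype=np.int64)
    for r in range(sched.rounds):
        E_r, C_r = sched.per_species(r, S)
        res = run_round(free, E_r, C_r, params, mode=mode, rng=rng)
        coded[:, r] = res.coded
        destroyed += res.destroyed
        free = res.free_after
    return CodedPool(counts=coded, residual_free=free, destroyed=destroyed)


def sequence_pool(
    pool: CodedPool,
    depth: int,
    rng: np.random.Generator | None = None,
    with_replacement: bool = False,
) -> RoundCountMatrix:
    """Sample ``depth`` reads from the coded pool.

    The pool is a finite library, so default sampling is without replacement
    (multivariate hypergeometric over the (species, round) cells).  A depth
    at or above the pool size returns the pool itself (exhaustive
    sequencing).  ``with_replacement=True`` switches to a multinomial draw.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    total = pool.total
    if depth == 0 or total == 0:
        return RoundCountMatrix(np.zeros_like(pool.counts))
    if not with_replacement and depth >= total:
        return RoundCountMatrix(pool.counts.copy())
    if rng is None:
        raise ValueError("subsampling requires an rng")
    flat = pool.counts.ravel()
    if with_replacement:
        draw = rng.multinomial(int(depth), flat / flat.sum())
    else:
        draw = rng.multivariate_hypergeometric(flat, int(depth), method="marginals")
    return RoundCountMatrix(np.asarray(draw, dtype=np.int64).reshape(pool.counts.shape))


def srs_sample(
    pop: SpeciesPopulation,
    depth: int,
    rng: np.random.Generator,
    method: str = "auto",
) -> np.ndarray:
    """Simple random sampling with replacement: ``depth`` urn draws.

    Exact multinomial for moderate problems; for extreme depths or totals
    (where sequential binomial conditioning is infeasible or float
    probabilities stop being exact) each species is drawn independently as
    Poisson with mean ``depth * n_i / total``, which is the standard
    approximation for small sampling fractions.  The switch depends only on
    (depth, total), so it is seed-stable.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    total = pop.total_molecules
    if total <= 0:
        raise ValueError("population is empty")
    if depth == 0:
        return np.zeros(pop.n_species, dtype=np.int64)
    if method == "auto":
        method = (
            "poisson"
            if (depth > SRS_POISSON_DEPTH or total > _EXACT_FLOAT)
            else "multinomial"
        )
    p = pop.abundances / float(total)
    if method == "multinomial":
        return rng.multinomial(int(depth), p).astype(np.int64)
    if method == "poisson":
        return rng.poisson(float(depth) * p).astype(np.int64)
    raise ValueError(f"unknown method {method!r}")
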