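"""One round of capacity-limited tagging and depletion.

In each round every species is exposed to a limited amount of *encoder*
probes (which tag a molecule with the round identity, making it sampleable)
and *competitor* probes (which capture and remove a molecule).  The model
keeps exact molecule conservation per species:

    coded + destroyed + free_after == free_before.

Hybridization imperfections enter through two parameters:

``eta``
    Per-molecule reaction efficiency (0 < eta <= 1).  With unlimited probes a
    fraction eta of free molecules reacts per round; the remainder carries
    over and can leak into later rounds.
``eps``
    Relative cross-hybridization weight of a code at substitution distance 1.
    Probe capacity left unused by its own species is offered, scaled by eps,
    to distance-1 neighbors that still have unreacted molecules.

Cross-hybridization is resolved by a two-pass allocation: pass 1 satisfies
each species' perfect-match demand ``min(eta*free, E+C)``; pass 2 distributes
each species' leftover probe capacity, weighted by eps, to its distance-1
neighbors in proportion to their residual demand.  There is no leakage beyond
distance 1.  The split of reacted molecules into coded vs destroyed follows
the encoder fraction of the capacity offered to the species; when encoders
and competitors are in excess of targets they compete proportionally for
binding, which is what makes sub-round ("significant figure") occupancy
informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ChemistryParams", "RoundResult", "run_round", "capacity_split"]


def _neighbor_csr(neighbor_map, n_species: int):
    """Normalize a neighbor map to CSR-style (indptr, indices) int64 arrays.

    Accepts a dict {i: [j, ...]}, a sequence of sequences, or an already-built
    (indptr, indices) pair.  Symmetry is validated.
    """
    if neighbor_map is None:
        return None
    if isinstance(neighbor_map, tuple) and len(neighbor_map) == 2:
        indptr, indices = neighbor_map
        return np.asarray(indptr, dtype=np.int64), np.asarray(indices, dtype=np.int64)
    if isinstance(neighbor_map, Mapping):
        lists = [list(neighbor_map.get(i, ())) for i in range(n_species)]
    else:
        lists = [list(x) for x in neighbor_map]
        if len(lists) != n_species:
            raise ValueError("neighbor map length does not match species count")
    pairs = {(i, j) for i, nb in enumerate(lists) for j in nb}
    if any((j, i) not in pairs for i, j in pairs):
        raise ValueError("neighbor map must be symmetric")
    indptr = np.zeros(n_species + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(x) for x in lists])
    indices = np.concatenate([np.asarray(x, dtype=np.int64) for x in lists]) if pairs else np.empty(0, dtype=np.int64)
    return indptr, indices


@dataclass
class ChemistryParams:
    """Hybridization parameters for a SQUICH round.

    neighbor_map may be ``None`` (no cross-hybridization), a dict/sequence of
    per-species neighbor id lists, or a prebuilt CSR pair (indptr, indices)
    as produced by :meth:`squich.codes.Codebook.neighbor_csr`.
    """

    eta: float = 0.95
    eps: float = 0.01
    neighbor_map: object = None

    def __post_init__(self) -> None:
        if not (0 < self.eta <= 1):
            raise ValueError("eta must satisfy 0 < eta <= 1")
        if not (0 <= self.eps < 1):
            raise ValueError("eps must satisfy 0 <= eps < 1")

    def neighbor_csr(self, n_species: int):
        return _neighbor_csr(self.neighbor_map, n_species)


@dataclass
class RoundResult:
    coded: np.ndarray
    destroyed: np.ndarray
    free_after: np.ndarray


def _offered_capacity(free, E, C, eta, eps, csr):
    """Two-pass capacity allocation (float arrays).

    Returns (reacted_mean, K_total, p_code): the expected number reacting per
    species, the total probe capacity offered to each species (own plus
    leaked), and the encoder fraction of that capacity.
    """
    demand = eta * free
    K_own = E + C
    react1 = np.minimum(demand, K_own)
    leftover = K_own - react1
    resid = demand - react1

    K_total = K_own.astype(float).copy()
    KE_total = E.astype(float).copy()
    react2 = np.zeros_like(react1)

    if (
        eps > 0
        and csr is not None
        and csr[1].size
        and np.any(resid > 0)
        and np.any(leftover > 0)
    ):
        indptr, indices = csr
        degree = np.diff(indptr)
        src = np.repeat(np.arange(free.size), degree)
        nbr_resid = resid[indices]
        # residual demand summed over each species' neighbors
        denom = np.bincount(src, weights=nbr_resid, minlength=free.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(denom[src] > 0, nbr_resid / denom[src], 0.0)
        w = eps * leftover[src] * share
        leak = np.bincount(indices, weights=w, minlength=free.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_frac_src = np.where(K_own[src] > 0, E[src] / K_own[src], 0.0)
        leakE = np.bincount(indices, weights=w * e_frac_src, minlength=free.size)
        K_total += leak
        KE_total += leakE
        react2 = np.minimum(resid, leak)

    reacted = react1 + react2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_code = np.where(K_total > 0, KE_total / K_total, 0.0)
    return reacted, K_total, p_code


def capacity_split(E, C, reacted):
    """Split ``reacted`` molecules into (coded, destroyed) ∝ (E, C).

    Largest-remainder rounding keeps coded + destroyed == reacted exactly;
    a half/half tie goes to the encoder side.
    """
    E = np.asarray(E, dtype=float)
    C = np.asarray(C, dtype=float)
    reacted = np.asarray(reacted, dtype=np.int64)
    K = E + C
    if np.any((K <= 0) & (reacted > 0)):
        raise ValueError("molecules cannot react with zero probe capacity")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(K > 0, E / K, 0.0)
    coded = _largest_remainder(reacted, p)
    return coded, reacted - coded


def _largest_remainder(reacted, p_code):
    """Round ``reacted * p_code`` so the coded/destroyed pair sums exactly."""
    coded_f = reacted * p_code
    coded = np.floor(coded_f).astype(np.int64)
    rem_c = coded_f - coded
    dest_f = reacted - coded_f
    rem_d = dest_f - np.floor(dest_f)
    deficit = reacted - coded - np.floor(dest_f).astype(np.int64)
    coded += np.where((deficit > 0) & (rem_c >= rem_d), 1, 0)
    return np.minimum(coded, reacted)


def run_round(
    free,
    E,
    C,
    params: ChemistryParams,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> RoundResult:
    """React free molecules with one round's encoders and competitors.

    Expectation mode is the deterministic idealization: the mean allocation,
    rounded to whole molecules with largest-remainder so conservation is
    exact.  Whenever encoders and at least one reacting molecule are present,
    at least one molecule is coded (the deterministic limit of "up to n of
    each shape is captured and tagged"); this floor preserves the
    interval-bracketing semantics of the idealized protocol and is never more
    than one molecule away from the proportional mean.

    Stochastic mode draws the number reacting as
    ``Binomial(free, min(1, eta*K/free))`` capped at the offered capacity K,
    then splits coded vs destroyed binomially by the encoder fraction of K.
    """
    free = np.asarray(free)
    if np.any(free < 0):
        raise ValueError("free counts must be non-negative")
    free = free.astype(np.int64)
    S = free.size
    E = np.broadcast_to(np.asarray(E, dtype=float), (S,)).copy()
    C = np.broadcast_to(np.asarray(C, dtype=float), (S,)).copy()
    if np.any(E < 0) or np.any(C < 0):
        raise ValueError("probe amounts must be non-negative")

    csr = params.neighbor_csr(S)
    reacted_mean, K_total, p_code = _offered_capacity(
        free.astype(float), E, C, params.eta, params.eps, csr
    )

    if mode == "expectation":
        reacted = np.floor(reacted_mean + 0.5).astype(np.int64)
        reacted = np.minimum(reacted, free)
        coded = _largest_remainder(reacted, p_code)
        # detection floor: an available encoder claims at least one molecule
        floor_mask = (coded == 0) & (reacted >= 1) & (p_code > 0)
        coded[floor_mask] = 1
    elif mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        p_react = np.minimum(1.0, params.eta * K_total / np.maximum(free, 1))
        reacted = rng.binomial(free, p_react)
        cap = np.ceil(K_total - 1e-9).astype(np.int64)
        reacted = np.minimum(reacted, cap)
        coded = rng.binomial(reacted, p_code)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    destroyed = reacted - coded
    return RoundResult(coded=coded, destroyed=destroyed, free_after=free - reacted)
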