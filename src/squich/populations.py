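"""Ground-truth species populations (the "urn" being quantified).

A population is a multiset: species ``0..S-1`` with exact integer molecule
counts ``n_i``.  All abundances are integers so that protocol arithmetic and
conservation checks are exact; the largest supported abundance is 10**15,
which is exactly representable both in int64 and in double precision.

Builders cover the four simulation regimes used throughout the package
(needle-in-haystack, small fold changes, high dynamic range, single-cell) as
well as arbitrary user-specified populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Largest abundance representable exactly (int64 and float64 safe).
MAX_ABUNDANCE = 10**15


@dataclass(frozen=True)
class SpeciesPopulation:
    """Per-species true molecule counts.

    Parameters
    ----------
    abundances:
        Non-negative integer molecule count per species; species identity is
        positional (0-based).
    marked_ids:
        Optional ids of "interesting" species (needles, enriched species);
        used by metrics as the positive set.
    """

    abundances: np.ndarray
    marked_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances)
        if ab.ndim != 1 or ab.size < 1:
            raise ValueError("population must contain at least one species")
        if not np.issubdtype(ab.dtype, np.integer):
            if not np.all(ab == np.floor(ab)):
                raise ValueError("abundances must be integers")
            ab = ab.astype(np.int64)
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        if np.any(ab > MAX_ABUNDANCE):
            raise OverflowError(
                f"abundances above {MAX_ABUNDANCE} are not exactly representable"
            )
        object.__setattr__(self, "abundances", ab.astype(np.int64))
        object.__setattr__(
            self, "marked_ids", np.asarray(self.marked_ids, dtype=np.int64)
        )

    @property
    def n_species(self) -> int:
        return int(self.abundances.size)

    @property
    def species_ids(self) -> np.ndarray:
        return np.arange(self.n_species, dtype=np.int64)

    @property
    def total_molecules(self) -> int:
        # int() promotes to an arbitrary-precision python int; the per-species
        # bound of 1e15 keeps the int64 sum itself far from overflow for any
        # realistic species count.
        return int(self.abundances.sum())

    def to_tsv(self, path) -> None:
        """Write a 2-column TSV (species_id, abundance)."""
        pd.DataFrame(
            {"species_id": self.species_ids, "abundance": self.abundances}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpeciesPopulation":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("species_id")
        return cls(abundances=df["abundance"].to_numpy(dtype=np.int64))


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def build_needle_haystack(
    background_abundance: int, needle_count: int, needle_abundance: int
) -> SpeciesPopulation:
    """One overwhelmingly abundant background species plus rare "needles".

    Species 0 is the background; species ``1..needle_count`` are needles and
    are recorded in ``marked_ids``.
    """
    for name, v in (
        ("background_abundance", background_abundance),
        ("needle_count", needle_count),
        ("needle_abundance", needle_abundance),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    ab = np.full(1 + needle_count, needle_abundance, dtype=np.int64)
    ab[0] = background_abundance
    return SpeciesPopulation(ab, marked_ids=np.arange(1, needle_count + 1))


def build_fold_change(
    n_species: int, background_level: int, enriched_count: int, fold: float
) -> SpeciesPopulation:
    """Uniform background with a small subset at ``fold`` times the level.

    Fractional products round half-up to whole molecules.  ``fold`` < 1 models
    depletion screens; ``fold`` <= 0 is rejected.  Enriched species occupy the
    last ``enriched_count`` ids and are recorded in ``marked_ids``.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if enriched_count > n_species:
        raise ValueError("enriched_count cannot exceed n_species")
    enriched_level = _round_half_up(fold * background_level)
    ab = np.full(n_species, background_level, dtype=np.int64)
    marked = np.arange(n_species - enriched_count, n_species, dtype=np.int64)
    ab[marked] = enriched_level
    return SpeciesPopulation(ab, marked_ids=marked)


def build_dynamic_range(
    mantissas: Sequence[int] = tuple(range(1, 11)),
    decades: Sequence[int] = tuple(range(0, 10)),
    species_per_level: int = 10,
    background_count: int = 3000,
    background_level: int = 100,
) -> SpeciesPopulation:
    """Species spanning abundances ``x * 10**y`` plus a flat background.

    Defaults give 10 species at each of the 100 levels x=1..10, y=0..9
    (1000 leveled species) on top of 3000 background species at level 100.
    The background count is a parameter because only its approximate size is
    pinned down by the regime this emulates.
    """
    mantissas = list(mantissas)
    decades = list(decades)
    if not mantissas or not decades:
        raise ValueError("mantissas and decades must be nonempty")
    levels = [int(x) * 10**int(y) for y in decades for x in mantissas]
    ab = np.repeat(np.asarray(levels, dtype=np.int64), species_per_level)
    if background_count:
        ab = np.concatenate(
            [ab, np.full(background_count, background_level, dtype=np.int64)]
        )
    return SpeciesPopulation(ab)


def build_single_cell(
    basal_count: int = 2587,
    basal_level: int = 100,
    level_mantissas: Sequence[int] = tuple(range(1, 10)),
    level_decades: Sequence[int] = tuple(range(0, 5)),
    species_per_level: int = 10,
    low_levels: Sequence[int] = tuple(range(1, 11)),
    species_per_low_level: int = 100,
) -> SpeciesPopulation:
    """Single pseudo-cell transcript population.

    Defaults: 2587 transcripts at basal expression 100, 10 transcripts at each
    value x*10**y for x=1..9 and y=0..4, and 100 transcripts at each level
    1..10 (4037 species in total).
    """
    blocks = []
    if basal_count:
        blocks.append(np.full(basal_count, basal_level, dtype=np.int64))
    levels = [int(x) * 10**int(y) for y in level_decades for x in level_mantissas]
    if levels and species_per_level:
        blocks.append(np.repeat(np.asarray(levels, dtype=np.int64), species_per_level))
    if low_levels is not None and species_per_low_level:
        blocks.append(
            np.repeat(np.asarray(list(low_levels), dtype=np.int64), species_per_low_level)
        )
    if not blocks:
        raise ValueError("population must be nonempty")
    return SpeciesPopulation(np.concatenate(blocks))
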