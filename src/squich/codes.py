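"""CGA codebooks, probe sequence layout, and synthetic read I/O.

A CGA codebook of order n is the set of 2**n DNA targets of the form
``A[(C/G)A]^n``: an A, then n blocks of (C or G) followed by A.  Bit k of a
codeword (k = 0 is the most significant, i.e. first variable base) selects C
(bit 0) or G (bit 1) at base ``2k + 1``.  Two codewords at bit Hamming
distance 1 are sequences at substitution distance 1 — the cross-hybridizing
neighbor structure the chemistry module consumes.

Reads carry the target followed by a round tag: a fixed-width tag over
{A, C, T} with pairwise Hamming distance >= 2 (a ternary parity code), so a
single substitution never turns one valid tag into another.  The writer and
parser are exact inverses at zero error rate; decoding is strict exact-match
by default, with optional single-mismatch rescue in the target region when
the codebook subset in use guarantees minimum distance >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .protocol import RoundCountMatrix

__all__ = [
    "Codebook",
    "ProbeLayout",
    "enumerate_cga",
    "select_min_distance",
    "round_tag",
    "write_reads",
    "parse_reads",
    "load_count_table",
]

_TAG_ALPHABET = "ACT"
TAG_LENGTH = 6


@dataclass(frozen=True)
class Codebook:
    """The 2**n CGA targets with their index<->sequence bijection."""

    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.n <= 24):
            raise ValueError("codebook order n must lie in 1..24")

    @property
    def size(self) -> int:
        return 2**self.n

    @property
    def sequence_length(self) -> int:
        return 2 * self.n + 1

    def index_to_sequence(self, index: int) -> str:
        if not (0 <= index < self.size):
            raise IndexError("codeword index out of range")
        bases = ["A"]
        for k in range(self.n):
            bit = (index >> (self.n - 1 - k)) & 1
            bases.append("G" if bit else "C")
            bases.append("A")
        return "".join(bases)

    def sequence_to_index(self, seq: str) -> int:
        """Strict inverse of :meth:`index_to_sequence`; raises on mismatch."""
        if len(seq) != self.sequence_length:
            raise ValueError("sequence length does not match codebook order")
        index = 0
        for k in range(self.n):
            if seq[2 * k] != "A" or seq[2 * k + 1] not in "CG":
                raise ValueError("sequence does not match the CGA format")
            index = (index << 1) | (seq[2 * k + 1] == "G")
        if seq[-1] != "A":
            raise ValueError("sequence does not match the CGA format")
        return index

    @property
    def sequences(self) -> list[str]:
        return [self.index_to_sequence(i) for i in range(self.size)]

    def neighbors(self, index: int) -> list[int]:
        """The n codewords at substitution distance 1."""
        return [index ^ (1 << k) for k in range(self.n - 1, -1, -1)]

    def neighbor_csr(self, indices: Sequence[int] | None = None):
        """CSR (indptr, indices) neighbor structure for the chemistry model.

        With ``indices`` given, species s corresponds to codeword
        ``indices[s]`` and only neighbors inside the subset are linked;
        default is the identity assignment over the full codebook.
        """
        if indices is None:
            ids = np.arange(self.size, dtype=np.int64)
            pos = ids
        else:
            ids = np.asarray(indices, dtype=np.int64)
            pos = -np.ones(self.size, dtype=np.int64)
            pos[ids] = np.arange(ids.size)
        flips = ids[:, None] ^ (np.int64(1) << np.arange(self.n, dtype=np.int64))
        nbr_pos = pos[flips]  # (S, n); -1 where the neighbor is not a species
        keep = nbr_pos >= 0
        indptr = np.zeros(ids.size + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(keep.sum(axis=1))
        return indptr, nbr_pos[keep].astype(np.int64)

    def to_fasta(self, path) -> None:
        records = (
            SeqRecord(Seq(self.index_to_sequence(i)), id=f"cga_{i}", description="")
            for i in range(self.size)
        )
        SeqIO.write(records, path, "fasta")


def enumerate_cga(n: int) -> Codebook:
    """Complete CGA codebook of order n (2**n targets, index order)."""
    return Codebook(n)


def select_min_distance(cb: Codebook, d: int) -> np.ndarray:
    """Greedy lexicographic codeword subset with pairwise bit distance >= d.

    Classic sphere-packing greedy: scan codewords in index order, keep one
    whenever it is at distance >= d from everything kept so far.  The result
    is maximal under that order (for d=2 it is the even-weight code).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if d == 1:
        return np.arange(cb.size, dtype=np.int64)
    words = np.arange(cb.size, dtype=np.int64)
    alive = np.ones(cb.size, dtype=bool)
    kept = []
    while alive.any():
        c = int(words[alive][0])
        kept.append(c)
        dist = np.bitwise_count(words[alive] ^ c)
        alive[np.flatnonzero(alive)[dist < d]] = False
    return np.asarray(kept, dtype=np.int64)


def round_tag(round_index: int) -> str:
    """Tag sequence for a 1-based round; ternary code with a parity digit."""
    if round_index < 1 or round_index > 3 ** (TAG_LENGTH - 1):
        raise ValueError("round index out of tag range")
    digits = []
    v = round_index - 1
    for _ in range(TAG_LENGTH - 1):
        digits.append(v % 3)
        v //= 3
    digits.append(sum(digits) % 3)
    return "".join(_TAG_ALPHABET[x] for x in digits)


def _tag_table(rounds: int) -> dict[str, int]:
    return {round_tag(r): r for r in range(1, rounds + 1)}


@dataclass(frozen=True)
class ProbeLayout:
    """Schematic sequence layout of encoders, competitors and reads.

    An encoder carries the reverse complement of its target, a round tag, a
    PCR handle and a terminator motif; a competitor carries only the target
    complement and the terminator.  A sequenced read is the target extended
    with the round tag (and handle).  The terminator chemistry itself is not
    simulated — this is sequence-level bookkeeping only.
    """

    codebook: Codebook
    pcr_handle: str = "TCACTCTACA"
    terminator: str = "TGTT"

    def encoder_sequence(self, index: int, round_index: int) -> str:
        target = self.codebook.index_to_sequence(index)
        return (
            str(Seq(target).reverse_complement())
            + round_tag(round_index)
            + self.pcr_handle
            + self.terminator
        )

    def competitor_sequence(self, index: int) -> str:
        target = self.codebook.index_to_sequence(index)
        return str(Seq(target).reverse_complement()) + self.terminator

    def read_sequence(self, index: int, round_index: int) -> str:
        return (
            self.codebook.index_to_sequence(index)
            + round_tag(round_index)
            + self.pcr_handle
        )

    @property
    def read_length(self) -> int:
        return self.codebook.sequence_length + TAG_LENGTH + len(self.pcr_handle)


def write_reads(
    matrix: RoundCountMatrix,
    cb: Codebook,
    layout: ProbeLayout | None = None,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.0,
) -> list[SeqRecord]:
    """One FASTQ record per read count, optional per-base substitution noise.

    Species s of the matrix is codeword s.  Quality is a constant Phred 40
    string.  Deterministic given the rng state.
    """
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must lie in [0, 1)")
    if error_rate > 0 and rng is None:
        raise ValueError("substitution noise requires an rng")
    layout = layout or ProbeLayout(cb)
    records = []
    ii, rr = np.nonzero(matrix.counts)
    serial = 0
    for i, r in zip(ii, rr):
        seq = layout.read_sequence(int(i), int(r) + 1)
        for _ in range(int(matrix.counts[i, r])):
            s = seq
            if error_rate > 0:
                arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
                hits = np.flatnonzero(rng.random(arr.size) < error_rate)
                for h in hits:
                    choices = [b for b in b"ACGT" if b != arr[h]]
                    arr[h] = choices[rng.integers(3)]
                s = arr.tobytes().decode()
            rec = SeqRecord(Seq(s), id=f"read_{serial}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(s)
            records.append(rec)
            serial += 1
    return records


def parse_reads(
    reads: Iterable,
    cb: Codebook,
    rounds: int,
    layout: ProbeLayout | None = None,
    rescue_one_mismatch: bool = False,
    min_distance: int = 1,
) -> tuple[RoundCountMatrix, int]:
    """Decode reads into a (species x round) count matrix.

    ``reads`` is an iterable of SeqRecords (or any object with ``.seq``), or
    a path/handle to a FASTQ/FASTA file.  Decoding is exact-match on the
    target region and the round tag; non-decodable reads are counted as
    unassigned, never guessed.  Single-mismatch rescue in the target region
    is allowed only when the codebook subset in use has ``min_distance`` >= 3.

    Returns (matrix, n_unassigned).
    """
    if rescue_one_mismatch and min_distance < 3:
        raise ValueError("1-mismatch rescue requires minimum code distance >= 3")
    layout = layout or ProbeLayout(cb)
    records = _as_records(reads)
    tags = _tag_table(rounds)
    L = cb.sequence_length
    counts = np.zeros((cb.size, rounds), dtype=np.int64)
    unassigned = 0
    for rec in records:
        seq = str(getattr(rec, "seq", rec))
        if len(seq) < L + TAG_LENGTH:
            unassigned += 1
            continue
        tag = seq[L : L + TAG_LENGTH]
        r = tags.get(tag)
        target = seq[:L]
        try:
            idx = cb.sequence_to_index(target)
        except ValueError:
            idx = _rescue(target, cb) if rescue_one_mismatch else None
        if r is None or idx is None:
            unassigned += 1
            continue
        counts[idx, r - 1] += 1
    return RoundCountMatrix(counts), unassigned


def _rescue(target: str, cb: Codebook) -> int | None:
    """Decode a target with exactly one substitution, if unambiguous."""
    for pos in range(len(target)):
        for base in "ACG":
            if base == target[pos]:
                continue
            candidate = target[:pos] + base + target[pos + 1 :]
            try:
                return cb.sequence_to_index(candidate)
            except ValueError:
                continue
    return None


def _as_records(reads) -> Iterator:
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        fmt = "fastq"
        if isinstance(reads, str) and reads.endswith((".fa", ".fasta")):
            fmt = "fasta"
        return SeqIO.parse(reads, fmt)
    return iter(reads)


def load_count_table(path_or_buf, rounds: int, cb: Codebook | None = None):
    """Load a long-format count CSV (species, sample, round, count).

    The species column may hold integer ids or CGA sequences (decoded with
    ``cb``).  Returns a dict mapping sample name to RoundCountMatrix.
    Provided for analyzing externally produced count tables; nothing in the
    simulators depends on it.
    """
    df = pd.read_csv(path_or_buf)
    required = {"species", "sample", "round", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    if cb is not None:
        df["species"] = [
            cb.sequence_to_index(s) if isinstance(s, str) else int(s)
            for s in df["species"]
        ]
    n_species = cb.size if cb is not None else int(df["species"].max()) + 1
    out = {}
    for sample, grp in df.groupby("sample"):
        m = np.zeros((n_species, rounds), dtype=np.int64)
        np.add.at(m, (grp["species"].to_numpy(), grp["round"].to_numpy() - 1), grp["count"].to_numpy())
        out[sample] = RoundCountMatrix(m)
    return out
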