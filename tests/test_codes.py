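import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import squich as sq
from squich.codes import TAG_LENGTH, round_tag
from squich.protocol import RoundCountMatrix


class TestCodebook:
    def test_smallest_codebook(self):
        cb = sq.enumerate_cga(1)
        assert [cb.index_to_sequence(i) for i in range(cb.size)] == ["ACA", "AGA"]

    def test_experimental_complexity(self):
        assert sq.enumerate_cga(18).size == 262144

    def test_bit_convention(self):
        cb = sq.enumerate_cga(3)
        # index 5 = binary 101 -> G, C, G at the variable positions
        assert cb.index_to_sequence(5) == "AGACAGA"
        assert cb.sequence_to_index("AGACAGA") == 5

    @pytest.mark.parametrize("n", [1, 2, 5, 8])
    def test_round_trip_exhaustive(self, n):
        cb = sq.enumerate_cga(n)
        for i in range(cb.size):
            assert cb.sequence_to_index(cb.index_to_sequence(i)) == i

    @given(idx=st.integers(0, 2**18 - 1))
    @settings(max_examples=50)
    def test_round_trip_large_order(self, idx):
        cb = sq.enumerate_cga(18)
        assert cb.sequence_to_index(cb.index_to_sequence(idx)) == idx

    def test_malformed_sequences_rejected(self):
        cb = sq.enumerate_cga(2)
        for bad in ["ACAC", "TCACA", "ACACT", "ACA"]:
            with pytest.raises(ValueError):
                cb.sequence_to_index(bad)

    def test_order_out_of_range(self):
        with pytest.raises(ValueError):
            sq.enumerate_cga(0)
        with pytest.raises(ValueError):
            sq.enumerate_cga(25)

    def test_neighbors_are_single_substitutions(self):
        cb = sq.enumerate_cga(4)
        for i in (0, 5, 15):
            nbrs = cb.neighbors(i)
            assert len(nbrs) == 4
            for j in nbrs:
                si, sjj = cb.index_to_sequence(i), cb.index_to_sequence(j)
                assert sum(a != b for a, b in zip(si, sjj)) == 1
                assert i in cb.neighbors(j)  # symmetric

    def test_neighbor_csr_subset(self):
        cb = sq.enumerate_cga(3)
        subset = np.array([0, 1, 4])  # 0~1 (bit 0) and 0~4 (bit 2) adjacent
        indptr, indices = cb.neighbor_csr(subset)
        nbrs = {i: set(indices[indptr[i]:indptr[i + 1]]) for i in range(3)}
        assert nbrs == {0: {1, 2}, 1: {0}, 2: {0}}


class TestMinDistanceSelection:
    def test_d1_keeps_everything(self):
        cb = sq.enumerate_cga(4)
        assert sq.select_min_distance(cb, 1).size == 16

    def test_even_weight_code(self):
        kept = sq.select_min_distance(sq.enumerate_cga(3), 2)
        assert kept.tolist() == [0, 3, 5, 6]

    @pytest.mark.parametrize("n, d", [(6, 2), (8, 3), (10, 4)])
    def test_all_pairs_distance_oracle(self, n, d):
        kept = sq.select_min_distance(sq.enumerate_cga(n), d)
        xor = kept[:, None] ^ kept[None, :]
        dist = np.bitwise_count(xor)
        np.fill_diagonal(dist, d)
        assert dist.min() >= d


class TestRoundTags:
    def test_supports_many_distinct_rounds(self):
        tags = [round_tag(r) for r in range(1, 33)]
        assert len(set(tags)) == 32
        assert all(len(t) == TAG_LENGTH for t in tags)

    def test_pairwise_hamming_distance_two(self):
        tags = [round_tag(r) for r in range(1, 17)]
        for a, b in itertools.combinations(tags, 2):
            assert sum(x != y for x, y in zip(a, b)) >= 2


class TestReadRoundTrip:
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 5), min_size=3, max_size=3),
            min_size=4,
            max_size=4,
        )
    )
    @settings(max_examples=25)
    def test_parse_inverts_write(self, counts):
        cb = sq.enumerate_cga(2)
        m = RoundCountMatrix(np.array(counts, dtype=np.int64))
        records = sq.write_reads(m, cb)
        back, unassigned = sq.parse_reads(records, cb, rounds=3)
        assert unassigned == 0
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_record_count_matches_depth(self):
        cb = sq.enumerate_cga(2)
        m = RoundCountMatrix(np.array([[2, 0], [1, 3], [0, 0], [0, 1]]))
        assert len(sq.write_reads(m, cb)) == 7

    def test_single_substitution_unassigned_in_strict_mode(self):
        cb = sq.enumerate_cga(2)
        m = RoundCountMatrix(np.array([[1], [0], [0], [0]]))
        rec = sq.write_reads(m, cb)[0]
        corrupted = "T" + str(rec.seq)[1:]
        back, unassigned = sq.parse_reads([corrupted], cb, rounds=1)
        assert unassigned == 1
        assert back.depth == 0

    def test_one_mismatch_rescue_requires_distance(self):
        cb = sq.enumerate_cga(4)
        with pytest.raises(ValueError):
            sq.parse_reads([], cb, rounds=1, rescue_one_mismatch=True, min_distance=2)
        m = RoundCountMatrix(np.zeros((16, 1), dtype=np.int64))
        m.counts[5, 0] = 1
        rec = sq.write_reads(m, cb)[0]
        corrupted = "T" + str(rec.seq)[1:]
        back, unassigned = sq.parse_reads(
            [corrupted], cb, rounds=1, rescue_one_mismatch=True, min_distance=3
        )
        assert unassigned == 0
        assert back.counts[5, 0] == 1

    def test_empty_input(self):
        back, unassigned = sq.parse_reads([], sq.enumerate_cga(2), rounds=4)
        assert back.depth == 0 and unassigned == 0

    def test_substitution_noise_unassignment_rate(self):
        """The unassigned fraction under per-base substitution noise matches
        the closed form: fixed target bases and tag bases must survive
        untouched, while a variable base survives a C<->G substitution (it
        then decodes, to a neighboring codeword).  Errors beyond the tag
        (in the handle) are harmless."""
        cb = sq.enumerate_cga(4)
        e = 0.02
        m = RoundCountMatrix(np.full((16, 2), 100, dtype=np.int64))
        rng = np.random.default_rng(17)
        records = sq.write_reads(m, cb, rng=rng, error_rate=e)
        _, unassigned = sq.parse_reads(records, cb, rounds=2)
        n_fixed = cb.n + 1 + TAG_LENGTH
        p = 1 - (1 - e) ** n_fixed * (1 - 2 * e / 3) ** cb.n
        total = int(m.counts.sum())
        se = np.sqrt(p * (1 - p) * total)
        assert abs(unassigned - total * p) < 4 * se

    def test_fastq_file_round_trip(self, tmp_path):
        from Bio import SeqIO

        cb = sq.enumerate_cga(3)
        m = RoundCountMatrix(np.zeros((8, 2), dtype=np.int64))
        m.counts[3, 0] = 4
        m.counts[6, 1] = 2
        path = tmp_path / "reads.fastq"
        SeqIO.write(sq.write_reads(m, cb), str(path), "fastq")
        back, unassigned = sq.parse_reads(str(path), cb, rounds=2)
        assert unassigned == 0
        np.testing.assert_array_equal(back.counts, m.counts)


def test_probe_layout_regions():
    cb = sq.enumerate_cga(2)
    layout = sq.ProbeLayout(cb)
    enc = layout.encoder_sequence(1, round_index=2)
    comp = layout.competitor_sequence(1)
    target_rc = enc[: cb.sequence_length]
    assert comp.startswith(target_rc)
    assert enc.endswith(layout.pcr_handle + layout.terminator)
    assert comp.endswith(layout.terminator)
    assert round_tag(2) in enc
    assert layout.pcr_handle not in comp


def test_count_table_loader():
    import io

    cb = sq.enumerate_cga(2)
    csv = io.StringIO(
        "species,sample,round,count\n"
        "ACACA,lib1,1,5\nAGACA,lib1,2,3\nACACA,lib2,1,1\n"
    )
    tables = sq.codes.load_count_table(csv, rounds=2, cb=cb)
    assert set(tables) == {"lib1", "lib2"}
    assert tables["lib1"].counts[0, 0] == 5
    assert tables["lib1"].counts[cb.sequence_to_index("AGACA"), 1] == 3
    assert tables["lib2"].depth == 1
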