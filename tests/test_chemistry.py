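import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import squich as sq
from squich.chemistry import run_round


def brute_force_allocation(free, E, C, eta, eps, neighbors):
    """Independent scalar implementation of the round allocation contract.

    Loops over species and neighbor lists with plain python floats: pass 1
    satisfies perfect-match demand, pass 2 hands each species' leftover probe
    capacity (weighted by eps) to its distance-1 neighbors in proportion to
    their residual demand.  Returns expected (reacted, coded) per species.
    """
    S = len(free)
    demand = [eta * free[i] for i in range(S)]
    react1 = [min(demand[i], E[i] + C[i]) for i in range(S)]
    leftover = [E[i] + C[i] - react1[i] for i in range(S)]
    resid = [demand[i] - react1[i] for i in range(S)]
    leak = [0.0] * S
    leakE = [0.0] * S
    for j in range(S):
        nbrs = neighbors.get(j, [])
        tot = sum(resid[i] for i in nbrs)
        if tot > 0 and leftover[j] > 0:
            for i in nbrs:
                w = eps * leftover[j] * resid[i] / tot
                leak[i] += w
                if E[j] + C[j] > 0:
                    leakE[i] += w * E[j] / (E[j] + C[j])
    reacted = [react1[i] + min(resid[i], leak[i]) for i in range(S)]
    coded = []
    for i in range(S):
        K = E[i] + C[i] + leak[i]
        KE = E[i] + leakE[i]
        coded.append(reacted[i] * (KE / K if K > 0 else 0.0))
    return reacted, coded


class TestCapacitySplit:
    @pytest.mark.parametrize(
        "E, C, reacted, expected",
        [
            (1, 8, 9, (1, 8)),  # tube round 2: tag 1, destroy 8
            (5, 0, 3, (3, 0)),  # encoders only
            (1, 899, 900, (1, 899)),  # tube round 4 proportions
            (1, 1, 3, (2, 1)),  # tie on the split goes to the encoder
        ],
    )
    def test_examples(self, E, C, reacted, expected):
        coded, destroyed = sq.capacity_split(E, C, reacted)
        assert (int(coded), int(destroyed)) == expected

    def test_zero_capacity_with_reaction_impossible(self):
        with pytest.raises(ValueError):
            sq.capacity_split(0, 0, 3)

    @given(
        E=st.integers(0, 50),
        C=st.integers(0, 50),
        reacted=st.integers(0, 100),
    )
    def test_split_conserves(self, E, C, reacted):
        if E + C == 0:
            reacted = 0
        coded, destroyed = sq.capacity_split(E, C, reacted)
        assert coded + destroyed == reacted
        assert coded >= 0 and destroyed >= 0


class TestDeterministicCapture:
    def test_tube_round_semantics(self, ideal_chem):
        # 1000 spheres / 10 cubes facing 1 encoder + 8 competitors each
        res = run_round([1000, 10], [1, 1], [8, 8], ideal_chem, "expectation")
        assert res.coded.tolist() == [1, 1]
        assert res.destroyed.tolist() == [8, 8]
        assert res.free_after.tolist() == [991, 1]

    def test_probes_in_excess(self, ideal_chem):
        res = run_round([5], [10], [0], ideal_chem, "expectation")
        assert res.coded.tolist() == [5]
        assert res.destroyed.tolist() == [0]
        assert res.free_after.tolist() == [0]

    def test_length_mismatch_rejected(self, ideal_chem):
        with pytest.raises(ValueError):
            run_round([1, 2], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0], ideal_chem)

    def test_negative_rejected(self, ideal_chem):
        with pytest.raises(ValueError):
            run_round([-1], [1], [0], ideal_chem)


class TestCrossHybridization:
    def test_leaked_capacity_feeds_starved_neighbor(self):
        # b has no molecules, so b's probes leak eps of their capacity to a
        params = sq.ChemistryParams(eta=1.0, eps=0.5, neighbor_map={0: [1], 1: [0]})
        res = run_round([100, 0], [10.0, 10.0], [0.0, 0.0], params, "expectation")
        # own capacity 10 plus eps * leftover_b = 0.5 * 10 = 5, all encoder
        assert res.coded.tolist() == [15, 0]
        assert res.free_after.tolist() == [85, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.integers(2, 9)
        free = rng.integers(0, 2000, S)
        E = rng.integers(0, 50, S).astype(float)
        C = rng.integers(0, 50, S).astype(float)
        eta = float(rng.uniform(0.5, 1.0))
        eps = float(rng.uniform(0.0, 0.5))
        neighbors = {i: [] for i in range(S)}
        for _ in range(S):
            i, j = rng.integers(0, S, 2)
            if i != j and j not in neighbors[i]:
                neighbors[i].append(int(j))
                neighbors[j].append(int(i))
        params = sq.ChemistryParams(eta=eta, eps=eps, neighbor_map=neighbors)
        res = run_round(free, E, C, params, "expectation")
        reacted_bf, coded_bf = brute_force_allocation(
            free.tolist(), E.tolist(), C.tolist(), eta, eps, neighbors
        )
        reacted = res.coded + res.destroyed
        for i in range(S):
            assert abs(reacted[i] - reacted_bf[i]) <= 1.0
            assert abs(res.coded[i] - coded_bf[i]) <= 1.0

    def test_asymmetric_neighbor_map_rejected(self):
        with pytest.raises(ValueError):
            sq.ChemistryParams(neighbor_map={0: [1], 1: []}).neighbor_csr(2)


class TestParamValidation:
    @pytest.mark.parametrize("eta, eps", [(0.0, 0.0), (1.5, 0.0), (0.9, 1.0), (0.9, -0.1)])
    def test_out_of_range(self, eta, eps):
        with pytest.raises(ValueError):
            sq.ChemistryParams(eta=eta, eps=eps)


@st.composite
def round_instances(draw):
    S = draw(st.integers(1, 6))
    free = draw(st.lists(st.integers(0, 5000), min_size=S, max_size=S))
    E = draw(st.lists(st.integers(0, 100), min_size=S, max_size=S))
    C = draw(st.lists(st.integers(0, 100), min_size=S, max_size=S))
    eta = draw(st.floats(0.05, 1.0))
    eps = draw(st.floats(0.0, 0.9))
    pairs = draw(
        st.lists(
            st.tuples(st.integers(0, S - 1), st.integers(0, S - 1)), max_size=4
        )
    )
    neighbors = {i: [] for i in range(S)}
    for i, j in pairs:
        if i != j and j not in neighbors[i]:
            neighbors[i].append(j)
            neighbors[j].append(i)
    return free, E, C, sq.ChemistryParams(eta=eta, eps=eps, neighbor_map=neighbors)


class TestConservation:
    @given(inst=round_instances(), mode=st.sampled_from(["expectation", "stochastic"]))
    def test_molecules_conserved_exactly(self, inst, mode):
        free, E, C, params = inst
        rng = np.random.default_rng(7)
        res = run_round(free, E, C, params, mode, rng=rng)
        assert np.all(res.coded >= 0)
        assert np.all(res.destroyed >= 0)
        assert np.all(res.free_after >= 0)
        np.testing.assert_array_equal(
            res.coded + res.destroyed + res.free_after, np.asarray(free)
        )

    @given(inst=round_instances(), seed=st.integers(0, 100))
    @settings(max_examples=30)
    def test_stochastic_respects_capacity(self, inst, seed):
        free, E, C, params = inst
        res = run_round(free, E, C, params, "stochastic", rng=np.random.default_rng(seed))
        reacted = res.coded + res.destroyed
        # offered capacity: own probes plus at most eps * leftover per neighbor
        K_max = np.asarray(E, dtype=float) + np.asarray(C, dtype=float)
        for i, nbrs in enumerate(params.neighbor_map.values()):
            K_max[i] += params.eps * sum(E[j] + C[j] for j in nbrs)
        assert np.all(reacted <= np.ceil(K_max))


class TestMonotonicity:
    def test_coded_increases_with_encoder_share(self, ideal_chem):
        # fixed total capacity K=10 against 100 free molecules
        coded = [
            int(run_round([100], [e], [10 - e], ideal_chem, "expectation").coded[0])
            for e in range(11)
        ]
        assert coded == sorted(coded)

    def test_reacted_increases_with_eta(self):
        reacted = []
        for eta in (0.2, 0.5, 0.8, 1.0):
            params = sq.ChemistryParams(eta=eta, eps=0.0)
            res = run_round([100], [5], [5], params, "expectation")
            reacted.append(int(res.coded[0] + res.destroyed[0]))
        assert reacted == sorted(reacted)
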