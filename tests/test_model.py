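"""State encoding, generator construction, and CTMC structural invariants."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings, strategies as st

from pairmhn.model import (
    LOG_RATE_FLOOR,
    EventSystem,
    PairMHNError,
    ParameterSet,
    assemble_dense_generator,
    build_generator_parts,
    decode_state,
    encode_state,
    reachable_state_indices,
    state_index,
)


class TestEncoding:
    def test_wild_type_is_index_zero(self):
        assert state_index([0], [0], 0) == 0
        assert state_index([0, 0, 0], [0, 0, 0], 0) == 0

    def test_shared_event_bits(self):
        st_ = encode_state([1], [1], 0)
        assert st_.bits == (1, 1, 0)
        assert st_.index == 3

    def test_bit_layout(self):
        # event i: PT bit at 2i, MT bit at 2i+1 (0-based); seeding at 2n
        st_ = encode_state([1, 0], [1, 1], 1)
        assert st_.bits == (1, 1, 0, 1, 1)
        assert st_.index == 1 + 2 + 8 + 16

    def test_round_trip(self):
        for idx in reachable_state_indices(2):
            full = decode_state(int(idx), 2)
            back = encode_state(full.pt, full.mt, full.seeding)
            assert back.index == idx

    def test_reachable_count(self):
        # shared pre-seeding states plus all post-seeding pairs: 2^n + 4^n
        assert len(reachable_state_indices(2)) == 2**2 + 4**2 == 20
        assert len(reachable_state_indices(0)) == 2
        assert len(reachable_state_indices(3)) == 2**3 + 4**3

    def test_unreachable_encoding_rejected(self):
        with pytest.raises(PairMHNError, match="unreachable"):
            encode_state([1, 0], [0, 0], 0)

    def test_length_mismatch(self):
        with pytest.raises(PairMHNError):
            encode_state([1, 0], [0], 1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=4), st.data())
    def test_encode_decode_invertible(self, n, data):
        pt = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        mt = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        seed = 1 if pt != mt else data.draw(st.integers(0, 1))
        full = encode_state(pt, mt, seed)
        back = decode_state(full.index, n)
        assert list(back.pt) == pt and list(back.mt) == mt and back.seeding == seed


class TestEventSystem:
    def test_validation(self):
        with pytest.raises(PairMHNError):
            EventSystem(2, ("A", "A"))
        with pytest.raises(PairMHNError):
            EventSystem(2, ("A",))
        with pytest.raises(PairMHNError):
            EventSystem(-1)
        with pytest.raises(PairMHNError):
            EventSystem(1, ("Seeding",))

    def test_defaults(self):
        sys = EventSystem(3)
        assert sys.event_names == ("E1", "E2", "E3")
        assert sys.seeding_index == 3
        assert sys.n_states == 2**7

    def test_non_finite_parameters_rejected(self):
        th = np.zeros((2, 2))
        th[0, 1] = np.inf
        with pytest.raises(PairMHNError, match="non-finite"):
            ParameterSet(th, np.zeros(2), np.zeros(2))


class TestGeneratorParts:
    def test_neutral_joint_rate_is_one(self):
        # all theta = 0 (multiplicative effects 1): empty product
        parts = build_generator_parts(ParameterSet.zeros(1), EventSystem(1))
        src = state_index([0], [0], 0)
        dst = state_index([1], [1], 0)
        assert parts.q0[dst, src] == pytest.approx(1.0)

    def test_joint_rate_includes_shared_effects(self):
        # event 2 base rate 1, promoted by present shared event 1 with effect 3
        th = np.zeros((3, 3))
        th[1, 0] = np.log(3.0)
        parts = build_generator_parts(ParameterSet(th, np.zeros(3), np.zeros(3)),
                                      EventSystem(2))
        src = state_index([1, 0], [1, 0], 0)
        dst = state_index([1, 1], [1, 1], 0)
        assert parts.q0[dst, src] == pytest.approx(3.0)

    def test_mt_rate_includes_seeding_environment_effect(self):
        th = np.zeros((2, 2))
        th[0, 1] = np.log(5.0)  # seeding's effect on event 1
        parts = build_generator_parts(ParameterSet(th, np.zeros(2), np.zeros(2)),
                                      EventSystem(1))
        for pt_bit in (0, 1):
            src = state_index([pt_bit], [0], 1)
            dst = state_index([pt_bit], [1], 1)
            assert parts.qm[dst, src] == pytest.approx(5.0)

    def test_u_mt_zero_before_seeding(self, rng):
        parts = build_generator_parts(ParameterSet.random(2, rng), EventSystem(2))
        from pairmhn.model import _bit_tables

        _, _, seed = _bit_tables(2)
        assert np.all(parts.u_mt[seed == 0] == 0.0)

    def test_wild_type_pt_observation_rate_is_one(self, rng):
        parts = build_generator_parts(ParameterSet.random(3, rng), EventSystem(3))
        assert parts.u_pt[0] == pytest.approx(1.0)  # empty product fixes the time unit

    def test_qp_independent_of_mt_bits(self, random_params2, sys2):
        # post-seeding PT rates depend on the PT genotype only (and vice versa)
        parts = build_generator_parts(random_params2, sys2)
        for pt in ([0, 0], [0, 1]):
            for i in (0, 1):
                if pt[i]:
                    continue
                dst_pt = list(pt)
                dst_pt[i] = 1
                rates = set()
                for mt_mask in range(4):
                    mt = [(mt_mask >> k) & 1 for k in range(2)]
                    src = state_index(pt, mt, 1)
                    dst = state_index(dst_pt, mt, 1)
                    rates.add(float(parts.qp[dst, src]))
                assert len(rates) == 1
        for mt in ([0, 0], [1, 0]):
            for i in (0, 1):
                if mt[i]:
                    continue
                dst_mt = list(mt)
                dst_mt[i] = 1
                rates = set()
                for pt_mask in range(4):
                    pt = [(pt_mask >> k) & 1 for k in range(2)]
                    src = state_index(pt, mt, 1)
                    dst = state_index(pt, dst_mt, 1)
                    rates.add(float(parts.qm[dst, src]))
                assert len(rates) == 1

    def test_transition_locality(self, random_params2, sys2):
        # every permitted jump changes exactly one unit: a shared pair, a PT
        # bit, an MT bit, or the seeding bit
        parts = build_generator_parts(random_params2, sys2)
        n = sys2.n
        for name, mat in (("q0", parts.q0), ("qs", parts.qs),
                          ("qp", parts.qp), ("qm", parts.qm)):
            coo = mat.tocoo()
            for y, x in zip(coo.row, coo.col):
                diff = int(y) ^ int(x)
                popcount = bin(diff).count("1")
                if name == "q0":
                    assert popcount == 2 and diff & (1 << (2 * n)) == 0
                elif name == "qs":
                    assert diff == 1 << (2 * n)
                else:
                    assert popcount == 1 and diff & (1 << (2 * n)) == 0

    def test_dimension_mismatch(self):
        with pytest.raises(PairMHNError):
            build_generator_parts(ParameterSet.zeros(2), EventSystem(3))


class TestDenseGenerator:
    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_columns_conserve(self, n, rng):
        for _ in range(25):
            params = ParameterSet.random(n, rng)
            G = assemble_dense_generator(build_generator_parts(params, EventSystem(n)))
            assert np.abs(G.sum(axis=0)).max() < 1e-12
            size = 1 << (2 * n + 1)
            off = G.copy()
            np.fill_diagonal(off, 0.0)
            assert off.min() >= 0.0
            # flagged blocks are absorbing
            assert np.all(G[:, size:] == 0.0)

    def test_n0_wild_type_exits(self):
        # seeding rate 1 and baseline PT observation rate 1 compete
        parts = build_generator_parts(ParameterSet.zeros(0), EventSystem(0))
        G = assemble_dense_generator(parts)
        seeded = state_index([], [], 1)
        assert G[seeded, 0] == pytest.approx(1.0)
        assert G[2 + 0, 0] == pytest.approx(1.0)  # PT-observed block starts at 2

    def test_guard(self, rng):
        parts = build_generator_parts(ParameterSet.random(5, rng), EventSystem(5))
        with pytest.raises(PairMHNError, match="guard"):
            assemble_dense_generator(parts)

    def test_n2_transition_diagram(self, random_params2, sys2):
        # hand enumeration of the n=2 diagram: per shared state, one joint
        # transition per absent event plus seeding; per post-seeding pair,
        # one PT and one MT transition per absent bit
        parts = build_generator_parts(random_params2, sys2)
        expected = 0
        for g in range(4):
            expected += (2 - bin(g).count("1")) + 1  # absent events + seeding
        for p in range(4):
            for m in range(4):
                expected += (2 - bin(p).count("1")) + (2 - bin(m).count("1"))
        total_nnz = sum(m.nnz for m in (parts.q0, parts.qs, parts.qp, parts.qm))
        assert total_nnz == expected == 40

    def test_no_mass_leaks_to_unreachable_states(self, random_params2, sys2):
        # forward evolution from wild type never populates pre-seeding states
        # with diverged genotypes
        parts = build_generator_parts(random_params2, sys2)
        R = parts.rate_matrix.toarray()
        Q = R - np.diag(R.sum(axis=0) + parts.u_pt + parts.u_mt)
        reachable = set(int(i) for i in reachable_state_indices(2))
        p0 = np.zeros(sys2.n_states)
        p0[0] = 1.0
        for t in (0.1, 0.5, 2.0, 10.0):
            pt = sla.expm(t * Q) @ p0
            for idx, mass in enumerate(pt):
                if idx not in reachable:
                    assert abs(mass) < 1e-12
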