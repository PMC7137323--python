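import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from hept.hept_core import (
    HeptConfig,
    ScoreState,
    build_transition_tensors,
    iterate_once,
    normalize_tensor,
    rank_proteins,
    run_hept,
)
from hept.io_formats import ProteinIndex
from hept.jump_vector import JumpVector
from hept.tensor_builder import RelationTensor

from _dense_reference import (
    dense_iterate,
    dense_personalized_hits,
    dense_run,
    dense_transitions,
    materialize_transitions,
    random_relation_tensor,
)
from conftest import sparse_tensor_from_dense


def uniform_jump(n):
    return JumpVector(d=np.full(n, 1.0 / n), normalized=True)


def random_jump(rng, n):
    d = rng.random(n) + 1e-3
    return JumpVector(d=d / d.sum(), normalized=True)


class TestNormalizeTensor:
    def test_authority_fiber_example(self):
        # one column fiber with entries (2, 3, 5)*c -> (0.2, 0.3, 0.5)
        T = np.zeros((4, 4, 1))
        T[0, 3, 0], T[1, 3, 0], T[2, 3, 0] = 0.4, 0.6, 1.0
        tensor = sparse_tensor_from_dense(T)
        mats, masks = normalize_tensor(tensor, "authority")
        col = np.asarray(mats[0].todense())[:, 3]
        assert np.allclose(col, [0.2, 0.3, 0.5, 0.0])
        assert not masks[0][3] and masks[0][0]

    def test_all_zero_fiber_uniform(self):
        tensor = sparse_tensor_from_dense(np.zeros((4, 4, 1)))
        tt = build_transition_tensors(tensor)
        Ta, Th, Te = materialize_transitions(tt)
        assert np.allclose(Ta, 0.25) and np.allclose(Th, 0.25)
        assert np.allclose(Te, 1.0)  # m = 1

    def test_edge_mode_pair(self):
        T = np.zeros((2, 2, 3))
        T[0, 1, 0] = T[1, 0, 0] = 0.5
        T[0, 1, 2] = T[1, 0, 2] = 0.5
        tt = build_transition_tensors(sparse_tensor_from_dense(T))
        _, _, Te = materialize_transitions(tt)
        assert np.allclose(Te[0, 1], [0.5, 0.0, 0.5])
        assert np.allclose(Te[0, 0], 1 / 3)  # diagonal pair -> uniform

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_tensor(sparse_tensor_from_dense(np.zeros((2, 2, 1))), "sideways")

    @pytest.mark.parametrize("seed", range(5))
    def test_fiber_stochasticity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        T = random_relation_tensor(rng, n)
        tt = build_transition_tensors(sparse_tensor_from_dense(T))
        Ta, Th, Te = materialize_transitions(tt)
        assert np.allclose(Ta.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(Th.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(Te.sum(axis=2), 1.0, atol=1e-12)


class TestIterateOnce:
    def test_alpha_zero_gives_jump_vector(self):
        rng = np.random.default_rng(0)
        T = random_relation_tensor(rng, 12)
        tt = build_transition_tensors(sparse_tensor_from_dense(T))
        jump = random_jump(rng, 12)
        cfg = HeptConfig(alpha=0.0)
        state = iterate_once(ScoreState.initial(12, 3), tt, jump, cfg)
        assert np.allclose(state.va, jump.d, atol=1e-14)

    def test_alpha_one_uniform_fixed_point(self):
        n, m = 5, 3
        tt = build_transition_tensors(sparse_tensor_from_dense(np.zeros((n, n, m))))
        cfg = HeptConfig(alpha=1.0)
        state = iterate_once(ScoreState.initial(n, m), tt, uniform_jump(n), cfg)
        assert np.allclose(state.va, 1 / n) and np.allclose(state.vh, 1 / n)
        assert np.allclose(state.ve, 1 / m)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("normalize", [True, False])
    def test_matches_dense_reference(self, seed, normalize):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        T = random_relation_tensor(rng, n)
        tt = build_transition_tensors(sparse_tensor_from_dense(T))
        jump = random_jump(rng, n)
        cfg = HeptConfig(alpha=0.3, normalize_state=normalize)
        state = ScoreState.initial(n, 3)
        Ta, Th, Te = dense_transitions(T)
        va, vh, ve = state.va, state.vh, state.ve
        for _ in range(4):
            state = iterate_once(state, tt, jump, cfg)
            va, vh, ve = dense_iterate(va, vh, ve, Ta, Th, Te, jump.d, 0.3, normalize)
            assert np.allclose(state.va, va, atol=1e-10)
            assert np.allclose(state.vh, vh, atol=1e-10)
            assert np.allclose(state.ve, ve, atol=1e-10)

    def test_nonnegative_and_normalized(self):
        rng = np.random.default_rng(3)
        n = 15
        T = random_relation_tensor(rng, n)
        tt = build_transition_tensors(sparse_tensor_from_dense(T))
        state = ScoreState.initial(n, 3)
        for _ in range(5):
            state = iterate_once(state, tt, random_jump(rng, n), HeptConfig())
            for v in (state.va, state.vh, state.ve):
                assert np.all(v >= 0)
                assert abs(v.sum() - 1.0) < 1e-10


class TestSingleSliceDegeneracy:
    """m = 1 reduces the method to personalized matrix HITS."""

    @pytest.mark.parametrize("seed", range(4))
    def test_trajectory_matches_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        W = random_relation_tensor(rng, n, m=1, zero_slice_prob=0.0)[:, :, 0]
        tensor = sparse_tensor_from_dense(W[:, :, None])
        tt = build_transition_tensors(tensor)
        jump = random_jump(rng, n)
        oracle = dense_personalized_hits(W, jump.d, alpha=0.3, n_iters=6)
        state = ScoreState.initial(n, 1)
        for va_ref, vh_ref in oracle:
            state = iterate_once(state, tt, jump, HeptConfig(alpha=0.3))
            assert np.allclose(state.va, va_ref, atol=1e-10)
            assert np.allclose(state.vh, vh_ref, atol=1e-10)
            assert np.allclose(state.ve, [1.0])


class TestRunHept:
    def test_huge_epsilon_one_iteration(self):
        rng = np.random.default_rng(1)
        tensor = sparse_tensor_from_dense(random_relation_tensor(rng, 10))
        state, converged, iters = run_hept(tensor, random_jump(rng, 10), HeptConfig(epsilon=10.0))
        assert converged and iters == 1

    def test_uniform_fixed_point_converges_fast(self):
        n, m = 6, 3
        tensor = sparse_tensor_from_dense(np.zeros((n, n, m)))
        state, converged, iters = run_hept(tensor, uniform_jump(n), HeptConfig(alpha=1.0))
        assert converged and iters <= 2
        assert np.allclose(state.va, 1 / n)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        T = random_relation_tensor(rng, 20)
        jump = random_jump(rng, 20)
        s1, c1, i1 = run_hept(sparse_tensor_from_dense(T), jump, HeptConfig(epsilon=1e-10))
        s2, c2, i2 = run_hept(sparse_tensor_from_dense(T), jump, HeptConfig(epsilon=1e-10))
        assert c1 and c2 and i1 == i2 and i1 <= 1000
        assert np.array_equal(s1.va, s2.va)
        assert np.array_equal(s1.vh, s2.vh)
        assert np.array_equal(s1.ve, s2.ve)

    def test_fixed_point_residual(self):
        rng = np.random.default_rng(5)
        tensor = sparse_tensor_from_dense(random_relation_tensor(rng, 15))
        jump = random_jump(rng, 15)
        cfg = HeptConfig(epsilon=1e-10)
        state, converged, _ = run_hept(tensor, jump, cfg)
        assert converged
        tt = build_transition_tensors(tensor)
        nxt = iterate_once(state, tt, jump, cfg)
        residual = (
            np.abs(nxt.va - state.va).sum()
            + np.abs(nxt.vh - state.vh).sum()
            + np.abs(nxt.ve - state.ve).sum()
        )
        assert residual < 10 * cfg.epsilon

    def test_matches_dense_run(self):
        rng = np.random.default_rng(11)
        n = 18
        T = random_relation_tensor(rng, n)
        jump = random_jump(rng, n)
        cfg = HeptConfig(epsilon=1e-9)
        state, conv, iters = run_hept(sparse_tensor_from_dense(T), jump, cfg)
        va, vh, ve, conv_d, iters_d = dense_run(T, jump.d, 0.3, 1e-9, 1000)
        assert conv == conv_d and iters == iters_d
        assert np.allclose(state.va, va, atol=1e-10)

    def test_max_iter_warning_flag(self, caplog):
        rng = np.random.default_rng(4)
        tensor = sparse_tensor_from_dense(random_relation_tensor(rng, 12))
        state, converged, iters = run_hept(
            tensor, random_jump(rng, 12), HeptConfig(epsilon=1e-16, max_iter=2)
        )
        assert not converged and iters == 2


class TestRankProteins:
    def test_descending(self):
        idx = ProteinIndex.from_ids(["P1", "P2", "P3"])
        state = ScoreState(va=np.array([0.5, 0.3, 0.2]), vh=np.zeros(3), ve=np.ones(1))
        assert [p for p, _ in rank_proteins(state, idx)] == ["P1", "P2", "P3"]

    def test_tie_breaks_lexicographic(self):
        idx = ProteinIndex.from_ids(["P2", "P1", "P3"])
        state = ScoreState(va=np.array([0.4, 0.4, 0.2]), vh=np.zeros(3), ve=np.ones(1))
        assert [p for p, _ in rank_proteins(state, idx)] == ["P1", "P2", "P3"]

    def test_all_equal_lexicographic(self):
        idx = ProteinIndex.from_ids(["B", "C", "A"])
        state = ScoreState(va=np.full(3, 1 / 3), vh=np.zeros(3), ve=np.ones(1))
        assert [p for p, _ in rank_proteins(state, idx)] == ["A", "B", "C"]


class TestPermutationEquivariance:
    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_va_permutes_with_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        T = random_relation_tensor(rng, n)
        d = rng.random(n) + 0.05
        d = d / d.sum()
        perm = rng.permutation(n)
        Tp = T[np.ix_(perm, perm)]
        dp = d[perm]
        cfg = HeptConfig(epsilon=1e-12)
        s1, _, _ = run_hept(sparse_tensor_from_dense(T), JumpVector(d=d, normalized=True), cfg)
        s2, _, _ = run_hept(sparse_tensor_from_dense(Tp), JumpVector(d=dp, normalized=True), cfg)
        assert np.allclose(s2.va, s1.va[perm], atol=1e-9)
        assert np.allclose(s2.vh, s1.vh[perm], atol=1e-9)


class TestHeptConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": -0.1}, {"alpha": 1.5}, {"epsilon": 0.0}, {"max_iter": 0}]
    )
    def test_rejects(self, kwargs):
        with pytest.raises(ValueError):
            HeptConfig(**kwargs)
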