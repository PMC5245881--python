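import numpy as np
import pytest
import scipy.sparse as sp

from procdl import (
    LearnConfig,
    SparseCodeMatrix,
    SparsifierSpec,
    init_dictionary,
    learn,
    objective,
    popularity_partition,
    sparse_code_batch,
)
from procdl.dictionary_learning import (
    _update_ilsdla,
    _update_ksvd,
    _update_rsvd,
)
from procdl.procrustes_update import build_cache
from procdl.synthetic_benchmark import generate_instance, match_atoms


class TestInit:
    def test_uses_all_columns_when_L_equals_m(self, rng):
        Y = rng.standard_normal((4, 6))
        D = init_dictionary(Y, 6, seed=0)
        normalized = Y / np.linalg.norm(Y, axis=0)
        # every atom is one of the normalized training columns
        for j in range(6):
            dists = np.linalg.norm(normalized - D.D[:, [j]], axis=0)
            assert dists.min() < 1e-12

    def test_atoms_unit_norm(self, rng):
        Y = rng.standard_normal((5, 30))
        D = init_dictionary(Y, 8, seed=3)
        np.testing.assert_allclose(np.linalg.norm(D.D, axis=0), 1.0, atol=1e-10)

    def test_seed_reproducibility(self, rng):
        Y = rng.standard_normal((5, 30))
        D1 = init_dictionary(Y, 8, seed=5)
        D2 = init_dictionary(Y, 8, seed=5)
        D3 = init_dictionary(Y, 8, seed=6)
        np.testing.assert_array_equal(D1.D, D2.D)
        assert not np.array_equal(D1.D, D3.D)

    def test_skips_zero_columns(self, rng):
        Y = rng.standard_normal((4, 20))
        Y[:, ::2] = 0.0  # half the columns unusable
        D = init_dictionary(Y, 10, seed=1)
        assert np.all(np.linalg.norm(D.D, axis=0) > 0.99)

    def test_too_few_columns_raises(self, rng):
        with pytest.raises(ValueError):
            init_dictionary(rng.standard_normal((4, 5)), 6, seed=0)


class TestPartition:
    def test_sort_then_chop(self):
        X = np.zeros((3, 6))
        X[0, :3] = 1.0  # usage 3
        X[2, :5] = 1.0  # usage 5; row 1 unused
        groups = popularity_partition(SparseCodeMatrix(X=X, k=3), s=2)
        assert [g.indices.tolist() for g in groups] == [[1, 0], [2]]

    def test_even_partition(self):
        X = sp.csc_array(np.ones((100, 120)) * (np.arange(120) < 100))
        groups = popularity_partition(X, s=10)
        assert len(groups) == 10
        assert all(g.s == 10 for g in groups)
        covered = np.sort(np.concatenate([g.indices for g in groups]))
        np.testing.assert_array_equal(covered, np.arange(100))

    def test_remainder_block(self, rng):
        X = sp.csc_array(rng.standard_normal((10, 15)))
        groups = popularity_partition(X, s=4)
        assert [g.s for g in groups] == [4, 4, 2]

    def test_ties_break_by_index(self):
        X = sp.csc_array(np.zeros((4, 5)))
        groups = popularity_partition(X, s=4)
        assert groups[0].indices.tolist() == [0, 1, 2, 3]


class TestRotationLearner:
    def test_recovers_atoms_on_easy_noiseless_instances(self):
        # configuration and threshold from pilot runs: the rotation learner
        # needs ample data per atom (L/m = 50 here) to recover reliably
        fractions = []
        for seed in range(5):
            inst = generate_instance(20, 40, 2000, 3, np.inf, seed)
            cfg = LearnConfig(m=40, k=3, s=5, T=60, seed=seed, algorithm="rsvd")
            res = learn(inst.Y, cfg)
            rep = match_atoms(inst.D_true, res.D)
            fractions.append(rep.recovered_count / 40)
        assert np.mean(fractions) >= 0.8

    def test_single_iteration_composes_expected_steps(self, rng):
        inst = generate_instance(10, 20, 80, 3, 20.0, 11)
        cfg = LearnConfig(m=20, k=3, s=5, T=1, seed=4, algorithm="rsvd")
        res = learn(inst.Y, cfg)
        # hand-composed: init -> sparse code -> cache -> partitioned rotations
        D = init_dictionary(inst.Y, 20, seed=4).D.copy()
        X = sparse_code_batch(inst.Y, D, SparsifierSpec(k=3))
        D, X = _update_rsvd(inst.Y.Y, D, X, cfg)
        used = X.row_usage() > 0
        np.testing.assert_allclose(res.D.D[:, used], D[:, used], atol=1e-12)

    def test_update_sweep_never_increases_objective(self, rng):
        inst = generate_instance(12, 24, 100, 3, 15.0, 12)
        D = init_dictionary(inst.Y, 24, seed=0).D.copy()
        cfg = LearnConfig(m=24, k=3, s=6, T=1, seed=0, algorithm="rsvd")
        for _ in range(3):
            X = sparse_code_batch(inst.Y, D, SparsifierSpec(k=3))
            before = objective(inst.Y, D, X)
            D, X = _update_rsvd(inst.Y.Y, D, X, cfg)
            assert objective(inst.Y, D, X) <= before + 1e-8

    def test_group_size_one_is_valid(self):
        inst = generate_instance(8, 16, 60, 2, 20.0, 13)
        cfg = LearnConfig(m=16, k=2, s=1, T=3, seed=0, algorithm="rsvd")
        res = learn(inst.Y, cfg)
        np.testing.assert_allclose(
            np.linalg.norm(res.D.D, axis=0), 1.0, atol=1e-8
        )


class TestKsvd:
    def test_single_used_atom_becomes_leading_singular_vector(self, rng):
        # one atom explains every signal; its update is the rank-1 SVD of
        # the full restored residual, here equal to Y itself
        n, m = 6, 7
        D = rng.standard_normal((n, m))
        D /= np.linalg.norm(D, axis=0)
        coef = rng.standard_normal(30) + 2.0
        Y = np.outer(D[:, 2], coef)
        Xd = np.zeros((m, 30))
        Xd[2] = coef
        X = SparseCodeMatrix(X=Xd, k=1)
        cfg = LearnConfig(m=m, k=1, T=1, seed=0, algorithm="ksvd")
        Dnew, Xnew = _update_ksvd(Y, D.copy(), X, cfg)
        U, S, Vt = np.linalg.svd(Y, full_matrices=False)
        angle = abs(float(Dnew[:, 2] @ U[:, 0]))
        assert angle == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            np.abs(Xnew.toarray()[2]), np.abs(S[0] * Vt[0]), atol=1e-8
        )

    def test_update_never_increases_objective(self, rng):
        inst = generate_instance(10, 20, 80, 3, 15.0, 14)
        D = init_dictionary(inst.Y, 20, seed=0).D.copy()
        X = sparse_code_batch(inst.Y, D, SparsifierSpec(k=3))
        before = objective(inst.Y, D, X)
        cfg = LearnConfig(m=20, k=3, T=1, seed=0, algorithm="ksvd")
        Dnew, Xnew = _update_ksvd(inst.Y.Y, D, X, cfg)
        assert objective(inst.Y, Dnew, Xnew) <= before + 1e-8

    def test_compiled_sweep_matches_numpy_sweep(self):
        from procdl.dictionary_learning import _update_ksvd_numpy

        inst = generate_instance(12, 24, 120, 3, 20.0, 18)
        D = init_dictionary(inst.Y, 24, seed=1).D
        X = sparse_code_batch(inst.Y, D, SparsifierSpec(k=3))
        cfg = LearnConfig(m=24, k=3, T=1, seed=1, algorithm="ksvd")
        D1, X1 = _update_ksvd(inst.Y.Y, D.copy(), X, cfg)
        D2, X2 = _update_ksvd_numpy(inst.Y.Y, D.copy(), X, cfg)
        # each atom's singular pair (d_j, x_j) is defined up to a joint sign
        signs = np.sign(np.einsum("ij,ij->j", D1, D2))
        np.testing.assert_allclose(D1, D2 * signs, atol=1e-8)
        np.testing.assert_allclose(X1.toarray(), X2.toarray() * signs[:, None],
                                   atol=1e-8)


class TestIlsdla:
    def test_identity_code_gives_normalized_signals(self, rng):
        Y = rng.standard_normal((4, 8))
        D0 = init_dictionary(Y, 8, seed=0).D.copy()
        X = SparseCodeMatrix(X=sp.eye_array(8, format="csc"), k=1)
        cfg = LearnConfig(m=8, k=1, T=1, seed=0, algorithm="ilsdla")
        Dnew, _ = _update_ilsdla(Y, D0, X, cfg)
        np.testing.assert_allclose(Dnew, Y / np.linalg.norm(Y, axis=0),
                                   atol=1e-10)

    def test_least_squares_update_dominates_perturbations(self, rng):
        # before renormalization, D = Y X^T (X X^T)^{-1} is the global
        # minimizer of ||Y - D X||_F^2
        Y = rng.standard_normal((6, 40))
        Xd = rng.standard_normal((10, 40))
        X = sp.csc_array(Xd)
        Dstar = np.linalg.solve(Xd @ Xd.T, Xd @ Y.T).T
        base = np.sum((Y - Dstar @ Xd) ** 2)
        for _ in range(500):
            P = rng.standard_normal(Dstar.shape) * 0.1
            assert base <= np.sum((Y - (Dstar + P) @ Xd) ** 2) + 1e-10


class TestLearnerInvariants:
    @pytest.mark.parametrize("algo", ["rsvd", "ksvd", "ilsdla"])
    def test_unit_norm_atoms_every_iteration(self, algo):
        inst = generate_instance(8, 16, 60, 2, 20.0, 15)
        for T in (1, 3):
            cfg = LearnConfig(m=16, k=2, s=4, T=T, seed=2, algorithm=algo)
            res = learn(inst.Y, cfg)
            np.testing.assert_allclose(
                np.linalg.norm(res.D.D, axis=0), 1.0, atol=1e-8
            )

    @pytest.mark.parametrize("algo", ["rsvd", "ksvd", "ilsdla"])
    def test_same_seed_bitwise_identical_traces(self, algo):
        inst = generate_instance(8, 16, 60, 2, 20.0, 16)
        cfg = LearnConfig(m=16, k=2, s=4, T=4, seed=9, algorithm=algo)
        r1 = learn(inst.Y, cfg)
        r2 = learn(inst.Y, cfg)
        np.testing.assert_array_equal(r1.error_trace, r2.error_trace)
        np.testing.assert_array_equal(r1.D.D, r2.D.D)

    def test_trace_length_matches_iterations(self):
        inst = generate_instance(8, 16, 60, 2, 20.0, 17)
        cfg = LearnConfig(m=16, k=2, s=4, T=6, seed=0, algorithm="rsvd")
        res = learn(inst.Y, cfg)
        assert len(res.error_trace) == 6
        assert len(res.objective_trace) == 6

    def test_dead_atoms_are_replaced(self, rng):
        # all signals use a single direction; most atoms go unused and must
        # be rescued to unit-norm training columns
        Y = np.outer(rng.standard_normal(6), rng.standard_normal(40))
        Y += 0.01 * rng.standard_normal((6, 40))
        cfg = LearnConfig(m=10, k=1, s=2, T=2, seed=0, algorithm="rsvd")
        res = learn(Y, cfg)
        np.testing.assert_allclose(
            np.linalg.norm(res.D.D, axis=0), 1.0, atol=1e-8
        )
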