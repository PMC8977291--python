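import itertools

import numpy as np
import pytest
import scipy.sparse as sps
from sklearn.linear_model import Lasso

from bregmri import sparse_model as sm


# --------------------------------------------------------------------------
# patch extraction / reassembly
# --------------------------------------------------------------------------

class TestExtractPatches:
    def test_constant_image_constant_columns(self):
        ps = sm.extract_patches(np.full((12, 12), 7.0), 4, 1, periodic=True)
        assert np.all(ps.patches == 7.0)

    def test_periodic_stride1_count(self):
        ps = sm.extract_patches(np.arange(16.0).reshape(4, 4), 2, 1, True)
        assert ps.n_patches == 16
        assert ps.patch_dim == 4

    def test_round_trip_identity(self, rng):
        u = rng.random((8, 8))
        ps = sm.extract_patches(u, 3, 1, periodic=True)
        np.testing.assert_allclose(sm.reassemble_patches(ps), u, atol=1e-12)

    def test_round_trip_nonperiodic(self, rng):
        u = rng.random((10, 9))
        ps = sm.extract_patches(u, 3, 1, periodic=False)
        np.testing.assert_allclose(sm.reassemble_patches(ps), u, atol=1e-12)

    def test_overlap_counts_p_squared(self):
        ps = sm.extract_patches(np.zeros((8, 8)), 3, 1, periodic=True)
        np.testing.assert_array_equal(sm.overlap_counts(ps), 9.0)

    def test_wrap_content(self):
        u = np.arange(16.0).reshape(4, 4)
        ps = sm.extract_patches(u, 2, 1, periodic=True)
        # patch at raster position (3, 3) wraps to rows [3,0] x cols [3,0]
        expected = np.array([u[3, 3], u[3, 0], u[0, 3], u[0, 0]])
        np.testing.assert_array_equal(ps.patches[:, 15], expected)

    def test_stride_warning_and_bad_sizes(self):
        with pytest.warns(UserWarning):
            sm.extract_patches(np.zeros((8, 8)), 2, 3)
        with pytest.raises(ValueError):
            sm.extract_patches(np.zeros((8, 8)), 0, 1)
        with pytest.raises(ValueError):
            sm.extract_patches(np.zeros((4, 4)), 8, 1)


class TestReassemblePatches:
    def test_zero_patches_zero_image(self):
        ps = sm.extract_patches(np.ones((6, 6)), 2, 1, True)
        out = sm.reassemble_patches(ps, np.zeros_like(ps.patches))
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch_rejected(self):
        ps = sm.extract_patches(np.ones((6, 6)), 2, 1, True)
        with pytest.raises(ValueError):
            sm.reassemble_patches(ps, np.zeros((3, 3)))


# --------------------------------------------------------------------------
# dictionary
# --------------------------------------------------------------------------

class TestInitDictionary:
    def test_unit_norm_columns(self):
        D = sm.init_dictionary(64, 256)
        np.testing.assert_allclose(np.linalg.norm(D.atoms, axis=0), 1.0,
                                   atol=1e-12)

    def test_dct_deterministic(self):
        a = sm.init_dictionary(64, 256)
        b = sm.init_dictionary(64, 256)
        np.testing.assert_array_equal(a.atoms, b.atoms)

    def test_first_dct_atom_is_dc(self):
        # closed form: the DC atom of a 64-dim patch is 1/8 everywhere
        D = sm.init_dictionary(64, 256)
        np.testing.assert_allclose(D.atoms[:, 0], 1.0 / 8.0, atol=1e-12)

    def test_undercomplete_warns(self):
        with pytest.warns(UserWarning):
            sm.init_dictionary(64, 32)

    def test_random_init_seeded(self):
        a = sm.init_dictionary(16, 32, method="random", seed=5)
        b = sm.init_dictionary(16, 32, method="random", seed=5)
        np.testing.assert_array_equal(a.atoms, b.atoms)


class TestUpdateDictionary:
    def make_instance(self, rng, n=16, J=32, m=40):
        D = sm.init_dictionary(n, J, method="random", seed=0)
        X = rng.standard_normal((n, m))
        ps = sm.PatchSet(patches=X, patch_size=4, stride=1, periodic=True,
                         source_shape=(8, 8))
        codes = sm.CodeMatrix(codes=rng.standard_normal((J, m)) *
                              (rng.random((J, m)) < 0.2))
        return D, ps, codes

    def test_residual_nonincreasing(self, rng):
        D, ps, codes = self.make_instance(rng)
        before = np.linalg.norm(ps.patches - D.atoms @ codes.codes)
        D2 = sm.update_dictionary(D, ps, codes, xi=1.0)
        after = np.linalg.norm(ps.patches - D2.atoms @ codes.codes)
        assert after <= before * (1 + 1e-12)

    def test_columns_unit_norm_after_update(self, rng):
        D, ps, codes = self.make_instance(rng)
        D2 = sm.update_dictionary(D, ps, codes, xi=1.0)
        np.testing.assert_allclose(np.linalg.norm(D2.atoms, axis=0), 1.0,
                                   atol=1e-12)

    def test_zero_codes_leave_normalized_dict_unchanged(self, rng):
        D, ps, codes = self.make_instance(rng)
        zero = sm.CodeMatrix(codes=np.zeros_like(codes.codes))
        D2 = sm.update_dictionary(D, ps, zero, xi=1.0)
        np.testing.assert_allclose(D2.atoms, D.atoms, atol=1e-12)

    def test_nonpositive_xi_rejected(self, rng):
        D, ps, codes = self.make_instance(rng)
        with pytest.raises(ValueError):
            sm.update_dictionary(D, ps, codes, xi=0.0)


# --------------------------------------------------------------------------
# OMP
# --------------------------------------------------------------------------

class TestSparseCodeOmp:
    def test_single_atom_recovery(self, rng):
        D = sm.init_dictionary(16, 24, method="random", seed=2)
        x = 3.7 * D.atoms[:, 3]
        ps = sm.PatchSet(patches=x[:, None], patch_size=4, stride=1,
                         periodic=True, source_shape=(4, 4))
        codes = sm.sparse_code_omp(ps, D, sparsity_T=1).codes[:, 0]
        assert codes[3] == pytest.approx(3.7, rel=1e-10)
        assert np.count_nonzero(codes) == 1

    def test_zero_patch_zero_code(self):
        D = sm.init_dictionary(16, 24, method="random", seed=2)
        ps = sm.PatchSet(patches=np.zeros((16, 3)), patch_size=4, stride=1,
                         periodic=True, source_shape=(4, 4))
        assert np.all(sm.sparse_code_omp(ps, D, sparsity_T=2).codes == 0)

    def test_non_finite_rejected(self):
        D = sm.init_dictionary(16, 24, method="random", seed=2)
        ps = sm.PatchSet(patches=np.full((16, 1), np.inf), patch_size=4,
                         stride=1, periodic=True, source_shape=(4, 4))
        with pytest.raises(ValueError):
            sm.sparse_code_omp(ps, D)

    def test_vs_exhaustive_support_oracle(self, rng):
        # oracle: best least-squares fit over all C(5,2) supports
        n, J, T = 16, 5, 2
        equal = 0
        for trial in range(100):
            r = np.random.default_rng(trial)
            D = sm.Dictionary(atoms=(lambda A: A / np.linalg.norm(A, axis=0))(
                r.standard_normal((n, J))))
            x = r.standard_normal(n)
            ps = sm.PatchSet(patches=x[:, None], patch_size=4, stride=1,
                             periodic=True, source_shape=(4, 4))
            code = sm.sparse_code_omp(ps, D, sparsity_T=T).codes[:, 0]
            omp_resid = np.linalg.norm(x - D.atoms @ code)
            best = min(
                np.linalg.norm(
                    x - D.atoms[:, list(s)] @ np.linalg.lstsq(
                        D.atoms[:, list(s)], x, rcond=None)[0])
                for s in itertools.combinations(range(J), T))
            assert omp_resid >= best - 1e-10
            if omp_resid <= best + 1e-8:
                equal += 1
        assert equal >= 90


# --------------------------------------------------------------------------
# similarity graph / Laplacian
# --------------------------------------------------------------------------

def _patchset_from_matrix(X):
    n = X.shape[0]
    p = int(round(np.sqrt(n)))
    return sm.PatchSet(patches=X, patch_size=p, stride=1, periodic=True,
                       source_shape=(p, X.shape[1]))


class TestSimilarityGraph:
    def test_identical_patches_weight_one(self, rng):
        X = rng.standard_normal((4, 6))
        X[:, 1] = X[:, 0]  # duplicate pair
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=2)
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert g.weights[1, 0] == pytest.approx(1.0)

    def test_laplacian_zero_row_sums(self, rng):
        X = rng.standard_normal((9, 30))
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=4)
        np.testing.assert_allclose(
            np.asarray(g.laplacian.sum(axis=1)).ravel(), 0.0, atol=1e-12)

    def test_laplacian_psd(self, rng):
        X = rng.standard_normal((9, 40))
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=5)
        eigs = np.linalg.eigvalsh(g.laplacian.toarray())
        assert eigs.min() >= -1e-10

    def test_symmetry_and_zero_diagonal(self, rng):
        X = rng.standard_normal((4, 25))
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=3)
        W = g.weights.toarray()
        np.testing.assert_allclose(W, W.T, atol=1e-14)
        np.testing.assert_array_equal(np.diag(W), 0.0)

    def test_bad_parameters_rejected(self, rng):
        X = rng.standard_normal((4, 10))
        with pytest.raises(ValueError):
            sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=2,
                                      kernel_sigma=0.0)
        with pytest.raises(ValueError):
            sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=10)


class TestLaplacianEnergy:
    def test_identical_columns_zero(self, rng):
        X = rng.standard_normal((4, 12))
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=3)
        codes = np.tile(rng.standard_normal((5, 1)), (1, 12))
        assert sm.laplacian_energy(codes, g) == pytest.approx(0.0, abs=1e-10)

    def test_two_node_hand_value(self):
        # W12 = 1, a1 = (1,0), a2 = (0,0) -> 1/2 * 2 * 1 * ||a1-a2||^2 = 1
        W = sps.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        L = sps.diags(np.asarray(W.sum(axis=1)).ravel()) - W
        g = sm.SimilarityGraph(weights=W, laplacian=L.tocsr())
        codes = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert sm.laplacian_energy(codes, g) == pytest.approx(1.0)

    def test_trace_equals_double_sum_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((4, 10))
            g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=3)
            codes = rng.standard_normal((6, 10))
            W = g.weights.toarray()
            double_sum = 0.5 * sum(
                W[i, j] * np.sum((codes[:, i] - codes[:, j]) ** 2)
                for i in range(10) for j in range(10))
            assert sm.laplacian_energy(codes, g) == pytest.approx(
                double_sum, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        X = rng.standard_normal((4, 10))
        g = sm.build_similarity_graph(_patchset_from_matrix(X), k_neighbors=3)
        with pytest.raises(ValueError):
            sm.laplacian_energy(np.zeros((6, 7)), g)


# --------------------------------------------------------------------------
# split-Bregman coder
# --------------------------------------------------------------------------

class TestSparseCodeBregman:
    def test_zero_patches_zero_codes(self):
        D = sm.init_dictionary(16, 32, method="random", seed=0)
        ps = _patchset_from_matrix(np.zeros((16, 5)))
        codes, aux = sm.sparse_code_bregman(ps, D, lam=1.0, mu_graph=0.0)
        assert np.all(codes.codes == 0)
        assert np.all(aux.z == 0)

    def test_large_lam_drives_exact_fit(self, rng):
        # lam -> inf: z -> 0 and D Gamma -> x (least-squares-exact fit here
        # since the dictionary is overcomplete)
        D = sm.init_dictionary(16, 32, method="random", seed=1)
        x = rng.standard_normal(16)
        ps = _patchset_from_matrix(x[:, None])
        codes, aux = sm.sparse_code_bregman(ps, D, lam=1e8, beta=1e4,
                                            mu_graph=0.0, n_inner=100,
                                            n_ista=30)
        assert np.linalg.norm(aux.z) < 1e-4
        assert np.linalg.norm(D.atoms @ codes.codes[:, 0] - x) < 1e-3

    def test_matches_lasso_oracle_single_patch(self, rng):
        # independent coordinate-descent LASSO oracle (sklearn);
        # unique solution via an injective (tall) dictionary
        n, J = 8, 6
        A = rng.standard_normal((n, J))
        D = sm.Dictionary(atoms=A / np.linalg.norm(A, axis=0))
        x = rng.standard_normal(n) * 3
        lam = 2.0
        ps = _patchset_from_matrix(x[:, None])
        codes, _ = sm.sparse_code_bregman(ps, D, lam=lam, mu_graph=0.0,
                                          n_inner=2000, n_ista=10)
        oracle = Lasso(alpha=1.0 / (lam * n), fit_intercept=False,
                       tol=1e-14, max_iter=200000).fit(D.atoms, x)
        np.testing.assert_allclose(codes.codes[:, 0], oracle.coef_, atol=1e-6)

    def test_objective_monotone_nonincreasing(self, rng):
        D = sm.init_dictionary(16, 32, method="random", seed=3)
        X = rng.standard_normal((16, 20)) * 2
        ps = _patchset_from_matrix(X)
        g = sm.build_similarity_graph(ps, k_neighbors=4)
        _, aux = sm.sparse_code_bregman(ps, D, graph=g, lam=0.5, mu_graph=0.05,
                                        beta=1.0, n_inner=30)
        hist = np.array(aux.objective_history)
        assert np.all(np.diff(hist) <= np.abs(hist[:-1]) * 1e-6 + 1e-12)

    def test_nonpositive_beta_rejected(self, rng):
        D = sm.init_dictionary(16, 32, method="random", seed=0)
        ps = _patchset_from_matrix(rng.standard_normal((16, 4)))
        with pytest.raises(ValueError):
            sm.sparse_code_bregman(ps, D, beta=0.0)
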