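"""Kernels and KRR: exact scalar values, contracts, and a dense-algebra oracle."""

import numpy as np
import pytest

from nmrkrr.krr import (
    KernelParams, assemble_targets, fit_krr_model, hyperparam_search,
    kernel, kernel_matrix, krr_fit, krr_predict, median_heuristic_sigma, pair_kernel,
)
from nmrkrr.representations import AtomicRep, PairRep, RepParams, represent_dataset
from nmrkrr.synthetic import OracleParams, gen_structures, label_dataset

from conftest import only_param


def vec_rep(values, element="C", sid="s", idx=0):
    """An AtomicRep with an arbitrary vector (coulomb family sized to fit)."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    p = RepParams(family="coulomb", max_atoms=len(values))
    return AtomicRep(sid, idx, element, values, p)


class TestScalarKernel:
    def test_self_similarity_exactly_one(self):
        x = vec_rep([1.3, -2.0, 0.7])
        for kind in ("gaussian", "laplacian"):
            assert kernel(x, x, KernelParams(kind, 2.0)) == 1.0

    def test_laplacian_hand_value(self):
        # |0-3|/sigma = 1 → exp(−1)
        x, y = vec_rep([0.0]), vec_rep([3.0])
        k = kernel(x, y, KernelParams("laplacian", 3.0))
        assert k == pytest.approx(np.exp(-1), abs=1e-6)
        assert k == pytest.approx(0.367879, abs=1e-6)

    def test_gaussian_hand_value(self):
        # ‖x−y‖² = 4, 2σ² = 8 → exp(−0.5)
        x, y = vec_rep([0.0, 0.0]), vec_rep([2.0, 0.0])
        assert kernel(x, y, KernelParams("gaussian", 2.0)) == pytest.approx(np.exp(-0.5))

    def test_huge_sigma_limit(self):
        x, y = vec_rep([0.0, 1.0]), vec_rep([5.0, -3.0])
        for kind in ("gaussian", "laplacian"):
            assert kernel(x, y, KernelParams(kind, 1e12)) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel(vec_rep([0.0]), vec_rep([0.0, 1.0]), KernelParams("laplacian", 1.0))

    def test_symmetry_and_range_random_vectors(self):
        rng = np.random.default_rng(7)
        kp = KernelParams("gaussian", 1.7)
        for _ in range(20):
            x, y = vec_rep(rng.normal(size=4)), vec_rep(rng.normal(size=4))
            kxy, kyx = kernel(x, y, kp), kernel(y, x, kp)
            assert kxy == pytest.approx(kyx, abs=1e-15)
            assert 0.0 < kxy <= 1.0


class TestPairKernel:
    def test_self_similarity(self):
        a = PairRep(vec_rep([1.0, 2.0], "C"), vec_rep([0.5, 0.1], "H"))
        assert pair_kernel(a, a, KernelParams("laplacian", 1.0)) == 1.0

    def test_factorizes_into_atomic_kernels(self):
        # Each factor is ln2 away under laplacian σ=1 → 0.5 each → product 0.25
        kp = KernelParams("laplacian", 1.0)
        a = PairRep(vec_rep([0.0], "C"), vec_rep([0.0], "H"))
        b = PairRep(vec_rep([np.log(2.0)], "C"), vec_rep([np.log(2.0)], "H"))
        kc = kernel(a.carbon, b.carbon, kp)
        kh = kernel(a.hydrogen, b.hydrogen, kp)
        assert kc == pytest.approx(0.5, abs=1e-12)
        assert pair_kernel(a, b, kp) == pytest.approx(kc * kh, abs=1e-12)
        assert pair_kernel(a, b, kp) == pytest.approx(0.25, abs=1e-12)

    def test_role_swap_rejected_by_ordering_contract(self):
        with pytest.raises(ValueError, match="ordered"):
            PairRep(vec_rep([0.0], "H"), vec_rep([0.0], "C"))

    def test_mixed_atomic_and_pair_rows_rejected(self):
        a = PairRep(vec_rep([0.0], "C"), vec_rep([0.0], "H"))
        with pytest.raises(TypeError, match="mix"):
            kernel_matrix([a], [vec_rep([0.0])], KernelParams("laplacian", 1.0))


class TestKernelMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        reps = [vec_rep(rng.normal(size=3), sid=f"s{i}") for i in range(3)]
        K = kernel_matrix(reps, reps, KernelParams("gaussian", 1.0))
        np.testing.assert_allclose(K, K.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_entries_match_scalar_kernel_bruteforce(self):
        rng = np.random.default_rng(5)
        kp = KernelParams("laplacian", 0.8)
        rows = [vec_rep(rng.normal(size=4)) for _ in range(4)]
        cols = [vec_rep(rng.normal(size=4)) for _ in range(3)]
        K = kernel_matrix(rows, cols, kp)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                assert K[i, j] == pytest.approx(kernel(r, c, kp), abs=1e-12)

    def test_empty_rows(self):
        assert kernel_matrix([], [vec_rep([0.0])], KernelParams("laplacian", 1.0)).shape == (0, 1)

    def test_positive_definite_with_jitter(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            reps = [vec_rep(rng.normal(size=3)) for _ in range(6)]
            K = kernel_matrix(reps, reps, KernelParams("gaussian", 1.0))
            w = np.linalg.eigvalsh(K + 1e-10 * np.eye(6))
            assert w.min() > 0


class TestKrrFit:
    def test_one_by_one_identity(self):
        assert krr_fit(np.array([[1.0]]), np.array([5.0]), 0.0) == pytest.approx([5.0])

    def test_orthogonal_environments(self):
        alpha = krr_fit(np.eye(2), np.array([2.0, -3.0]), 0.0)
        np.testing.assert_allclose(alpha, [2.0, -3.0])

    def test_ridge_shrinks(self):
        # (1 + 1)·α = 4 → α = 2
        assert krr_fit(np.array([[1.0]]), np.array([4.0]), 1.0) == pytest.approx([2.0])

    def test_not_positive_definite_advises_larger_lam(self):
        K = np.array([[1.0, 1.0], [1.0, 1.0]])  # singular
        with pytest.raises(ValueError, match="increase lam"):
            krr_fit(K, np.array([1.0, 2.0]), 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="match"):
            krr_fit(np.eye(2), np.array([1.0]), 0.0)


@pytest.fixture(scope="module")
def small_fit():
    """6 labelled synthetic structures, 13C shifts, cached representations."""
    d = only_param(label_dataset(gen_structures(6, seed=31), OracleParams(seed=31)),
                   "shift_13C")
    rp = RepParams()
    cache = represent_dataset(d, rp)
    reps, y, _ = assemble_targets(d, "shift_13C", cache)
    return d, rp, reps, y


class TestKrrModel:
    def test_interpolation_at_lam_zero(self, small_fit):
        _, rp, reps, y = small_fit
        kp = KernelParams("laplacian", median_heuristic_sigma(reps, "laplacian"))
        m = fit_krr_model("shift_13C", reps, y, kp, lam=0.0, rep_params=rp)
        pred = krr_predict(m, reps)
        np.testing.assert_allclose(pred, y, rtol=1e-6)

    def test_single_training_point_one_term_sum(self, small_fit):
        _, rp, reps, y = small_fit
        kp = KernelParams("laplacian", 5.0)
        m = fit_krr_model("shift_13C", reps[:1], y[:1], kp, lam=0.0, rep_params=rp)
        target = reps[3]
        k = kernel(target, reps[0], kp)
        # centering: alpha fits the residual about the (single-point) mean
        assert krr_predict(m, [target])[0] == pytest.approx(
            m.y_mean + m.alpha[0] * k, rel=1e-12)

    def test_matches_dense_inversion_oracle(self, small_fit):
        """Cholesky path vs naive full matrix inversion on 20 random points."""
        _, rp, reps, y = small_fit
        rng = np.random.default_rng(17)
        idx = rng.choice(len(reps), size=min(20, len(reps)), replace=False)
        reps20 = [reps[i] for i in idx]
        y20 = y[idx]
        kp = KernelParams("gaussian", 8.0)
        lam = 1e-6
        m = fit_krr_model("shift_13C", reps20, y20, kp, lam=lam, rep_params=rp)
        K = kernel_matrix(reps20, reps20, kp)
        alpha_naive = np.linalg.inv(K + lam * np.eye(len(y20))) @ (y20 - y20.mean())
        pred_naive = kernel_matrix(reps20, reps20, kp) @ alpha_naive + y20.mean()
        np.testing.assert_allclose(krr_predict(m, reps20), pred_naive, atol=1e-8)

    def test_matches_sklearn_kernel_ridge(self, small_fit):
        """Independent cross-check against scikit-learn with a precomputed kernel."""
        sklearn = pytest.importorskip("sklearn.kernel_ridge")
        _, rp, reps, y = small_fit
        kp = KernelParams("gaussian", 8.0)
        lam = 1e-4
        m = fit_krr_model("shift_13C", reps, y, kp, lam=lam, rep_params=rp)
        K = kernel_matrix(reps, reps, kp)
        kr = sklearn.KernelRidge(alpha=lam, kernel="precomputed")
        kr.fit(K, y - y.mean())
        pred_sk = kr.predict(K) + y.mean()
        np.testing.assert_allclose(krr_predict(m, reps), pred_sk, atol=1e-8)

    def test_monotone_regularization(self, small_fit):
        _, rp, reps, y = small_fit
        kp = KernelParams("laplacian", median_heuristic_sigma(reps, "laplacian"))
        fit_errors = []
        for lam in (1e-8, 1e-4, 1e-2, 1.0, 100.0):
            m = fit_krr_model("shift_13C", reps, y, kp, lam=lam, rep_params=rp)
            fit_errors.append(np.abs(krr_predict(m, reps) - y).mean())
        assert np.all(np.diff(fit_errors) >= -1e-10)


class TestHyperparamSearch:
    def test_single_point_grid_returned(self, small_fit):
        d, rp, _, _ = small_fit
        grid = [(KernelParams("laplacian", 50.0), 1e-6)]
        best, table = hyperparam_search(d, "shift_13C", grid, n_folds=3, seed=0, rep_params=rp)
        assert best == grid[0]
        assert len(table) == 3

    def test_absurd_sigma_loses_to_sane(self, small_fit):
        d, rp, reps, _ = small_fit
        sane = (KernelParams("laplacian", median_heuristic_sigma(reps, "laplacian")), 1e-6)
        absurd = (KernelParams("laplacian", 1e-12), 1e-6)
        best, _ = hyperparam_search(d, "shift_13C", [absurd, sane], n_folds=3,
                                    seed=1, rep_params=rp)
        assert best == sane

    def test_deterministic_given_seed(self, small_fit):
        d, rp, _, _ = small_fit
        grid = [(KernelParams("laplacian", 30.0), 1e-6),
                (KernelParams("laplacian", 90.0), 1e-6)]
        _, t1 = hyperparam_search(d, "shift_13C", grid, n_folds=3, seed=5, rep_params=rp)
        _, t2 = hyperparam_search(d, "shift_13C", grid, n_folds=3, seed=5, rep_params=rp)
        assert t1.equals(t2)

    def test_too_few_structures(self, small_fit):
        d, rp, _, _ = small_fit
        with pytest.raises(ValueError, match="fewer"):
            hyperparam_search(d, "shift_13C", [(KernelParams("laplacian", 1.0), 0.0)],
                              n_folds=99, seed=0, rep_params=rp)
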