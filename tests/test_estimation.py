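import numpy as np
import pytest
import scipy.sparse as sp

from atacsim import (
    estimate_library_model,
    estimate_nonzero_proportions,
    estimate_profile,
    fit_bin_mean_polynomial,
    normalize_matrix,
    read_profile,
    write_profile,
)
from atacsim.estimation import EstimationError
from atacsim.matrix_io import BinByCellMatrix
from conftest import matrix_from_dense


def draw_mixture(n, mu1, s1, mu2, s2, w, seed):
    rng = np.random.default_rng(seed)
    first = rng.random(n) < w
    logl = np.where(first, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
    return 2.0**logl


class TestLibrarySizeModel:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_bimodal_recovery(self, seed):
        lib = draw_mixture(10_000, 11, 0.5, 13.5, 0.6, 0.4, seed)
        m = estimate_library_model(lib)
        assert abs(m.mu1 - 11) <= 0.1 and abs(m.mu2 - 13.5) <= 0.1
        assert abs(m.sigma1 - 0.5) <= 0.05 and abs(m.sigma2 - 0.6) <= 0.05
        assert abs(m.w - 0.4) <= 0.03

    def test_constant_vector(self):
        m = estimate_library_model(np.full(50, 2.0**12))
        assert m.mu1 == pytest.approx(12.0) and m.mu2 == pytest.approx(12.0)
        assert m.sigma1 > 0  # variance floor

    def test_single_mode(self):
        rng = np.random.default_rng(0)
        lib = 2.0 ** rng.normal(12, 0.5, 10_000)
        m = estimate_library_model(lib, n_components=1)
        assert m.w == 1.0
        assert abs(m.mu1 - 12) <= 0.05
        assert m.mu2 == m.mu1 and m.sigma2 == m.sigma1

    def test_too_few_cells(self):
        with pytest.raises(EstimationError):
            estimate_library_model(np.full(5, 100.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(EstimationError):
            estimate_library_model(np.array([0.0] + [100.0] * 20))

    def test_components_ordered(self):
        lib = draw_mixture(5000, 14, 0.4, 10, 0.4, 0.3, 7)  # modes given reversed
        m = estimate_library_model(lib)
        assert m.mu1 <= m.mu2


class TestNonzeroProportions:
    def test_hand_count(self):
        m = matrix_from_dense([[0, 2], [1, 0], [0, 0]])
        assert list(estimate_nonzero_proportions(m)) == [0.5, 0.5, 0.0]

    def test_full_row(self):
        m = matrix_from_dense([[1, 3], [0, 0]])
        assert estimate_nonzero_proportions(m)[0] == 1.0

    def test_matches_brute_force(self, random_matrix):
        dense = random_matrix.counts.toarray()
        assert np.array_equal(
            estimate_nonzero_proportions(random_matrix),
            (dense > 0).mean(axis=1),
        )


class TestNormalizeMatrix:
    def test_identity_when_lib_equals_median(self):
        m = matrix_from_dense([[2], [0]])
        assert np.array_equal(normalize_matrix(m).toarray(), [[2], [0]])

    def test_scaling_arithmetic(self):
        m = matrix_from_dense([[2, 4]])
        out = normalize_matrix(m).toarray()
        # libs (2, 4), median 3: columns scaled by 1.5 and 0.75
        assert np.allclose(out, [[3.0, 3.0]])

    def test_column_sums_equal_median(self, random_matrix):
        lib = random_matrix.library_sizes()
        keep = lib > 0
        m = BinByCellMatrix(
            random_matrix.counts[:, keep],
            random_matrix.bins,
            [b for b, k in zip(random_matrix.barcodes, keep) if k],
        )
        out = normalize_matrix(m)
        sums = np.asarray(out.sum(axis=0)).ravel()
        assert np.allclose(sums, np.median(m.library_sizes()))

    def test_zero_library_size_is_error(self):
        m = matrix_from_dense([[1, 0], [2, 0]])
        with pytest.raises(EstimationError):
            normalize_matrix(m)


class TestBinMeanPolynomial:
    def test_noiseless_exact(self):
        p = np.linspace(0, 1, 11)
        y = 0.1 + 2 * p + 3 * p**2
        fit = fit_bin_mean_polynomial(p, y)
        assert np.allclose(list(fit), [0.1, 2, 3], atol=1e-10)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(5)
        p = rng.random(5000)
        y = 0.1 + 2 * p + 3 * p**2 + rng.normal(0, 0.01, 5000)
        fit = fit_bin_mean_polynomial(p, y)
        assert np.allclose(list(fit), [0.1, 2, 3], atol=0.02)

    def test_rank_deficient(self):
        with pytest.raises(EstimationError):
            fit_bin_mean_polynomial(np.full(10, 0.4), np.arange(10.0))


class TestEstimateProfile:
    def test_self_consistency(self, small_fixture):
        matrix, truth = small_fixture
        est = estimate_profile(matrix, seed=0)
        r = np.corrcoef(truth.bin_model.p, est.bin_model.p)[0, 1]
        assert r >= 0.95
        # mode separation and weight of the generating mixture survive
        # Bernoulli-Poisson thinning (absolute location shifts down)
        sep_true = truth.library_model.mu2 - truth.library_model.mu1
        sep_est = est.library_model.mu2 - est.library_model.mu1
        assert abs(sep_est - sep_true) <= 0.5
        assert abs(est.library_model.w - truth.library_model.w) <= 0.1

    def test_zero_cell_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(30, 20))
        dense[:, 7] = 0
        m = matrix_from_dense(dense)
        with pytest.warns(UserWarning, match="zero library size"):
            prof = estimate_profile(m, seed=0)
        assert prof.n_cells_source == 19

    def test_unimodal_hint_returns_weight_one(self, small_fixture):
        matrix, _ = small_fixture
        prof = estimate_profile(matrix, platform_hint="unimodal", seed=0)
        assert prof.library_model.w == 1.0

    def test_auto_picks_unimodal_on_single_mode_data(self):
        rng = np.random.default_rng(3)
        # exact library sizes drawn from one log-normal mode, spread over
        # bins with varying accessibility: BIC should prefer 1 component
        libs = np.round(2.0 ** rng.normal(12, 0.4, 200)).astype(int)
        probs = rng.dirichlet(np.full(60, 0.3))
        dense = np.column_stack([rng.multinomial(l, probs) for l in libs])
        m = matrix_from_dense(dense)
        prof = estimate_profile(m, platform_hint="auto", seed=0)
        assert prof.library_model.w == 1.0

    def test_auto_picks_bimodal_on_two_mode_data(self, small_fixture):
        matrix, _ = small_fixture
        prof = estimate_profile(matrix, platform_hint="auto", seed=0)
        assert 0.0 < prof.library_model.w < 1.0

    def test_column_permutation_invariance(self, random_matrix):
        dense = random_matrix.counts.toarray()
        dense = dense[:, dense.sum(axis=0) > 0]
        rng = np.random.default_rng(1)
        perm = rng.permutation(dense.shape[1])
        a = estimate_profile(matrix_from_dense(dense), seed=0)
        b = estimate_profile(matrix_from_dense(dense[:, perm]), seed=0)
        assert np.allclose(a.bin_model.p, b.bin_model.p)
        # identical up to floating-point summation order inside EM/OLS
        for attr in ("mu1", "sigma1", "mu2", "sigma2", "w"):
            assert getattr(a.library_model, attr) == pytest.approx(
                getattr(b.library_model, attr), abs=1e-9
            )
        assert a.bin_model.beta0 == pytest.approx(b.bin_model.beta0)

    def test_row_permutation_equivariance(self, random_matrix):
        dense = random_matrix.counts.toarray()
        dense = dense[:, dense.sum(axis=0) > 0]
        rng = np.random.default_rng(2)
        perm = rng.permutation(dense.shape[0])
        a = estimate_profile(matrix_from_dense(dense), seed=0)
        b = estimate_profile(matrix_from_dense(dense[perm, :]), seed=0)
        assert np.allclose(a.bin_model.p[perm], b.bin_model.p)


class TestProfileSerialization:
    def test_round_trip(self, small_fixture, tmp_path):
        _, profile = small_fixture
        write_profile(profile, tmp_path / "prof")
        back = read_profile(tmp_path / "prof")
        assert back.library_model == profile.library_model
        assert np.allclose(back.bin_model.p, profile.bin_model.p)
        assert back.bin_model.beta2 == pytest.approx(profile.bin_model.beta2)
        assert back.bins == profile.bins
        assert back.n_cells_source == profile.n_cells_source
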