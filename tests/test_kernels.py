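import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarekernel import (
    build_similarity_matrix,
    exponential_kernel,
    per_snp_similarity,
    weighted_exponential_kernel,
    weighted_ibs_kernel,
    weighted_linear_kernel,
    weighted_quadratic_kernel,
)
from rarekernel.errors import (
    DegenerateWeightsError,
    KernelValidityError,
    ShapeError,
    ValidationError,
)
from rarekernel.kernels import check_psd, kernel_matrix


class TestScalarKernels:
    @pytest.mark.parametrize(
        "gn, gm, expected",
        [
            ((0, 1, 2), (0, 1, 2), 1.0),
            ((0, 1), (0, 0), np.exp(-1)),
            ((2, 0), (0, 0), np.exp(-4)),
        ],
    )
    def test_exponential_values(self, gn, gm, expected):
        assert exponential_kernel(gn, gm) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "gn, gm, w, expected",
        [
            ((1, 2), (1, 2), (1, 1), 1.0),
            ((0, 1), (0, 0), (1, 1), np.exp(-0.5)),
            ((1, 0), (0, 0), (3, 1), np.exp(-0.75)),
        ],
    )
    def test_weighted_exponential_values(self, gn, gm, w, expected):
        assert weighted_exponential_kernel(gn, gm, w) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_weights_degenerate(self):
        with pytest.raises(DegenerateWeightsError):
            weighted_exponential_kernel((0, 1), (1, 1), (0, 0))

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            exponential_kernel((0, 1), (0, 1, 2))

    @pytest.mark.parametrize(
        "gn, gm, w, expected",
        [
            ((0, 1, 2), (0, 1, 2), (1, 2, 3), 12.0),  # 2 * sum(w)
            ((0,), (2,), (1,), 0.0),
            ((0, 1), (1, 1), (1, 2), 5.0),
        ],
    )
    def test_weighted_ibs_values(self, gn, gm, w, expected):
        assert weighted_ibs_kernel(gn, gm, w) == pytest.approx(expected)

    def test_ibs_rejects_real_valued_genotypes(self):
        with pytest.raises(ValidationError):
            weighted_ibs_kernel((0.5, 1), (0, 1), (1, 1))

    def test_linear_and_quadratic(self):
        assert weighted_linear_kernel((0, 0), (2, 1), (1, 1)) == 0.0
        assert weighted_quadratic_kernel((0, 0), (2, 1), (1, 1)) == 1.0
        assert weighted_linear_kernel((1, 2), (2, 0), (1, 1)) == pytest.approx(2.0)

    @given(
        st.lists(st.integers(0, 2), min_size=1, max_size=10),
        st.lists(st.integers(0, 2), min_size=1, max_size=10),
    )
    @settings(deadline=None, derandomize=True)
    def test_kernel_symmetry(self, a, b):
        n = min(len(a), len(b))
        gn, gm = a[:n], b[:n]
        w = [1.0 + i for i in range(n)]
        assert exponential_kernel(gn, gm) == exponential_kernel(gm, gn)
        assert weighted_exponential_kernel(gn, gm, w) == weighted_exponential_kernel(
            gm, gn, w
        )
        assert weighted_ibs_kernel(gn, gm, w) == weighted_ibs_kernel(gm, gn, w)


class TestMatrixBuilder:
    def test_single_sample(self):
        sm = build_similarity_matrix(np.array([[0.0, 1.0]]))
        np.testing.assert_array_equal(sm.values, [[1.0]])

    def test_identical_individuals_hit_one(self):
        X = np.array([[0, 1, 2], [0, 1, 2], [1, 1, 1]], float)
        sm = build_similarity_matrix(X)
        assert sm.values[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(sm.values) == 1.0)
        assert np.all((sm.values > 0) & (sm.values <= 1))

    def test_exponential_matrices_are_psd(self, rng):
        # Gaussian-kernel PSD property, including real-valued (adjusted) input
        for _ in range(100):
            n, L = rng.integers(2, 12), rng.integers(1, 8)
            X = rng.normal(size=(n, L)) * 2
            sm = build_similarity_matrix(X, validate=True)
            ev = np.linalg.eigvalsh(sm.values)
            assert ev[0] >= -1e-8 * max(ev[-1], 1e-12)

    def test_weighted_kernel_matches_scalar_function(self, rng):
        X = rng.integers(0, 3, size=(6, 5)).astype(float)
        w = rng.uniform(0.5, 3.0, size=5)
        sm = build_similarity_matrix(X, weights=w)
        assert sm.weighted
        for i in range(6):
            for j in range(6):
                assert sm.values[i, j] == pytest.approx(
                    weighted_exponential_kernel(X[i], X[j], w), abs=1e-12
                )

    def test_equal_weights_equal_unweighted_with_scaled_distance(self, rng):
        X = rng.integers(0, 3, size=(8, 6)).astype(float)
        L = X.shape[1]
        Kw = kernel_matrix(X, w=np.full(L, 7.0))
        Ku = np.exp(-kernel_matrix_sq(X) / L)
        np.testing.assert_allclose(Kw, Ku, atol=1e-12)

    def test_psd_check_rejects_indefinite(self):
        M = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(KernelValidityError):
            check_psd(M)

    def test_non_psd_weighted_ibs_raises_on_build(self):
        # weights chosen so the weighted IBS matrix picks up a negative eigenvalue
        X = np.array([[0, 2], [2, 0], [1, 1], [0, 0]], float)
        K = kernel_matrix(X, kernel="ibs", w=np.array([1.0, 1.0]))
        ev = np.linalg.eigvalsh(K)
        if ev[0] < -1e-8 * ev[-1]:
            with pytest.raises(KernelValidityError):
                build_similarity_matrix(X, kernel="ibs", weights=np.array([1.0, 1.0]))


def kernel_matrix_sq(X):
    """Plain squared-distance matrix helper for the equal-weights identity."""
    diff = X[:, None, :] - X[None, :, :]
    return (diff**2).sum(axis=2)


class TestPerSnpSimilarity:
    def test_single_variant_equals_full_matrix(self, rng):
        X = rng.integers(0, 3, size=(5, 1)).astype(float)
        full = build_similarity_matrix(X)
        per = per_snp_similarity(X)
        assert len(per) == 1
        np.testing.assert_allclose(per[0].values, full.values)

    def test_monomorphic_column_is_all_ones(self):
        per = per_snp_similarity(np.zeros((4, 1)))
        np.testing.assert_array_equal(per[0].values, np.ones((4, 4)))

    def test_column_0_1_2_offdiagonals(self):
        per = per_snp_similarity(np.array([[0.0], [1.0], [2.0]]))
        K = per[0].values
        assert K[0, 1] == pytest.approx(np.exp(-1))
        assert K[0, 2] == pytest.approx(np.exp(-4))
        assert K[1, 2] == pytest.approx(np.exp(-1))
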