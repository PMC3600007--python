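import numpy as np
import pytest

import _oracles as oracles
from rarekernel import (
    from_counts,
    kbat_statistic,
    mdmr_statistic,
    permutation_pvalue,
    per_snp_similarity,
    run_all_tests,
    run_test,
    skat_statistic,
    u_test_statistic,
)
from rarekernel.association import (
    _kbat_stats,
    _mdmr_stats,
    _perm_case_matrix,
    _skat_stats,
    _utest_stats,
)
from rarekernel.errors import (
    DegenerateStatisticError,
    InsufficientGroupError,
)
from rarekernel.kernels import kernel_matrix


def random_instance(rng, n=10, L=5):
    X = rng.integers(0, 3, size=(n, L)).astype(float)
    K = kernel_matrix(X)
    y01 = np.zeros(n)
    y01[rng.permutation(n)[: n // 2]] = 1.0
    return X, K, y01


class TestStatisticContracts:
    def test_mdmr_degenerates_on_constant_similarity(self):
        K = np.ones((4, 4))
        with pytest.raises(DegenerateStatisticError):
            mdmr_statistic(K, np.array([1.0, 1.0, -1.0, -1.0]))

    def test_mdmr_label_symmetry_within_groups(self, rng):
        _, K, y01 = random_instance(rng)
        ypm = np.where(y01 == 1, 1.0, -1.0)
        cases = np.nonzero(ypm == 1)[0]
        swapped = ypm.copy()
        swapped[cases[0]], swapped[cases[1]] = ypm[cases[1]], ypm[cases[0]]
        assert mdmr_statistic(K, swapped) == pytest.approx(
            mdmr_statistic(K, ypm), abs=1e-14
        )

    def test_skat_zero_for_constant_phenotype_or_flat_kernel(self):
        K = np.eye(4)
        assert skat_statistic(K, np.ones(4)) == 0.0
        assert skat_statistic(np.ones((4, 4)), np.array([1.0, 1.0, 0, 0])) == pytest.approx(0.0)

    def test_utest_zero_for_constant_offdiagonal(self):
        K = np.full((6, 6), 0.37)
        np.fill_diagonal(K, 1.0)
        y = np.array([1.0, 1, 1, -1, -1, -1])
        assert u_test_statistic(K, y) == pytest.approx(0.0, abs=1e-15)

    def test_utest_group_swap_invariance(self, rng):
        _, K, y01 = random_instance(rng, n=8)
        ypm = np.where(y01 == 1, 1.0, -1.0)
        assert u_test_statistic(K, ypm) == pytest.approx(
            u_test_statistic(K, -ypm), abs=1e-14
        )

    def test_small_groups_rejected(self):
        K = np.eye(4)
        with pytest.raises(InsufficientGroupError):
            u_test_statistic(K, np.array([1.0, 1, 1, -1]))

    def test_kbat_equal_weights_cancel(self, rng):
        X, _, y01 = random_instance(rng, n=8, L=4)
        ypm = np.where(y01 == 1, 1.0, -1.0)
        Ks = [m.values for m in per_snp_similarity(X)]
        unweighted = kbat_statistic(Ks, ypm)
        weighted = kbat_statistic(Ks, ypm, w=np.full(4, 3.7))
        assert weighted == pytest.approx(unweighted, rel=1e-12)

    def test_statistics_invariant_under_joint_relabeling(self, rng):
        X, K, y01 = random_instance(rng, n=10, L=4)
        ypm = np.where(y01 == 1, 1.0, -1.0)
        perm = rng.permutation(10)
        Kp = K[np.ix_(perm, perm)]
        Xp = X[perm]
        Ks = [m.values for m in per_snp_similarity(X)]
        Ksp = [m.values for m in per_snp_similarity(Xp)]
        assert mdmr_statistic(Kp, ypm[perm]) == pytest.approx(
            mdmr_statistic(K, ypm), abs=1e-12
        )
        assert skat_statistic(Kp, y01[perm]) == pytest.approx(
            skat_statistic(K, y01), abs=1e-12
        )
        assert u_test_statistic(Kp, ypm[perm]) == pytest.approx(
            u_test_statistic(K, ypm), abs=1e-14
        )
        assert kbat_statistic(Ksp, ypm[perm]) == pytest.approx(
            kbat_statistic(Ks, ypm), rel=1e-12
        )


class TestAgainstBruteForceOracles:
    def test_all_four_statistics_match_oracles_on_random_instances(self, rng):
        for _ in range(25):
            X, K, y01 = random_instance(rng, n=int(rng.integers(6, 14)), L=4)
            ypm = np.where(y01 == 1, 1.0, -1.0)
            Ks = [m.values for m in per_snp_similarity(X)]
            assert mdmr_statistic(K, ypm) == pytest.approx(
                oracles.mdmr_oracle(K, ypm), abs=1e-12
            )
            assert skat_statistic(K, y01) == pytest.approx(
                oracles.skat_oracle(K, y01), abs=1e-12
            )
            assert u_test_statistic(K, ypm) == pytest.approx(
                oracles.utest_oracle(K, ypm), abs=1e-12
            )
            assert kbat_statistic(Ks, ypm) == pytest.approx(
                oracles.kbat_oracle(Ks, ypm), rel=1e-12
            )


class TestPermutationEngine:
    def test_engine_matches_naive_statistics_columnwise(self, rng):
        X, K, y01 = random_instance(rng, n=12, L=5)
        n_cases = int(y01.sum())
        C = _perm_case_matrix(y01, 40, rng)
        Ks = [m.values for m in per_snp_similarity(X)]
        skat = _skat_stats(K, C, n_cases)
        ut = _utest_stats(K, C, n_cases)
        md = _mdmr_stats(K, C)
        kb = _kbat_stats(X, C, n_cases)
        for b in range(C.shape[1]):
            c = C[:, b]
            ypm = np.where(c == 1, 1.0, -1.0)
            assert skat[b] == pytest.approx(skat_statistic(K, c), abs=1e-12)
            assert ut[b] == pytest.approx(u_test_statistic(K, ypm), abs=1e-13)
            assert md[b] == pytest.approx(mdmr_statistic(K, ypm), abs=1e-10)
            assert kb[b] == pytest.approx(kbat_statistic(Ks, ypm), rel=1e-10)

    def test_pvalue_floor_and_ceiling(self):
        # statistic maximal only at the observed labeling -> p = 1/(B+1)
        observed = np.arange(50.0)
        res = permutation_pvalue(
            lambda y: float(np.array_equal(y, observed)), observed, B=9, seed=1
        )
        assert res.p_value == pytest.approx(1 / 10)
        # permutation-invariant statistic -> p = 1
        res = permutation_pvalue(lambda y: 1.0, np.array([1.0, 1, 0, 0]), B=9, seed=1)
        assert res.p_value == 1.0

    def test_run_test_deterministic_given_seed(self, rng):
        g = from_counts(rng.integers(0, 3, size=(20, 6)).astype(float))
        y = np.r_[np.ones(10), np.zeros(10)]
        a = run_test("skat", g, y, pooling="none", B=50, seed=7)
        b = run_test("skat", g, y, pooling="none", B=50, seed=7)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)

    def test_single_variant_region_runs_all_methods(self, rng):
        counts = rng.binomial(1, 0.3, size=(16, 1)).astype(float)
        g = from_counts(counts)
        y = np.r_[np.ones(8), np.zeros(8)]
        res = run_all_tests(g, y, poolings=("none",), B=30, seed=0)
        for m, tr in res["none"].items():
            assert 0 < tr.p_value <= 1.0

    def test_collapsing_all_rare_runs_on_super_locus_alone(self, rng):
        # every variant rare -> the analysis matrix is the super-locus only
        counts = np.zeros((300, 5))
        idx = rng.permutation(300)
        counts[idx[:3], 0] = 1
        counts[idx[3:5], 1] = 1
        counts[idx[5:7], 2] = 1
        counts[idx[7:8], 3] = 1
        counts[idx[8:10], 4] = 1
        g = from_counts(counts)
        y = np.r_[np.ones(150), np.zeros(150)]
        res = run_all_tests(g, y, poolings=("collapsing",), B=30, seed=0)
        assert set(res["collapsing"]) == {"mdmr", "skat", "utest", "kbat"}

    def test_null_pvalues_super_uniform(self):
        """Permutation p-values behave like valid p-values under the null:
        the rejection rate at 0.05 stays inside the binomial 99% band."""
        from rarekernel.power import type1_error_ci

        rng = np.random.default_rng(5)
        n_sims, B = 500, 199
        hits = 0
        for _ in range(n_sims):
            X, K, y01 = random_instance(rng, n=20, L=5)
            C = _perm_case_matrix(y01, B, rng)
            stats = _skat_stats(K, C, int(y01.sum()))
            p = (1 + np.count_nonzero(stats[1:] >= stats[0])) / (B + 1)
            hits += p <= 0.05
        lo, hi = type1_error_ci(0.05, n_sims, 0.99)
        assert lo <= hits / n_sims <= hi
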