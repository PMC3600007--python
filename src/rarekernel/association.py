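"""The four similarity-based association tests and permutation inference.

Statistics (all computed from the genotype similarity matrix K and binary
phenotype):

* **MDMR** — distance-matrix regression pseudo-F. With H = Y(YᵀY)⁻¹Yᵀ the
  projection onto the ±1 phenotype, D = 11ᵀ − K, A = {−d²/2} and
  Gc = C A C the Gower-centered matrix (C = I − 11ᵀ/N), the statistic is
  tr(H Gc H) / tr((I−H) Gc (I−H)).
* **SKAT** — quadratic form T = (Y − Ȳ)ᵀ K (Y − Ȳ)/2 with 1/0 phenotype
  coding and Ȳ = (N_A/N)·1.
* **U-test** — squared difference of the average within-case and
  within-control similarities, U = (U₁ − U₀)², with
  U₁ = Σ_{case pairs n<m} K_nm / [N_A (N_A − 1)] and U₀ analogously.
* **KBAT** — per-SNP analysis-of-variance of pairwise similarities:
  KBAT = Σ_l BSS_l / Σ_l WSS_l over single-SNP similarity matrices K_l;
  the weighted form KBAT_W uses Σ_l w_l BSS_l / Σ_l w_l WSS_l.

Significance is assessed by permuting case/control labels; the p-value is
the add-one estimator (1 + #{permuted stat >= observed}) / (B + 1). One
permutation set is shared across methods (and pooling strategies) within a
run, so method comparisons are paired.

Naive per-statistic functions operate on explicit similarity matrices; the
permutation engine evaluates all B+1 labelings with dense matrix products
(and, for KBAT, genotype-value counts), which is what makes 1000-permutation
studies on 1000 individuals tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateStatisticError,
    InsufficientGroupError,
    ShapeError,
    ValidationError,
)
from .genotype_io import GenotypeMatrix, PhenotypeVector, drop_monomorphic
from .kernels import SimilarityMatrix, kernel_matrix
from .pooling import (
    DEFAULT_BETA_PARAMS,
    RARE_MAF_THRESHOLD,
    WeightVector,
    pooled_analysis_matrix,
)

logger = logging.getLogger("rarekernel")

METHODS = ("mdmr", "skat", "utest", "kbat")

#: Number of phenotype permutations used for significance by default.
DEFAULT_PERMUTATIONS = 1000

_DEGENERATE_TOL = 1e-12


@dataclass
class TestResult:
    """Observed statistic and permutation p-value of one test."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    pooling: str | None = None
    kernel: str | None = None


def _k_array(K) -> np.ndarray:
    K = np.asarray(getattr(K, "values", K), dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ShapeError("similarity matrix must be square")
    return K


def _pm_labels(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.to_plus_minus()
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {1.0, -1.0}:
        raise ValidationError("phenotype must be coded 1 (case) / -1 (control)")
    return y


def _zo_labels(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.to_zero_one()
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {1.0, 0.0}:
        raise ValidationError("phenotype must be coded 1 (case) / 0 (control)")
    return y


# ---------------------------------------------------------------------------
# naive statistics (explicit matrix evaluation)


def gower_centered(K: np.ndarray) -> np.ndarray:
    """Gower double-centered matrix Gc = C A C, A = -(1-K)^2 / 2."""
    D = 1.0 - K
    A = -0.5 * D * D
    rm = A.mean(axis=1, keepdims=True)
    cm = A.mean(axis=0, keepdims=True)
    return A - rm - cm + A.mean()


def mdmr_statistic(K, y) -> float:
    """Distance-matrix-regression pseudo-F; large values indicate association."""
    K = _k_array(K)
    ypm = _pm_labels(y)
    if ypm.size != K.shape[0]:
        raise ShapeError("phenotype length does not match similarity matrix")
    Y = ypm[:, None]
    H = Y @ np.linalg.inv(Y.T @ Y) @ Y.T
    Gc = gower_centered(K)
    I = np.eye(K.shape[0])
    num = np.trace(H @ Gc @ H)
    den = np.trace((I - H) @ Gc @ (I - H))
    if den <= _DEGENERATE_TOL * max(abs(np.trace(Gc)), 1.0):
        raise DegenerateStatisticError(
            "residual trace is not positive: all pairwise dissimilarities "
            "are (numerically) zero"
        )
    return float(num / den)


def skat_statistic(K, y) -> float:
    """T = (Y - Ybar)' K (Y - Ybar) / 2 with 1/0 phenotype coding."""
    K = _k_array(K)
    y01 = _zo_labels(y)
    if y01.size != K.shape[0]:
        raise ShapeError("phenotype length does not match similarity matrix")
    if y01.min() == y01.max():
        logger.warning("all-case or all-control phenotype: SKAT statistic is 0")
    z = y01 - y01.mean()
    return float(z @ K @ z / 2.0)


def _group_pair_average(K: np.ndarray, idx: np.ndarray) -> float:
    """Sum over pairs n<m within idx of K, divided by k(k-1)."""
    k = idx.size
    sub = K[np.ix_(idx, idx)]
    pair_sum = (sub.sum() - np.trace(sub)) / 2.0
    return pair_sum / (k * (k - 1))


def u_test_statistic(K, y) -> float:
    """U = (U1 - U0)^2, squared gap between within-group average similarities."""
    K = _k_array(K)
    ypm = _pm_labels(y)
    cases = np.nonzero(ypm == 1.0)[0]
    controls = np.nonzero(ypm == -1.0)[0]
    if cases.size < 2 or controls.size < 2:
        raise InsufficientGroupError(
            "U-test needs at least two cases and two controls"
        )
    u1 = _group_pair_average(K, cases)
    u0 = _group_pair_average(K, controls)
    return float((u1 - u0) ** 2)


def kbat_statistic(Ks, y, w=None) -> float:
    """KBAT (or KBAT_W with weights) from per-SNP similarity matrices."""
    ypm = _pm_labels(y)
    cases = np.nonzero(ypm == 1.0)[0]
    controls = np.nonzero(ypm == -1.0)[0]
    nA, nU = cases.size, controls.size
    if nA < 2 or nU < 2:
        raise InsufficientGroupError(
            "KBAT needs at least two cases and two controls"
        )
    mats = [_k_array(K) for K in Ks]
    w = np.ones(len(mats)) if w is None else np.asarray(getattr(w, "w", w), float)
    if w.size != len(mats):
        raise ShapeError("weight length does not match number of per-SNP matrices")
    pa, pu = nA * (nA - 1) / 2.0, nU * (nU - 1) / 2.0
    bss_sum = 0.0
    wss_sum = 0.0
    for wl, Kl in zip(w, mats):
        u1 = _group_pair_average(Kl, cases)
        u0 = _group_pair_average(Kl, controls)
        ul = (u1 + u0) / 2.0
        sub_a = Kl[np.ix_(cases, cases)][np.triu_indices(nA, 1)]
        sub_u = Kl[np.ix_(controls, controls)][np.triu_indices(nU, 1)]
        wss = np.sum((sub_a - u1) ** 2) + np.sum((sub_u - u0) ** 2)
        bss = pa * (ul - u1) ** 2 + pu * (ul - u0) ** 2
        bss_sum += wl * bss
        wss_sum += wl * wss
    if wss_sum <= _DEGENERATE_TOL:
        raise DegenerateStatisticError(
            "within-group similarity sum of squares is zero; KBAT undefined"
        )
    return float(bss_sum / wss_sum)


def permutation_pvalue(stat_fn, y, B: int = DEFAULT_PERMUTATIONS, seed: int = 0,
                       method: str = "custom") -> TestResult:
    """Permutation p-value of an arbitrary statistic closure.

    ``stat_fn(labels)`` must be deterministic given the label vector. Labels
    are permuted uniformly at random B times (the similarity matrix closed
    over by ``stat_fn`` stays fixed); ties count toward the tail.
    """
    if B < 1:
        raise ValidationError("need at least one permutation")
    values = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    rng = np.random.default_rng(seed)
    observed = float(stat_fn(values))
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(values.size)
        if stat_fn(values[perm]) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (B + 1.0)
    return TestResult(method, observed, p, B, seed)


# ---------------------------------------------------------------------------
# vectorized permutation engine


def _perm_case_matrix(y01: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """N x (B+1) case-indicator matrix; column 0 is the observed labeling."""
    n = y01.size
    n_cases = int(round(y01.sum()))
    C = np.zeros((n, B + 1))
    C[:, 0] = y01
    for b in range(1, B + 1):
        C[rng.permutation(n)[:n_cases], b] = 1.0
    return C


def _pair_sums(K: np.ndarray, C: np.ndarray):
    """Within-case / within-control pair sums of K for every labeling column."""
    d = np.ascontiguousarray(np.diag(K))
    M = K @ C
    a = np.einsum("nb,nb->b", C, M)  # c'Kc, ordered pairs incl. diagonal
    colsum = M.sum(axis=0)  # 1'Kc
    diag_case = d @ C
    total = K.sum()
    s_case = 0.5 * (a - diag_case)
    uKu = total - 2.0 * colsum + a
    s_ctrl = 0.5 * (uKu - (d.sum() - diag_case))
    return s_case, s_ctrl, a, colsum, total


def _skat_stats(K, C, n_cases):
    _, _, a, colsum, total = _pair_sums(K, C)
    p = n_cases / K.shape[0]
    return 0.5 * (a - 2.0 * p * colsum + p * p * total)


def _utest_stats(K, C, n_cases):
    n = K.shape[0]
    n_ctrl = n - n_cases
    if n_cases < 2 or n_ctrl < 2:
        raise InsufficientGroupError("U-test needs >= 2 cases and >= 2 controls")
    s_case, s_ctrl, *_ = _pair_sums(K, C)
    u1 = s_case / (n_cases * (n_cases - 1))
    u0 = s_ctrl / (n_ctrl * (n_ctrl - 1))
    return (u1 - u0) ** 2


def _mdmr_stats(K, C):
    n = K.shape[0]
    Gc = gower_centered(K)
    tr = np.trace(Gc)
    if tr <= _DEGENERATE_TOL:
        raise DegenerateStatisticError(
            "Gower-centered trace is not positive; MDMR undefined"
        )
    Mg = Gc @ C
    q = (
        4.0 * np.einsum("nb,nb->b", C, Mg)
        - 4.0 * (Gc.sum(axis=0) @ C)
        + Gc.sum()
    )  # y'Gc y with y = 2c - 1
    num = q / n
    return num / (tr - num)


def _kernel_value_matrix(levels: np.ndarray, kernel: str) -> np.ndarray:
    """Single-site kernel evaluated on a grid of genotype values."""
    u = levels[:, None]
    v = levels[None, :]
    if kernel == "exponential":
        return np.exp(-((u - v) ** 2))
    if kernel == "linear":
        return u * v
    if kernel == "quadratic":
        return (1.0 + u * v) ** 2
    if kernel == "ibs":
        return 2.0 - np.abs(u - v)
    raise ValueError(f"unknown kernel {kernel!r}")


def _kbat_stats(X, C, n_cases, w=None, kernel: str = "exponential"):
    """KBAT statistics for all labeling columns from genotype-value counts.

    For a single-SNP kernel, K_l = E V Eᵀ where E one-hot encodes the
    distinct genotype values of column l and V is the kernel on those
    values; every within-group pair sum (and sum of squares, via V∘V) is
    then a quadratic form in the per-group value counts Eᵀc.
    """
    n, L = X.shape
    n_ctrl = n - n_cases
    if n_cases < 2 or n_ctrl < 2:
        raise InsufficientGroupError("KBAT needs >= 2 cases and >= 2 controls")
    w = np.ones(L) if w is None else np.asarray(getattr(w, "w", w), float)
    pa, pu = n_cases * (n_cases - 1) / 2.0, n_ctrl * (n_ctrl - 1) / 2.0
    B1 = C.shape[1]
    bss = np.zeros((L, B1))
    wss = np.zeros((L, B1))
    for l in range(L):
        col = X[:, l]
        levels, codes = np.unique(col, return_inverse=True)
        V = _kernel_value_matrix(levels, kernel)
        E = np.zeros((n, levels.size))
        E[np.arange(n), codes] = 1.0
        cnt_a = E.T @ C  # value counts among cases, per labeling
        cnt_u = E.sum(axis=0)[:, None] - cnt_a
        vdiag = np.diag(V)
        W2 = V * V
        s_a = 0.5 * (np.einsum("ab,aB,bB->B", V, cnt_a, cnt_a) - vdiag @ cnt_a)
        s_u = 0.5 * (np.einsum("ab,aB,bB->B", V, cnt_u, cnt_u) - vdiag @ cnt_u)
        q_a = 0.5 * (np.einsum("ab,aB,bB->B", W2, cnt_a, cnt_a) - (vdiag**2) @ cnt_a)
        q_u = 0.5 * (np.einsum("ab,aB,bB->B", W2, cnt_u, cnt_u) - (vdiag**2) @ cnt_u)
        u1 = s_a / (n_cases * (n_cases - 1))
        u0 = s_u / (n_ctrl * (n_ctrl - 1))
        ul = 0.5 * (u1 + u0)
        wss[l] = (q_a - 2.0 * u1 * s_a + pa * u1**2) + (
            q_u - 2.0 * u0 * s_u + pu * u0**2
        )
        bss[l] = pa * (ul - u1) ** 2 + pu * (ul - u0) ** 2
    num = w @ bss
    den = w @ wss
    if den[0] <= _DEGENERATE_TOL:
        raise DegenerateStatisticError(
            "within-group similarity sum of squares is zero; KBAT undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, 0.0)


def _pvalue_from_stats(stats: np.ndarray) -> tuple[float, float]:
    observed = stats[0]
    p = (1.0 + np.count_nonzero(stats[1:] >= observed)) / stats.size
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# high-level runners


def run_all_tests(
    g: GenotypeMatrix,
    y,
    methods=METHODS,
    poolings=("weighting", "collapsing"),
    kernel: str = "exponential",
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    maf_threshold: float = RARE_MAF_THRESHOLD,
    beta_params=DEFAULT_BETA_PARAMS,
    weight_exponent: float = 1.0,
    weights: WeightVector | None = None,
    case_matrix: np.ndarray | None = None,
) -> dict:
    """Run the requested tests under the requested pooling strategies.

    One permutation set (``case_matrix``, built from ``seed`` when not
    supplied) is shared across all methods and poolings so comparisons are
    paired. Returns ``{pooling: {method: TestResult}}``.
    """
    g = drop_monomorphic(g)
    y01 = _zo_labels(y)
    if y01.size != g.n_samples:
        raise ShapeError("phenotype length does not match genotype matrix")
    n_cases = int(round(y01.sum()))
    if case_matrix is None:
        rng = np.random.default_rng(seed)
        case_matrix = _perm_case_matrix(y01, B, rng)
    else:
        B = case_matrix.shape[1] - 1
    C = case_matrix
    results: dict = {}
    for pooling in poolings:
        X, w = pooled_analysis_matrix(
            g, pooling, threshold=maf_threshold, beta_params=beta_params,
            weights=weights,
        )
        if w is not None and weight_exponent != 1.0:
            w = w**weight_exponent
        per_pool: dict = {}
        need_k = any(m in methods for m in ("mdmr", "skat", "utest"))
        if need_k:
            K = kernel_matrix(X, kernel=kernel, w=w)
        for method in methods:
            if method == "skat":
                stats = _skat_stats(K, C, n_cases)
            elif method == "utest":
                stats = _utest_stats(K, C, n_cases)
            elif method == "mdmr":
                stats = _mdmr_stats(K, C)
            elif method == "kbat":
                if w is not None:
                    logger.info("KBAT with weights: using KBAT_W statistic")
                stats = _kbat_stats(X, C, n_cases, w=w, kernel=kernel)
            else:
                raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
            obs, p = _pvalue_from_stats(stats)
            per_pool[method] = TestResult(
                method, obs, p, B, seed, pooling=pooling, kernel=kernel
            )
        results[pooling] = per_pool
    return results


def run_test(
    method: str,
    g: GenotypeMatrix,
    y,
    pooling: str = "none",
    kernel: str = "exponential",
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    maf_threshold: float = RARE_MAF_THRESHOLD,
    beta_params=DEFAULT_BETA_PARAMS,
) -> TestResult:
    """Pool, build the similarity structure, and permutation-test one method."""
    res = run_all_tests(
        g,
        y,
        methods=(method,),
        poolings=(pooling,),
        kernel=kernel,
        B=B,
        seed=seed,
        maf_threshold=maf_threshold,
        beta_params=beta_params,
    )
    return res[pooling][method]
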