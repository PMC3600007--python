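"""Genotype similarity kernels.

Every kernel maps two multi-site genotype vectors to a real similarity and
yields a symmetric positive-semi-definite N x N matrix K = {s(g_n, g_m)}.
The exponential (Gaussian) kernel exp(-sum_l (g_nl - g_ml)^2) is the default;
its weighted form normalises the weighted squared distance by the total
weight, exp(-sum_l w_l (g_nl - g_ml)^2 / sum_l w_l). The weighted IBS, linear
and quadratic kernels are provided for sensitivity analyses; IBS is defined
on integer genotype codes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import (
    DegenerateWeightsError,
    KernelValidityError,
    ShapeError,
    ValidationError,
)

KERNEL_NAMES = ("exponential", "ibs", "linear", "quadratic")

#: Relative eigenvalue tolerance for the PSD check.
PSD_RTOL = 1e-8


@dataclass
class SimilarityMatrix:
    """An N x N genotype similarity matrix with provenance flags."""

    values: np.ndarray
    kernel_name: str
    weighted: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_pair(gn, gm):
    gn = np.asarray(gn, dtype=float).ravel()
    gm = np.asarray(gm, dtype=float).ravel()
    if gn.shape != gm.shape:
        raise ShapeError(f"genotype length mismatch: {gn.size} vs {gm.size}")
    if gn.size == 0:
        raise ShapeError("genotype vectors must have length >= 1")
    return gn, gm


def _check_weights(w, L):
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != L:
        raise ShapeError(f"weight length {w.size} does not match {L} variants")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    return w


def exponential_kernel(gn, gm) -> float:
    """exp(-sum_l (g_nl - g_ml)^2); equals 1 iff the genotypes coincide."""
    gn, gm = _as_pair(gn, gm)
    return float(np.exp(-np.sum((gn - gm) ** 2)))


def weighted_exponential_kernel(gn, gm, w) -> float:
    """exp(-sum_l w_l (g_nl - g_ml)^2 / sum_l w_l)."""
    gn, gm = _as_pair(gn, gm)
    w = _check_weights(_weights_array(w), gn.size)
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("sum of weights must be positive")
    return float(np.exp(-np.sum(w * (gn - gm) ** 2) / total))


def _require_genotype_codes(*vecs):
    for v in vecs:
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isin(arr, (0.0, 1.0, 2.0))):
            raise ValidationError(
                "IBS similarity is defined on genotype codes {0, 1, 2} only"
            )


def weighted_ibs_kernel(gn, gm, w) -> float:
    """sum_l w_l (2 - |g_nl - g_ml|), identity-by-state allele sharing."""
    gn, gm = _as_pair(gn, gm)
    _require_genotype_codes(gn, gm)
    w = _check_weights(_weights_array(w), gn.size)
    return float(np.sum(w * (2.0 - np.abs(gn - gm))))


def weighted_linear_kernel(gn, gm, w) -> float:
    """sum_l w_l g_nl g_ml."""
    gn, gm = _as_pair(gn, gm)
    w = _check_weights(_weights_array(w), gn.size)
    return float(np.sum(w * gn * gm))


def weighted_quadratic_kernel(gn, gm, w) -> float:
    """(1 + sum_l w_l g_nl g_ml)^2."""
    return (1.0 + weighted_linear_kernel(gn, gm, w)) ** 2


def _weights_array(w):
    # accept a pooling.WeightVector or a plain array
    return getattr(w, "w", w)


# ---------------------------------------------------------------------------
# matrix builders


def _pairwise_sq_dists(X: np.ndarray, w=None) -> np.ndarray:
    """(Optionally weighted) squared Euclidean distances between rows of X."""
    Xw = X if w is None else X * w
    S = Xw @ X.T
    q = np.einsum("nl,nl->n", Xw, X)
    sq = q[:, None] + q[None, :] - (S + S.T)
    np.maximum(sq, 0.0, out=sq)
    np.fill_diagonal(sq, 0.0)
    return sq


def kernel_matrix(X: np.ndarray, kernel: str = "exponential", w=None) -> np.ndarray:
    """Raw kernel matrix over the rows of ``X`` (no PSD check)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = None if w is None else _check_weights(_weights_array(w), X.shape[1])
    if kernel == "exponential":
        if w is None:
            K = np.exp(-_pairwise_sq_dists(X))
        else:
            total = w.sum()
            if total <= 0:
                raise DegenerateWeightsError("sum of weights must be positive")
            K = np.exp(-_pairwise_sq_dists(X, w) / total)
    elif kernel == "linear":
        ww = np.ones(X.shape[1]) if w is None else w
        K = (X * ww) @ X.T
    elif kernel == "quadratic":
        ww = np.ones(X.shape[1]) if w is None else w
        K = (1.0 + (X * ww) @ X.T) ** 2
    elif kernel == "ibs":
        _require_genotype_codes(X)
        ww = np.ones(X.shape[1]) if w is None else w
        from scipy.spatial.distance import cdist

        man = cdist(X, X, metric="cityblock", w=ww) if X.shape[1] else None
        K = 2.0 * ww.sum() - man
    else:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNEL_NAMES}")
    return (K + K.T) / 2.0


def check_psd(values: np.ndarray, rtol: float = PSD_RTOL) -> None:
    """Raise :class:`KernelValidityError` unless ``values`` is symmetric PSD.

    The smallest eigenvalue must be >= -rtol * largest eigenvalue.
    """
    if values.shape[0] != values.shape[1]:
        raise KernelValidityError("similarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise KernelValidityError("similarity matrix is not symmetric")
    ev = scipy.linalg.eigvalsh(values)
    lo, hi = ev[0], max(ev[-1], 0.0)
    if lo < -rtol * max(hi, 1e-300):
        raise KernelValidityError(
            f"similarity matrix is not positive semi-definite "
            f"(min eigenvalue {lo:.3e}, max {hi:.3e})"
        )


def build_similarity_matrix(
    g, kernel: str = "exponential", weights=None, validate: bool = True
) -> SimilarityMatrix:
    """Full N x N similarity matrix for a genotype matrix.

    ``g`` may be a :class:`~rarekernel.genotype_io.GenotypeMatrix` or a plain
    (N, L) array. ``validate=True`` runs the symmetry/PSD check (O(N^3));
    large permutation studies skip it because the exponential kernel is PSD
    by construction.
    """
    X = np.asarray(getattr(g, "counts", g), dtype=float)
    K = kernel_matrix(X, kernel=kernel, w=weights)
    if validate:
        check_psd(K)
    return SimilarityMatrix(K, kernel, weighted=weights is not None)


def per_snp_similarity(
    g, kernel: str = "exponential", validate: bool = False
) -> list[SimilarityMatrix]:
    """One single-SNP similarity matrix K_l per variant (used by KBAT).

    Materialises L dense N x N matrices; intended for small N. The KBAT
    permutation engine computes the same quantities from genotype-value
    counts without building these.
    """
    X = np.asarray(getattr(g, "counts", g), dtype=float)
    return [
        build_similarity_matrix(X[:, [l]], kernel=kernel, validate=validate)
        for l in range(X.shape[1])
    ]
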