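"""Population-stratification and covariate adjustment.

The adjustment mirrors the standard exome-workshop pipeline for a
multi-population sample: (1) compute the top-k principal components R of the
column-standardized genotype matrix; (2) project genotypes, phenotypes and
covariates onto the orthogonal complement of R (x -> x - R Rᵀ x); (3) regress
the adjusted phenotype on the adjusted covariates by OLS and keep the
residuals; (4) dichotomize the residuals, declaring the upper 30% cases.
The adjusted genotype matrix is real-valued, which is why the exponential
kernel (a function of Euclidean distance) is the default similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, ValidationError
from .genotype_io import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger("rarekernel")

DEFAULT_N_COMPONENTS = 10
DEFAULT_TOP_FRACTION = 0.30


@dataclass
class AdjustedData:
    """Stratification/covariate-adjusted data ready for association testing."""

    g_adj: np.ndarray
    pheno_adj: np.ndarray
    covariates_adj: np.ndarray | None
    components: np.ndarray
    residuals: np.ndarray
    phenotype: PhenotypeVector


def pca_components(g, k: int = DEFAULT_N_COMPONENTS) -> np.ndarray:
    """Top-k left singular vectors (N x k, orthonormal) of the standardized
    genotype matrix.

    Columns are centered and scaled by sqrt(2 p (1-p)) with p the allele
    frequency estimate (column mean / 2) — the usual Eigenstrat-style
    standardization. Monomorphic columns are skipped. If the matrix rank is
    below k the component count is truncated with a warning.
    """
    X = np.asarray(getattr(g, "counts", g), dtype=float)
    n = X.shape[0]
    if k == 0:
        return np.zeros((n, 0))
    if k < 0 or k >= n:
        raise ValidationError("need 0 <= k < number of samples")
    p = X.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd > 0
    Z = (X[:, keep] - 2.0 * p[keep]) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    tol = s.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < k:
        logger.warning(
            "genotype matrix rank %d < requested %d components; truncating", rank, k
        )
        k = rank
    return U[:, :k]


def project_out(x, R: np.ndarray):
    """x - R Rᵀ x: remove the span of the (orthonormal) columns of R."""
    x = np.asarray(x, dtype=float)
    R = np.asarray(R, dtype=float)
    if x.shape[0] != R.shape[0]:
        raise ShapeError(
            f"row count mismatch: data has {x.shape[0]}, components {R.shape[0]}"
        )
    if R.shape[1] == 0:
        return x.copy()
    return x - R @ (R.T @ x)


def regress_out_covariates(pheno_adj, covariates_adj) -> np.ndarray:
    """OLS residuals of the adjusted phenotype on intercept + adjusted covariates."""
    y = np.asarray(pheno_adj, dtype=float).ravel()
    E = np.atleast_2d(np.asarray(covariates_adj, dtype=float))
    if E.shape[0] != y.size:
        raise ShapeError("covariate rows do not match phenotype length")
    X = np.column_stack([np.ones(y.size), E])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose addition does not raise the rank
        r = 1
        for j in range(1, X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise ValidationError(
                    f"covariate column {j - 1} is collinear with the preceding design"
                )
            r = rj
        raise ValidationError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def dichotomize(residuals, top_fraction: float = DEFAULT_TOP_FRACTION) -> PhenotypeVector:
    """Declare the ceil(top_fraction * N) largest residuals cases (coded 1/0).

    Ties at the cutoff are broken by stable original-index order and logged.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if not np.all(np.isfinite(r)):
        raise ValidationError("residuals must be finite")
    if not 0.0 < top_fraction < 1.0:
        raise ValidationError("top_fraction must be in (0, 1)")
    n = r.size
    k = int(np.ceil(top_fraction * n))
    order = np.argsort(-r, kind="stable")
    labels = np.zeros(n)
    labels[order[:k]] = 1.0
    if k < n and r[order[k - 1]] == r[order[k]]:
        logger.warning(
            "ties at the %g dichotomization cutoff broken by index order",
            top_fraction,
        )
    return PhenotypeVector(labels, "zero_one")


def adjust_dataset(
    g: GenotypeMatrix,
    phenotype,
    covariates=None,
    k: int = DEFAULT_N_COMPONENTS,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> AdjustedData:
    """Full adjustment pipeline: PCA projection, covariate regression,
    dichotomization.

    ``phenotype`` may be quantitative or an (already binary) trait; both are
    projected, residualized and re-dichotomized identically.
    """
    values = (
        phenotype.values
        if isinstance(phenotype, PhenotypeVector)
        else np.asarray(phenotype, dtype=float)
    )
    R = pca_components(g, k=k)
    g_adj = project_out(g.counts, R)
    pheno_adj = project_out(values, R)
    if covariates is not None:
        cov_adj = project_out(np.atleast_2d(np.asarray(covariates, float)), R)
        residuals = regress_out_covariates(pheno_adj, cov_adj)
    else:
        cov_adj = None
        residuals = pheno_adj - pheno_adj.mean()
    binary = dichotomize(residuals, top_fraction=top_fraction)
    return AdjustedData(g_adj, pheno_adj, cov_adj, R, residuals, binary)
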