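"""Rare-variant pooling: Beta-density MAF weighting and super-locus collapsing.

Two strategies pool the information in low-frequency variants:

* **weighting** — every variant (rare and common) enters the similarity
  kernel, weighted by w_l = Beta(maf_l; 1, 25)^2, the squared Beta(1, 25)
  density at the variant's MAF. The weight increases monotonically as MAF
  decreases, so rare alleles dominate the kernel distance.
* **collapsing** — rare variants (maf <= 0.01) are summed into a single
  super-locus g_{n,L+1} = min(2, sum of rare minor-allele counts); tests
  then run on the common variants plus the unweighted super-locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .errors import EmptyRegionError, ValidationError
from .genotype_io import GenotypeMatrix, from_counts

logger = logging.getLogger("rarekernel")

#: MAF at or below which a variant counts as rare (1%).
RARE_MAF_THRESHOLD = 0.01

#: Default Beta-density parameters (b, c) of the MAF weight.
DEFAULT_BETA_PARAMS = (1.0, 25.0)

POOLING_STRATEGIES = ("weighting", "collapsing", "none")


@dataclass
class WeightVector:
    """Per-variant non-negative weights with provenance."""

    w: np.ndarray
    source: str = "custom"

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if np.any(self.w < 0):
            raise ValidationError("weights must be non-negative")

    def __len__(self):
        return self.w.size

    def __pow__(self, p: float) -> "WeightVector":
        return WeightVector(self.w**p, source=f"{self.source}^{p:g}")


@dataclass
class PooledGenotype:
    """Result of super-locus collapsing at a MAF threshold."""

    common: GenotypeMatrix | None
    super_locus: np.ndarray
    threshold: float

    def analysis_counts(self) -> np.ndarray:
        """[common block || super-locus] matrix the tests are run on."""
        sl = self.super_locus[:, None].astype(float)
        if self.common is None:
            return sl
        return np.hstack([self.common.counts, sl])

    def analysis_variant_ids(self) -> np.ndarray:
        ids = [] if self.common is None else list(self.common.variant_ids)
        return np.asarray(ids + ["super_locus"])


def beta_weights(maf, b: float = 1.0, c: float = 25.0) -> WeightVector:
    """w_l = Beta(maf_l; b, c)^2 with defaults (1, 25).

    The admissible range 0 <= b <= 1, c >= 1 keeps the weight monotonically
    increasing as MAF decreases.
    """
    maf = np.asarray(maf, dtype=float).ravel()
    if np.any(maf < 0) or np.any(maf > 0.5):
        raise ValidationError("MAF values must lie in [0, 0.5]")
    if not (0 <= b <= 1 and c >= 1):
        raise ValidationError("Beta parameters must satisfy 0 <= b <= 1 and c >= 1")
    w = beta_dist.pdf(maf, b, c) ** 2
    return WeightVector(w, source="beta_maf")


def collapse_rare(
    g: GenotypeMatrix, threshold: float = RARE_MAF_THRESHOLD
) -> PooledGenotype:
    """Collapse rare variants (maf <= threshold) into a super-locus.

    super_locus_n = min(2, sum over rare l of g_nl), treated as a new SNP
    alongside the common block (maf > threshold). If no variant is rare the
    super-locus is all-zero and a warning is logged.
    """
    rare = np.asarray(g.maf) <= threshold
    if not rare.any():
        logger.warning("no variant with maf <= %g; super-locus is all zero", threshold)
        super_locus = np.zeros(g.n_samples)
    else:
        super_locus = np.minimum(2.0, g.counts[:, rare].sum(axis=1))
    common = g.take_variants(~rare) if (~rare).any() else None
    return PooledGenotype(common, super_locus, threshold)


def exclude_common(
    g: GenotypeMatrix, threshold: float = RARE_MAF_THRESHOLD
) -> GenotypeMatrix:
    """Keep only rare variants (maf <= threshold)."""
    rare = np.asarray(g.maf) <= threshold
    if not rare.any():
        raise EmptyRegionError(
            f"no variants remain with maf <= {threshold}; region is all-common"
        )
    return g.take_variants(rare)


def pooled_analysis_matrix(
    g: GenotypeMatrix,
    pooling: str,
    threshold: float = RARE_MAF_THRESHOLD,
    beta_params=DEFAULT_BETA_PARAMS,
    weights: WeightVector | None = None,
):
    """Genotype matrix + weights actually fed to a similarity-based test.

    Returns ``(X, w)`` where ``X`` is the (N, L') analysis matrix and ``w``
    the per-variant :class:`WeightVector` or None:

    * ``weighting`` — all variants, Beta-MAF weights (or ``weights`` override);
    * ``collapsing`` — [common block || super-locus], unweighted;
    * ``none`` — all variants, unweighted.
    """
    if pooling == "weighting":
        w = weights if weights is not None else beta_weights(g.maf, *beta_params)
        return g.counts, w
    if pooling == "collapsing":
        return collapse_rare(g, threshold).analysis_counts(), None
    if pooling == "none":
        return g.counts, None
    raise ValueError(f"unknown pooling {pooling!r}; choose from {POOLING_STRATEGIES}")
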