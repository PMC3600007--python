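"""Genotype and phenotype containers and readers.

Genotypes are held as an N x L matrix of minor-allele counts. Raw data must
be coded 0/1/2 (missing allowed, mean-imputed per variant); after population
stratification adjustment entries may be real-valued. Columns are always
oriented so that the counted allele is the minor one (sample frequency
<= 0.5), which every downstream weight and pooling rule assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, ParseError, ShapeError, ValidationError

logger = logging.getLogger("rarekernel")

_MISSING_TOKENS = {"na", "nan", ".", "", "-9", "./.", ".|."}


@dataclass
class GenotypeMatrix:
    """Minor-allele-count matrix for N individuals at L variant sites.

    Attributes
    ----------
    counts : (N, L) float array
        Minor-allele counts. Raw data are in {0, 1, 2}; mean imputation of
        missing genotypes and stratification adjustment introduce reals.
    variant_ids : (L,) array of str
    maf : (L,) array
        Per-variant minor allele frequency, ``counts[:, l].sum() / (2 N)``.
    sample_ids : optional (N,) array of str
    n_imputed : int
        Number of missing genotype calls that were mean-imputed at read time.
    raw : bool
        True when every entry is an integer allele count in {0, 1, 2}.
    """

    counts: np.ndarray
    variant_ids: np.ndarray
    maf: np.ndarray
    sample_ids: np.ndarray | None = None
    n_imputed: int = 0
    raw: bool = True

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def take_variants(self, index) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given variant index/mask."""
        return replace(
            self,
            counts=self.counts[:, index],
            variant_ids=np.asarray(self.variant_ids)[index],
            maf=np.asarray(self.maf)[index],
        )


def from_counts(
    counts,
    variant_ids=None,
    sample_ids=None,
    orient: bool = True,
    validate: bool = True,
    n_imputed: int = 0,
) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` from an array of allele counts.

    With ``orient=True`` any column whose counted-allele frequency exceeds 0.5
    is recoded as ``2 - count`` so that counts always refer to the minor
    allele. ``validate=True`` enforces the raw coding {0, 1, 2}.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ShapeError("genotype counts must be a 2-D (samples x variants) array")
    n, L = counts.shape
    if n == 0 or L == 0:
        raise EmptyRegionError("empty genotype matrix")
    if not np.all(np.isfinite(counts)):
        raise ValidationError("genotype counts contain non-finite values")
    raw = bool(np.all((counts == 0) | (counts == 1) | (counts == 2)))
    if validate and not raw:
        bad = np.argwhere(~((counts == 0) | (counts == 1) | (counts == 2)))
        i, j = bad[0]
        raise ValidationError(
            f"genotype entry {counts[i, j]!r} at sample {i}, variant {j} "
            "is outside {0, 1, 2}"
        )
    counts = counts.copy()
    if orient:
        freq = counts.mean(axis=0) / 2.0
        flip = freq > 0.5
        if flip.any():
            counts[:, flip] = 2.0 - counts[:, flip]
    maf = counts.sum(axis=0) / (2.0 * n)
    if variant_ids is None:
        variant_ids = np.array([f"v{l + 1}" for l in range(L)])
    variant_ids = np.asarray(variant_ids)
    if variant_ids.shape[0] != L:
        raise ShapeError("variant_ids length does not match number of variants")
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
        if sample_ids.shape[0] != n:
            raise ShapeError("sample_ids length does not match number of samples")
    return GenotypeMatrix(counts, variant_ids, maf, sample_ids, n_imputed, raw)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequencies maf_l = sum_n g_nl / (2N).

    Assumes counts are minor-allele oriented (every column mean <= 1).
    """
    if g.n_samples == 0:
        raise EmptyRegionError("cannot compute MAF with zero samples")
    return g.counts.sum(axis=0) / (2.0 * g.n_samples)


def drop_monomorphic(g: GenotypeMatrix, keep: bool = False) -> GenotypeMatrix:
    """Drop variants with maf == 0 (they carry no similarity information
    and take the maximal Beta-density weight, which is pathological).

    ``keep=True`` opts in to retaining them.
    """
    if keep:
        return g
    mono = g.maf == 0.0
    if mono.any():
        logger.warning(
            "dropping %d monomorphic variant(s): %s",
            int(mono.sum()),
            ", ".join(map(str, np.asarray(g.variant_ids)[mono][:10])),
        )
        if mono.all():
            raise EmptyRegionError("all variants are monomorphic")
        return g.take_variants(~mono)
    return g


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(
    path, format: str = "auto", allow_real: bool = False
) -> GenotypeMatrix:
    """Read genotypes from a VCF (v4.x, biallelic) or a delimited matrix.

    The matrix format has one header row of variant ids and one leading
    column of sample ids; entries are minor-allele counts in {0, 1, 2}
    (missing as NA/./empty). ``allow_real=True`` accepts real-valued entries
    (e.g. stratification-adjusted genotypes) and skips orientation.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path, allow_real=allow_real)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ParseError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples)
    columns, ids = [], []
    n_imputed = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(split multi-allelic sites before analysis)"
            )
        col = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 ALT copies, 3=missing
        miss = col == 3
        if miss.any():
            obs = col[~miss]
            if obs.size == 0:
                col[:] = 0.0
            else:
                col[miss] = obs.mean()
            n_imputed += int(miss.sum())
        columns.append(col)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if not columns:
        raise EmptyRegionError(f"no variant records in {path}")
    counts = np.column_stack(columns)
    if n_imputed:
        logger.info("mean-imputed %d missing genotype call(s)", n_imputed)
    return from_counts(
        counts,
        variant_ids=np.asarray(ids),
        sample_ids=samples,
        orient=True,
        validate=False,  # imputed entries are real-valued by construction
        n_imputed=n_imputed,
    )


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def _read_matrix(path: str, allow_real: bool = False) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header row and at least one sample row")
    header = _tokenize(lines[0])
    variant_ids = np.asarray(header[1:])
    L = len(variant_ids)
    if L == 0:
        raise ParseError(f"{path}: header row names no variants")
    sample_ids, rows = [], []
    n_imputed = 0
    for lineno, line in enumerate(lines[1:], start=2):
        toks = _tokenize(line)
        if len(toks) != L + 1:
            raise ParseError(
                f"{path}: line {lineno} has {len(toks)} fields, expected {L + 1}"
            )
        sample_ids.append(toks[0])
        row = np.empty(L)
        for j, tok in enumerate(toks[1:]):
            if tok.lower() in _MISSING_TOKENS:
                row[j] = np.nan
                continue
            try:
                row[j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: cannot parse genotype {tok!r}"
                ) from None
            if not allow_real and row[j] not in (0.0, 1.0, 2.0):
                raise ValidationError(
                    f"{path}: line {lineno}: genotype {tok!r} for variant "
                    f"{variant_ids[j]} is outside {{0, 1, 2, missing}}"
                )
        rows.append(row)
    counts = np.vstack(rows)
    miss = np.isnan(counts)
    if miss.any():
        n_imputed = int(miss.sum())
        colmean = np.nanmean(np.where(miss, np.nan, counts), axis=0)
        colmean = np.nan_to_num(colmean)
        counts[miss] = np.take(colmean, np.nonzero(miss)[1])
        logger.info("mean-imputed %d missing genotype call(s)", n_imputed)
    return from_counts(
        counts,
        variant_ids=variant_ids,
        sample_ids=np.asarray(sample_ids),
        orient=not allow_real,
        validate=False,
        n_imputed=n_imputed,
    )


def write_matrix(g: GenotypeMatrix, path, fmt: str = "%.10g") -> None:
    """Write the delimited matrix format read back by :func:`read_genotypes`."""
    sample_ids = (
        g.sample_ids
        if g.sample_ids is not None
        else np.array([f"s{i + 1}" for i in range(g.n_samples)])
    )
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, g.variant_ids)) + "\n")
        for sid, row in zip(sample_ids, g.counts):
            fh.write(str(sid) + "\t" + "\t".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeVector:
    """Length-N phenotype with an explicit coding.

    ``coding`` is one of ``plus_minus_one`` (1 case / -1 control),
    ``zero_one`` (1 case / 0 control) or ``quantitative``.
    """

    values: np.ndarray
    coding: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ShapeError("phenotype must be one-dimensional")
        allowed = {"plus_minus_one": {1.0, -1.0}, "zero_one": {1.0, 0.0}}
        if self.coding in allowed:
            vals = set(np.unique(self.values))
            if not vals <= allowed[self.coding]:
                raise ValidationError(
                    f"values {sorted(vals)} incompatible with coding {self.coding}"
                )
        elif self.coding != "quantitative":
            raise ValidationError(f"unknown phenotype coding {self.coding!r}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def is_binary(self) -> bool:
        return self.coding in ("plus_minus_one", "zero_one")

    @property
    def n_cases(self) -> int:
        self._require_binary()
        return int(np.sum(self.values == 1.0))

    @property
    def n_controls(self) -> int:
        self._require_binary()
        return self.n - self.n_cases

    def _require_binary(self):
        if not self.is_binary:
            raise ValidationError("operation requires a binary phenotype")

    def to_zero_one(self) -> np.ndarray:
        self._require_binary()
        return (self.values == 1.0).astype(float)

    def to_plus_minus(self) -> np.ndarray:
        self._require_binary()
        return np.where(self.values == 1.0, 1.0, -1.0)

    @classmethod
    def binary(cls, values) -> "PhenotypeVector":
        """Infer the binary coding from the observed label set."""
        values = np.asarray(values, dtype=float)
        vals = set(np.unique(values))
        if vals <= {1.0, -1.0}:
            return cls(values, "plus_minus_one")
        if vals <= {1.0, 0.0}:
            return cls(values, "zero_one")
        raise ValidationError(f"cannot infer binary coding from labels {sorted(vals)}")

    @classmethod
    def quantitative(cls, values) -> "PhenotypeVector":
        return cls(values, "quantitative")


def read_phenotypes(path, column: str | None = None, sample_ids=None) -> PhenotypeVector:
    """Read a phenotype from a delimited table keyed by a sample-id column.

    The first column is the sample id; ``column`` selects the phenotype
    (default: the second column). If ``sample_ids`` is given, rows are
    aligned to it and missing samples raise.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a sample-id column plus phenotype column")
    df = df.set_index(df.columns[0])
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise ParseError(f"{path}: no phenotype column {col!r}")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ParseError(f"{path}: no phenotype for samples {missing[:5]}")
        series = df.loc[list(sample_ids), col]
    else:
        series = df[col]
    values = series.to_numpy(dtype=float)
    try:
        return PhenotypeVector.binary(values)
    except ValidationError:
        return PhenotypeVector.quantitative(values)


def read_covariates(path, columns=None, sample_ids=None) -> np.ndarray:
    """Read covariates (N x p) from a delimited table keyed by sample id."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    if columns is not None:
        df = df[list(columns)]
    if sample_ids is not None:
        df = df.loc[list(sample_ids)]
    return df.to_numpy(dtype=float)
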