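# Methods

This note documents the statistical procedures implemented in `rarekernel`,
the numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Similarity kernels

A region of L variants for N individuals is represented by the minor-allele
count matrix G (entries 0/1/2; real-valued after adjustment). All tests
consume an N × N similarity matrix K = {s(g_n, g_m)}. Implemented kernels:

| kernel      | s(g_n, g_m)                                   | notes |
|-------------|------------------------------------------------|-------|
| exponential | exp(−Σ_l (g_nl − g_ml)²)                       | default; Gaussian kernel of the genotype Euclidean distance, PSD for any real input, defined for adjusted genotypes |
| weighted exponential | exp(−Σ_l w_l (g_nl − g_ml)² / Σ_l w_l) | the weight normalization sits **inside** the exponent; this changes values, not just scale, so it is implemented exactly rather than as post-hoc matrix scaling |
| weighted IBS | Σ_l w_l (2 − \|g_nl − g_ml\|)                 | allele sharing; defined on integer genotype codes only and rejected otherwise |
| weighted linear / quadratic | Σ w_l g_nl g_ml / (1 + Σ w_l g_nl g_ml)² | for sensitivity analyses |

`build_similarity_matrix` verifies symmetry and positive semi-definiteness
(smallest eigenvalue ≥ −1e−8 × largest). The permutation engine skips this
O(N³) check for the exponential kernel, which is PSD by construction. With
equal weights the weighted exponential kernel equals the unweighted kernel
with squared distances scaled by 1/L; this identity (to 1e−12) is a test.

## Pooling strategies

*Weighting*: w_l = Beta(maf_l; 1, 25)², the squared Beta(1, 25) density at
the variant's MAF (625 at maf = 0, ≈ 386 at 1%, ≈ 2e−12 at 50%), strictly
decreasing on [0, 0.5]. Parameters (b, c) are configurable within
0 ≤ b ≤ 1, c ≥ 1, which preserves monotonicity. All variants, rare and
common, enter the kernel under weighting. For MDMR, SKAT and the U-test the
weights act inside the kernel; for KBAT they multiply the per-SNP BSS/WSS
terms (KBAT_W), because KBAT never forms a multi-site kernel.

*Collapsing*: the super-locus g_{n,L+1} = min(2, Σ_{l: maf_l ≤ 0.01} g_nl)
replaces the rare variants and is analysed **unweighted** alongside the
common variants. The boundary convention is rare ⇔ maf ≤ 0.01, common ⇔
maf > 0.01, one threshold constant (default 0.01, configurable). The two
strategies are mutually exclusive: the super-locus is never Beta-weighted.

Monomorphic variants (maf = 0) are dropped with a logged warning before
either strategy — they carry no similarity information and would take the
maximal Beta weight; `drop_monomorphic(keep=True)` opts back in.
`exclude_common` restricts a region to its rare variants for
"rare-only" analyses, in which collapsing reduces to testing the super-locus
alone.

## Test statistics and permutation inference

The four statistics are defined in the package docstrings (MDMR pseudo-F,
SKAT quadratic form, U-test squared mean-similarity gap, KBAT similarity
ANOVA). Conventions that required a decision:

* **Pair sums** run over unordered pairs n < m; the diagonal
  (self-similarity) is excluded. Denominators are N_A(N_A − 1) (no factor
  2): any consistent constant rescaling of the within-group averages leaves
  the squared-difference and ratio statistics' permutation p-values
  unchanged, so the absolute U and KBAT values are defined up to that
  convention.
* **KBAT BSS** uses pair-group sizes N_A(N_A−1)/2 and N_U(N_U−1)/2 as the
  between-group weights.
* **MDMR centering** is the standard Gower double-centering
  Gc = C A C with C = I − 11ᵀ/N on both sides; the phenotype projection
  H = Y(YᵀY)⁻¹Yᵀ uses the ±1 coding without an intercept, so H = yyᵀ/N.
* **Degenerate inputs**: an all-ones K (zero dissimilarity everywhere)
  makes the MDMR denominator trace vanish and raises
  `DegenerateStatisticError`; all-zero within-group similarity variance
  raises for KBAT; groups smaller than 2 raise for the pairwise statistics.
  An all-case or all-control SKAT input yields exactly 0 and is logged.

P-values use the add-one estimator p = (1 + #{permuted ≥ observed})/(B + 1),
which cannot return 0 and counts ties toward the tail; B = 1000 by default,
so the resolution floor is 1/1001 ≈ 0.001. All randomness flows from one
user-supplied seed. Within a run one permutation set is shared across
methods and pooling strategies, so comparisons between them are paired —
this removes a layer of Monte-Carlo noise from power differences.

### Vectorized evaluation

The permutation engine evaluates all B + 1 labelings simultaneously.
Within-group pair sums of K for every labeling come from K·C where C is the
N × (B+1) case-indicator matrix; SKAT and the U-test are direct functions of
those sums. For the ±1 phenotype MDMR reduces algebraically (H = yyᵀ/N,
H idempotent) to num = yᵀGc y / N and den = tr(Gc) − num, which the tests
verify against the explicit trace formula. For KBAT, each single-SNP kernel
factors as K_l = E V Eᵀ with E the one-hot encoding of the distinct genotype
values of column l and V the kernel on those values, so every within-group
sum (and sum of squares, via V∘V) is a quadratic form in the per-group
genotype-value counts EᵀC. For balanced designs SKAT and MDMR are monotone
transforms of the sum and the sum of squares of case–control pair
dissimilarities respectively; the acceptance suite checks that the
permutation p-values coincide exactly with brute-force oracles built on
those sums.

## Stratification and covariate adjustment

For multi-population samples: (1) genotype columns are centered and scaled
by √(2p(1−p)) before an SVD, and the top k = 10 left singular vectors R are
retained (rank deficiencies truncate k with a warning); (2) genotypes,
phenotypes and covariates are projected as x − RRᵀx; (3) the adjusted
phenotype is residualized on an intercept plus the adjusted covariates by
OLS; (4) residuals are dichotomized, the ⌈0.30 N⌉ largest becoming cases,
with ties at the cutoff broken by stable index order and logged. Binary
traits are adjusted, residualized and re-dichotomized through the identical
path as quantitative ones. Adjusted genotypes are real-valued, which is the
reason the exponential kernel is the package default; the IBS kernel is
restricted to raw codes.

## Synthetic-data generator

Study conditions default to 500 cases / 500 controls and L = 50 variants per
region. Per-variant population MAFs are drawn from a mixture: rare with
probability 0.8, log-uniform on [0.001, 0.01]; otherwise common, log-uniform
on (0.01, 0.5] (log-uniform approximates the 1/x shape of a neutral
site-frequency spectrum at desk scale). Genotypes are binomial(2, maf) under
Hardy–Weinberg with independent sites. Disease status follows a logistic
model on the causal burden, logit P(case) = logit(0.2) + Σ β_l g_l, and
individuals are drawn retrospectively until the case and control quotas are
met (a draw cap raises `SamplingLimitError` for degenerate penetrance).
Replicates are bit-reproducible from (config, seed, replicate_id).

Scenario presets (per-allele log odds ratios, chosen a priori to put the
favoured strategy's power in a readable mid-to-high range at N = 1000 rather
than at either saturation point):

| scenario    | rare effect  | common effect | causal fractions (rare/common) |
|-------------|--------------|---------------|-------------------------------|
| risk_rare   | log 4        | —             | 0.5 / 0                       |
| risk_both   | log 2.5      | log 1.3       | 0.5 / 0.5                     |
| risk_common | log 1.2      | log 1.8       | 0.2 / 0.5                     |
| mixed_rare  | ±log 4 (half protective) | — | 0.5 / 0                       |
| null        | 0            | 0             | 0 / 0                         |

What the generator does **not** emulate: linkage disequilibrium (sites are
independent; a block-correlation option was considered and left out of the
defaults), recurrent-mutation site-frequency detail, demographic history,
and any population substructure. Consequently the simulation studies here
support *relative* statements — type-I error control, and which pooling
strategy wins under which causal architecture — not the absolute power
values a forward population-genetics simulation or a real exome data set
would give. The per-gene results of such data are outside this package's
scope.

## Type-I error, power, and calibration checks

Power at level α is the fraction of replicates with p ≤ α over the grid
{0.001, 0.002, 0.005, 0.01, 0.02, 0.05}; the lower end matches the B = 1000
permutation resolution. The binomial-normal CI
nominal ± z_{(1+c)/2}·√(nominal(1−nominal)/n) gives (0.010, 0.090) at
nominal 0.05 with n = 200 replicates and 99% confidence, and
(0.032, 0.068) at n = 1000; reporting rounds to two significant figures,
raw values are kept. `max_abs_power_difference` is the largest gap between
the weighting and collapsing power curves over the α grid.

Problem sizes used by the shipped studies: the null calibration runs 200
replicates at B = 1000 (the full study conditions); the qualitative
pooling-ordering checks run 200 replicates per scenario at B = 500 and the
MDMR weight-exponent sweep 100 replicates on the grid p ∈ {0, 0.5, 1} —
power at α = 0.05 is insensitive to the permutation count at these
resolutions, and the ordering assertions carry two-standard-error
Monte-Carlo slack on the paired difference. The weight-exponent sweep raises
the Beta weights to w^p, so p = 0 is the uniform-weight analysis (the
normalized kernel with equal weights, not the unnormalized one) and p = 1
the full Beta weighting.

## Known limitations

* Permutation-only inference: the asymptotic weighted-χ² distribution of the
  SKAT statistic is not implemented, so genome-wide significance levels
  would need prohibitively many permutations; the intended use is candidate
  regions.
* Prospective covariate adjustment inside the tests (score-test style) is
  not provided; covariates are handled by the residualization pipeline.
* The U-test and KBAT absolute statistic values depend on the
  unordered-pair denominator convention (see above); p-values do not.
* VCF input is restricted to biallelic records; split multi-allelic sites
  upstream. Missing genotypes are mean-imputed per variant and counted.
* No family data, no BGEN/PLINK formats, no variant annotation.
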