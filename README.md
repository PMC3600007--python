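# rarekernel

Similarity-based association testing for rare genomic variants, with the two
standard rare-variant pooling strategies and a simulation harness for
comparing them.

## The problem

Single-variant association tests have essentially no power against rare
alleles (MAF ≤ 1%): each variant is seen in a handful of carriers. Regional
tests therefore pool the variants of a gene or window. A flexible family of
such tests works on the N × N **genotype similarity matrix**
K = {s(g_n, g_m)}, where g_n is the vector of minor-allele counts of
individual n across the L variants of the region and s is a positive
semi-definite kernel — by default the exponential (Gaussian) kernel

    s(g_n, g_m) = exp(−Σ_l (g_nl − g_ml)²)

or its weighted form exp(−Σ_l w_l (g_nl − g_ml)² / Σ_l w_l). Four tests built
on K are implemented:

* **MDMR** — distance-matrix regression: with H = Y(YᵀY)⁻¹Yᵀ the projection
  onto the ±1 phenotype and Gc the Gower-centered matrix of −d²/2
  (d = 1 − K), the pseudo-F statistic tr(H Gc H)/tr((I−H) Gc (I−H)).
* **SKAT** — the quadratic form T = (Y − Ȳ)ᵀ K (Y − Ȳ)/2 with 1/0 coding.
* **U-test** — U = (U₁ − U₀)², the squared gap between the average
  within-case and within-control pairwise similarity.
* **KBAT** — Σ_l BSS_l / Σ_l WSS_l, a per-SNP between/within analysis of
  variance of pairwise similarities (weighted form KBAT_W with per-SNP
  weights in the statistic).

Significance is always by phenotype-label permutation with the add-one
estimator p = (1 + #{perm ≥ obs})/(B + 1), B = 1000 by default.

Two **pooling strategies** concentrate the analysis on rare variation:

* *weighting* — every variant enters the kernel with weight
  w_l = Beta(maf_l; 1, 25)², which grows steeply as MAF falls;
* *collapsing* — rare variants (MAF ≤ 1%) are summed into one super-locus
  min(2, Σ rare counts) analysed unweighted next to the common variants.

The package also provides population-stratification adjustment (genotype
PCA projection, covariate residualization, upper-30% dichotomization) and a
synthetic-data generator with five causal architectures (risk in rare
variants, in both classes, in common variants, mixed-sign rare effects, and
a null) for type-I-error and power studies.

## Worked example

`examples/02_pooling_strategies.py` simulates two 500-sample regions and
runs SKAT under both pooling strategies:

```
risk_rare: 50 variants (39 rare -> 1 super-locus + 11 common)
  Beta(1,25)^2 weight range: 0.781 (common) .. 625 (rare)
  SKAT under weighting : p = 0.01898
  SKAT under collapsing: p = 0.1329

mixed_rare: 50 variants (39 rare -> 1 super-locus + 11 common)
  Beta(1,25)^2 weight range: 0.321 (common) .. 625 (rare)
  SKAT under weighting : p = 0.003996
  SKAT under collapsing: p = 0.992
```

With risk confined to rare alleles, weighting finds the signal that the
super-locus dilutes; with mixed risk/protective rare alleles the super-locus
sums opposing effects to nearly zero (p ≈ 1) while the kernel distance still
separates cases from controls. The other examples cover the four tests on
one region, a type-I-error/power study, and stratification adjustment.

Library use is one call:

```python
from rarekernel import generate_replicate, run_all_tests, scenario_config

rep = generate_replicate(scenario_config("risk_rare"), seed=7)
res = run_all_tests(rep.genotypes, rep.phenotype, B=1000, seed=1)
print(res["weighting"]["skat"].p_value)
```

A thin CLI mirrors the library: `rarekernel test|simulate|power|adjust`
(see `rarekernel --help`); every output file gets a JSON manifest with the
seed and configuration needed to regenerate it exactly.

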