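"""Small type-I error and power study.

Estimates (at reduced scale for a quick run) the empirical type-I error of
every test x pooling combination under the null, checks it against the
binomial-normal 99% confidence band, and compares power between the two
pooling strategies in the risk_common scenario, where collapsing should win
because Beta-MAF weighting suppresses the causal common variants.
"""

from rarekernel import (
    empirical_type1_error,
    max_abs_power_difference,
    run_power_study,
    type1_error_ci,
)

N_REP, B = 50, 200

rates = empirical_type1_error(
    n_replicates=N_REP, B=B, seed=5, n_cases=100, n_controls=100, n_variants=30
)
lo, hi = type1_error_ci(0.05, N_REP, confidence=0.99)
print(f"null rejection rates at alpha = 0.05 (99% band: {lo:.3f} - {hi:.3f}):")
for (method, pooling), rate in sorted(rates.items()):
    flag = "ok" if lo <= rate <= hi else "outside band"
    print(f"  {method:6s} {pooling:10s} {rate:.3f}  {flag}")

curves = run_power_study(
    "risk_common", n_replicates=N_REP, B=B, seed=5,
    n_cases=100, n_controls=100, n_variants=30,
)
print("\nrisk_common power at alpha = 0.05 and max |power difference| over the grid:")
for method in ("mdmr", "skat", "utest", "kbat"):
    cw = curves[(method, "weighting")]
    cc = curves[(method, "collapsing")]
    gap = max_abs_power_difference(cw, cc)
    print(f"  {method:6s} weighting {cw.at(0.05):.2f}  collapsing {cc.at(0.05):.2f}"
          f"  max|diff| {gap:.2f}")

print("\nThe pooling choice can move power by tens of percentage points;")
print("under common-variant signal, collapsing preserves it while weighting")
print("down-weights exactly the variants that matter.")
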