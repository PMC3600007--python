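"""Type-I error and power estimation over simulation replicates.

Power at significance level alpha is the fraction of replicates whose
permutation p-value is <= alpha; type-I error is the same quantity under the
null scenario. The binomial-normal confidence interval
nominal ± z * sqrt(nominal (1 - nominal) / n) calibrates how far an
empirical type-I error may drift from the nominal level by Monte-Carlo
chance alone. The maximum absolute power difference between the two pooling
strategies, max_alpha |power_w(alpha) - power_c(alpha)|, summarises how much
the pooling choice matters for a given test and scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .association import DEFAULT_PERMUTATIONS, METHODS, _perm_case_matrix, run_all_tests
from .errors import ShapeError, ValidationError
from .genotype_io import drop_monomorphic
from .simulate import ScenarioConfig, generate_replicate, scenario_config

#: Significance grid; the lower end matches the 1/(B+1) resolution of
#: B = 1000 permutations.
DEFAULT_ALPHAS = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05)


@dataclass
class PowerCurve:
    """Power as a function of significance level for one test/pooling/scenario."""

    alphas: np.ndarray
    power: np.ndarray
    method: str = ""
    pooling: str = ""
    scenario: str = ""
    n_replicates: int = 0
    p_values: np.ndarray | None = None

    def at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.alphas - alpha)))
        if not np.isclose(self.alphas[idx], alpha):
            raise ValidationError(f"alpha {alpha} not on the grid {self.alphas}")
        return float(self.power[idx])


def estimate_power(p_values, alphas=DEFAULT_ALPHAS, **meta) -> PowerCurve:
    """power(alpha) = #{p <= alpha} / n_replicates over one batch of p-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValidationError("no p-values supplied")
    alphas = np.asarray(alphas, dtype=float)
    power = np.array([np.mean(p <= a) for a in alphas])
    meta.setdefault("n_replicates", p.size)
    return PowerCurve(alphas, power, p_values=p, **meta)


def max_abs_power_difference(curve_w: PowerCurve, curve_c: PowerCurve) -> float:
    """max over the alpha grid of |power_w - power_c|."""
    if not np.array_equal(curve_w.alphas, curve_c.alphas):
        raise ShapeError("power curves must share the same alpha grid")
    return float(np.max(np.abs(curve_w.power - curve_c.power)))


def type1_error_ci(
    nominal: float, n_replicates: int, confidence: float = 0.99
) -> tuple[float, float]:
    """Binomial-normal CI for an empirical type-I error estimate.

    nominal ± z_{(1+confidence)/2} sqrt(nominal (1-nominal) / n), clipped to
    [0, 1]. Raw bounds are returned; use :func:`format_ci` for the
    2-significant-figure reporting convention.
    """
    if not 0.0 < nominal < 1.0:
        raise ValidationError("nominal level must be in (0, 1)")
    if n_replicates < 1:
        raise ValidationError("need at least one replicate")
    z = norm.ppf(0.5 * (1.0 + confidence))
    half = z * np.sqrt(nominal * (1.0 - nominal) / n_replicates)
    return (max(0.0, nominal - half), min(1.0, nominal + half))


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def format_ci(ci: tuple[float, float], sig: int = 2) -> tuple[float, float]:
    """Round CI bounds to ``sig`` significant figures for reporting."""
    return (_round_sig(ci[0], sig), _round_sig(ci[1], sig))


# ---------------------------------------------------------------------------
# simulation studies


def run_power_study(
    scenario,
    n_replicates: int = 200,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    methods=METHODS,
    poolings=("weighting", "collapsing"),
    kernel: str = "exponential",
    alphas=DEFAULT_ALPHAS,
    weight_exponent: float = 1.0,
    **config_overrides,
) -> dict:
    """Estimate power curves for every method x pooling combination.

    ``scenario`` is a name or a :class:`ScenarioConfig`. Each replicate draws
    a fresh region and phenotype; its permutation set is shared across
    methods and poolings (paired comparisons). Returns
    ``{(method, pooling): PowerCurve}``.
    """
    config = (
        scenario
        if isinstance(scenario, ScenarioConfig)
        else scenario_config(scenario, **config_overrides)
    )
    pvals = {(m, p): np.empty(n_replicates) for m in methods for p in poolings}
    for rep_id in range(n_replicates):
        rep = generate_replicate(config, seed, rep_id)
        perm_rng = np.random.default_rng([seed, rep_id, 1])
        g = drop_monomorphic(rep.genotypes)
        C = _perm_case_matrix(rep.phenotype.to_zero_one(), B, perm_rng)
        res = run_all_tests(
            g,
            rep.phenotype,
            methods=methods,
            poolings=poolings,
            kernel=kernel,
            B=B,
            seed=seed,
            weight_exponent=weight_exponent,
            case_matrix=C,
        )
        for pooling, per_pool in res.items():
            for method, tr in per_pool.items():
                pvals[(method, pooling)][rep_id] = tr.p_value
    return {
        key: estimate_power(
            p,
            alphas,
            method=key[0],
            pooling=key[1],
            scenario=config.name,
            n_replicates=n_replicates,
        )
        for key, p in pvals.items()
    }


def empirical_type1_error(
    n_replicates: int = 200,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alpha: float = 0.05,
    methods=METHODS,
    poolings=("weighting", "collapsing"),
    **config_overrides,
) -> dict:
    """Empirical type-I error at ``alpha`` under the null scenario.

    Returns ``{(method, pooling): fraction of replicates with p <= alpha}``.
    """
    curves = run_power_study(
        "null",
        n_replicates=n_replicates,
        B=B,
        seed=seed,
        methods=methods,
        poolings=poolings,
        alphas=(alpha,),
        **config_overrides,
    )
    return {key: float(curve.power[0]) for key, curve in curves.items()}


def weight_exponent_sweep(
    scenario="risk_rare",
    p_grid=(0.0, 0.5, 1.0),
    n_replicates: int = 100,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alphas=DEFAULT_ALPHAS,
    method: str = "mdmr",
    **config_overrides,
) -> dict:
    """Power of the weighted test as the Beta-MAF weights are raised to p.

    ``p = 0`` reproduces the uniform-weight analysis, ``p = 1`` the full
    Beta-density weighting; intermediate p interpolates the relative emphasis
    on rare variants. Permutation sets are shared across grid points.
    Returns ``{p: PowerCurve}``.
    """
    p_grid = tuple(float(p) for p in p_grid)
    if 0.0 not in p_grid or 1.0 not in p_grid:
        raise ValidationError("p_grid must include the endpoints 0 and 1")
    config = (
        scenario
        if isinstance(scenario, ScenarioConfig)
        else scenario_config(scenario, **config_overrides)
    )
    pvals = {p: np.empty(n_replicates) for p in p_grid}
    for rep_id in range(n_replicates):
        rep = generate_replicate(config, seed, rep_id)
        perm_rng = np.random.default_rng([seed, rep_id, 1])
        g = drop_monomorphic(rep.genotypes)
        C = _perm_case_matrix(rep.phenotype.to_zero_one(), B, perm_rng)
        for p in p_grid:
            res = run_all_tests(
                g,
                rep.phenotype,
                methods=(method,),
                poolings=("weighting",),
                B=B,
                seed=seed,
                weight_exponent=p,
                case_matrix=C,
            )
            pvals[p][rep_id] = res["weighting"][method].p_value
    return {
        p: estimate_power(
            v,
            alphas,
            method=method,
            pooling=f"weighting^p={p:g}",
            scenario=config.name,
            n_replicates=n_replicates,
        )
        for p, v in pvals.items()
    }
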