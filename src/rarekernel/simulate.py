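"""Synthetic genotype/phenotype replicates for power and type-I-error studies.

The generator emulates a resequenced region dominated by rare variation:
per-variant population MAFs are drawn from a log-uniform mixture (a
configurable majority, 80% by default, below 1%; the rest between 1% and
50%), genotypes are binomial(2, maf) under Hardy-Weinberg with independent
sites, and disease status follows a logistic model on the causal-allele
burden. Cases and controls are sampled retrospectively until the requested
group sizes are reached.

Five causal architectures are provided:

* ``risk_rare``   — risk effects at a fraction of the rare variants only;
* ``risk_both``   — moderate rare effects plus weak common effects;
* ``risk_common`` — strong common effects plus weak rare effects;
* ``mixed_rare``  — rare effects of both signs (risk and protective);
* ``null``        — no genetic effect (type-I error calibration).

This is a deliberately simple stand-in for a forward population-genetics
simulation: it reproduces which variant class carries signal and in which
direction, not the linkage and site-frequency detail of a demographic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .errors import SamplingLimitError, ValidationError
from .genotype_io import GenotypeMatrix, PhenotypeVector, from_counts

SCENARIOS = ("risk_rare", "risk_both", "risk_common", "mixed_rare", "null")

#: per-scenario log-odds-ratio presets (see docs/methods.md for rationale)
_PRESETS = {
    "null": dict(
        rare_effect=0.0, common_effect=0.0,
        causal_rare_fraction=0.0, causal_common_fraction=0.0,
        protective_fraction=0.0,
    ),
    "risk_rare": dict(
        rare_effect=math.log(4.0), common_effect=0.0,
        causal_rare_fraction=0.5, causal_common_fraction=0.0,
        protective_fraction=0.0,
    ),
    "risk_both": dict(
        rare_effect=math.log(2.5), common_effect=math.log(1.3),
        causal_rare_fraction=0.5, causal_common_fraction=0.5,
        protective_fraction=0.0,
    ),
    "risk_common": dict(
        rare_effect=math.log(1.2), common_effect=math.log(1.8),
        causal_rare_fraction=0.2, causal_common_fraction=0.5,
        protective_fraction=0.0,
    ),
    "mixed_rare": dict(
        rare_effect=math.log(4.0), common_effect=0.0,
        causal_rare_fraction=0.5, causal_common_fraction=0.0,
        protective_fraction=0.5,
    ),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated disease scenario."""

    name: str
    n_cases: int = 500
    n_controls: int = 500
    n_variants: int = 50
    rare_fraction: float = 0.8
    rare_maf_range: tuple = (0.001, 0.01)
    common_maf_range: tuple = (0.01, 0.5)
    rare_effect: float = 0.0
    common_effect: float = 0.0
    causal_rare_fraction: float = 0.0
    causal_common_fraction: float = 0.0
    protective_fraction: float = 0.0
    baseline_prevalence: float = 0.2

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.name!r}; one of {SCENARIOS}")
        if self.name == "null" and (self.rare_effect or self.common_effect):
            raise ValidationError("null scenario must have all effects zero")
        if self.name == "mixed_rare":
            if not 0.0 < self.protective_fraction < 1.0:
                raise ValidationError(
                    "mixed_rare needs protective_fraction in (0, 1)"
                )
        elif self.protective_fraction != 0.0:
            raise ValidationError(
                "protective_fraction applies to the mixed_rare scenario only"
            )
        if self.name != "mixed_rare" and (
            self.rare_effect < 0 or self.common_effect < 0
        ):
            raise ValidationError("risk scenarios must have non-negative effects")
        if min(self.n_cases, self.n_controls) < 2 or self.n_variants < 1:
            raise ValidationError("need >= 2 cases, >= 2 controls, >= 1 variant")


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Preset :class:`ScenarioConfig` for a named scenario, with overrides."""
    if name not in _PRESETS:
        raise ValidationError(f"unknown scenario {name!r}; one of {SCENARIOS}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return ScenarioConfig(name=name, **params)


@dataclass
class Replicate:
    """One simulated data set plus its causal ground truth."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    causal_flags: np.ndarray  # per-variant {"risk", "protective", "neutral"}
    replicate_id: int
    seed: int


def sample_maf_spectrum(
    L: int, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw L population MAFs from the rare-skewed log-uniform mixture.

    Each variant is rare with probability ``config.rare_fraction``; rare and
    common MAFs are log-uniform on their respective ranges.
    """
    if L < 1:
        raise ValidationError("need at least one variant")
    is_rare = rng.random(L) < config.rare_fraction
    lo_r, hi_r = config.rare_maf_range
    lo_c, hi_c = config.common_maf_range
    maf = np.empty(L)
    maf[is_rare] = np.exp(
        rng.uniform(np.log(lo_r), np.log(hi_r), size=int(is_rare.sum()))
    )
    maf[~is_rare] = np.exp(
        rng.uniform(np.log(lo_c), np.log(hi_c), size=int((~is_rare).sum()))
    )
    return maf


def _assign_effects(maf, config: ScenarioConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    L = maf.size
    beta = np.zeros(L)
    flags = np.full(L, "neutral", dtype=object)
    rare_idx = np.nonzero(maf <= 0.01)[0]
    common_idx = np.nonzero(maf > 0.01)[0]
    k_rare = int(round(config.causal_rare_fraction * rare_idx.size))
    if k_rare and config.rare_effect:
        chosen = rng.choice(rare_idx, size=k_rare, replace=False)
        beta[chosen] = config.rare_effect
        flags[chosen] = "risk"
        if config.protective_fraction > 0:
            n_prot = int(round(config.protective_fraction * k_rare))
            prot = rng.choice(chosen, size=n_prot, replace=False)
            beta[prot] = -config.rare_effect
            flags[prot] = "protective"
    k_common = int(round(config.causal_common_fraction * common_idx.size))
    if k_common and config.common_effect:
        chosen = rng.choice(common_idx, size=k_common, replace=False)
        beta[chosen] = config.common_effect
        flags[chosen] = "risk"
    return beta, flags.astype(str)


#: cap on retrospective draws, as a multiple of the target sample size
_MAX_DRAW_FACTOR = 2000


def generate_replicate(
    config: ScenarioConfig, seed: int, replicate_id: int = 0
) -> Replicate:
    """Generate one replicate; bit-reproducible given (config, seed, id)."""
    rng = np.random.default_rng([seed, replicate_id])
    maf = sample_maf_spectrum(config.n_variants, config, rng)
    beta, flags = _assign_effects(maf, config, rng)
    b0 = logit(config.baseline_prevalence)
    n_total = config.n_cases + config.n_controls
    case_rows, ctrl_rows = [], []
    n_case = n_ctrl = 0
    drawn = 0
    batch = max(2 * n_total, 512)
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if drawn >= _MAX_DRAW_FACTOR * n_total:
            raise SamplingLimitError(
                f"could not reach {config.n_cases} cases / "
                f"{config.n_controls} controls within {drawn} draws "
                "(degenerate penetrance?)"
            )
        G = rng.binomial(2, maf, size=(batch, maf.size)).astype(float)
        prob = expit(b0 + G @ beta)
        status = rng.random(batch) < prob
        drawn += batch
        if n_case < config.n_cases:
            need = config.n_cases - n_case
            rows = G[status][:need]
            case_rows.append(rows)
            n_case += rows.shape[0]
        if n_ctrl < config.n_controls:
            need = config.n_controls - n_ctrl
            rows = G[~status][:need]
            ctrl_rows.append(rows)
            n_ctrl += rows.shape[0]
    counts = np.vstack(case_rows + ctrl_rows)
    y = np.concatenate(
        [np.ones(config.n_cases), np.zeros(config.n_controls)]
    )
    genotypes = from_counts(counts, orient=True, validate=False)
    return Replicate(
        genotypes=genotypes,
        phenotype=PhenotypeVector(y, "zero_one"),
        causal_flags=flags,
        replicate_id=replicate_id,
        seed=seed,
    )


def generate_replicates(config: ScenarioConfig, n_replicates: int, seed: int):
    """Yield ``n_replicates`` independent replicates with ids 0..n-1."""
    for rep_id in range(n_replicates):
        yield generate_replicate(config, seed, rep_id)
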