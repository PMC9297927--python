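"""Brood bookkeeping statistics of the inbreeding experiment.

A brood record is one mother's offspring and host outcome counts. Because
unmated haplodiploid females produce all-male (haploid) broods, all-male
broods are classified and excluded before sex-ratio analysis. The module
also provides the detection-power calculus for diploid males: the
probability of finding zero diploid males among ``n`` tested males when a
fraction ``d`` of males is expected to be diploid.

Brood CSV schema (header required, optional cells blank):

    mother_id,group,generation,n_female_adults,n_male_adults,
    n_flies_emerged,n_fly_pupae_unemerged,n_hosts,
    n_dead_wasps_female,n_dead_wasps_male
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import SimulationSummary

__all__ = [
    "BROOD_COLUMNS",
    "ProportionResult",
    "MeanResult",
    "proportion_result",
    "brood_category",
    "classify_all_male",
    "all_male_proportion",
    "exclude_all_male",
    "sex_ratio",
    "emergence_proportions",
    "compare_proportions",
    "dead_wasp_female_proportion",
    "zero_diploid_probability",
    "zero_diploid_probability_aggregate",
    "power_from_simulation",
]

BROOD_COLUMNS = [
    "mother_id",
    "group",
    "generation",
    "n_female_adults",
    "n_male_adults",
    "n_flies_emerged",
    "n_fly_pupae_unemerged",
    "n_hosts",
    "n_dead_wasps_female",
    "n_dead_wasps_male",
]


@dataclass(frozen=True)
class ProportionResult:
    """A count proportion with an exact (Clopper-Pearson) 95% interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MeanResult:
    mean: float
    se: float
    n: int


def proportion_result(
    numerator: int, denominator: int, confidence: float = 0.95
) -> ProportionResult:
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    ci = stats.binomtest(numerator, denominator).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return ProportionResult(
        numerator=int(numerator),
        denominator=int(denominator),
        proportion=numerator / denominator,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def brood_category(record: Mapping) -> str:
    """'no_offspring', 'all_male', or 'daughter_producing'."""
    nf = int(record["n_female_adults"])
    nm = int(record["n_male_adults"])
    if nf == 0 and nm == 0:
        return "no_offspring"
    if nf == 0:
        return "all_male"
    return "daughter_producing"


def classify_all_male(record: Mapping) -> bool:
    """True iff the brood yielded males but no female adults.

    Broods with no adults at all are 'no-offspring', not all-male.
    """
    return brood_category(record) == "all_male"


def all_male_proportion(
    records: pd.DataFrame, group: str | None = None
) -> ProportionResult:
    """Proportion of offspring-bearing broods that were all-male."""
    df = records if group is None else records[records["group"] == group]
    if df.empty:
        raise ValueError(f"no brood records for group {group!r}")
    cats = df.apply(brood_category, axis=1)
    with_offspring = int((cats != "no_offspring").sum())
    if with_offspring == 0:
        raise ValueError("no offspring-bearing broods in group")
    return proportion_result(int((cats == "all_male").sum()), with_offspring)


def exclude_all_male(records: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep daughter-producing broods; return them with an exclusion log.

    All-male broods are treated as products of unmated mothers; broods with
    no offspring are dropped too. Idempotent. Counts are conserved:
    kept + logged exclusions = input rows.
    """
    if records.empty:
        return records.copy(), []
    cats = records.apply(brood_category, axis=1)
    kept = records[cats == "daughter_producing"].copy()
    log = [
        f"excluded mother_id={row['mother_id']} ({cat})"
        for (_, row), cat in zip(records.iterrows(), cats)
        if cat != "daughter_producing"
    ]
    return kept, log


def sex_ratio(records: pd.DataFrame, mode: str = "pooled"):
    """Progeny sex ratio (proportion male among adult wasps).

    ``pooled``: total males over total adults, with an exact interval.
    ``per_brood_mean``: unweighted mean of per-brood ratios with its SE.
    """
    males = records["n_male_adults"].astype(int)
    females = records["n_female_adults"].astype(int)
    totals = males + females
    if int(totals.sum()) == 0:
        raise ValueError("no adult wasps in records")
    if mode == "pooled":
        return proportion_result(int(males.sum()), int(totals.sum()))
    if mode == "per_brood_mean":
        ratios = (males / totals)[totals > 0]
        n = len(ratios)
        se = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return MeanResult(mean=float(ratios.mean()), se=se, n=n)
    raise ValueError("mode must be 'pooled' or 'per_brood_mean'")


def emergence_proportions(
    record: Mapping, denominator: str = "outcomes"
) -> tuple[float | None, float | None]:
    """Adult-wasp and non-emerged-fly-pupa proportions for one brood.

    With ``denominator='outcomes'`` the denominator is the total of scored
    host outcomes (adult wasps + emerged flies + unemerged pupae); with
    ``'hosts'`` it is the recorded host number. Returns ``(None, None)``
    when the denominator is zero.
    """
    adults = int(record["n_female_adults"]) + int(record["n_male_adults"])
    flies = int(record["n_flies_emerged"])
    pupae = int(record["n_fly_pupae_unemerged"])
    if denominator == "outcomes":
        denom = adults + flies + pupae
    elif denominator == "hosts":
        denom = int(record["n_hosts"])
    else:
        raise ValueError("denominator must be 'outcomes' or 'hosts'")
    if denom <= 0:
        return None, None
    return adults / denom, pupae / denom


def compare_proportions(
    a: ProportionResult, b: ProportionResult, method: str = "fisher"
) -> float:
    """Two-sided test of equal success probabilities for two count proportions.

    ``fisher`` is the conditional exact test on the 2x2 table (default;
    exact at small counts); ``normal`` is the pooled-proportion normal test
    with continuity correction (the squared statistic is the Yates-corrected
    chi-square), which tracks the exact test closely at large counts.
    """
    table = [
        [a.numerator, a.denominator - a.numerator],
        [b.numerator, b.denominator - b.numerator],
    ]
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "normal":
        return float(stats.chi2_contingency(table, correction=True)[1])
    raise ValueError("method must be 'fisher' or 'normal'")


def dead_wasp_female_proportion(records: pd.DataFrame) -> ProportionResult:
    """Pooled female fraction among dissected dead (non-emerged) wasps."""
    fem = records["n_dead_wasps_female"].fillna(0).astype(int)
    male = records["n_dead_wasps_male"].fillna(0).astype(int)
    total = int(fem.sum() + male.sum())
    if total == 0:
        raise ValueError("no dissected dead wasps in records")
    return proportion_result(int(fem.sum()), total)


def zero_diploid_probability(n_tested: int, d: float) -> float:
    """Probability that none of ``n_tested`` males is diploid.

    ``d`` is the expected diploid fraction among males; the tested males are
    treated as independent, giving ``(1 - d) ** n_tested``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must be in [0, 1]")
    if n_tested < 0:
        raise ValueError("n_tested must be >= 0")
    return (1.0 - d) ** n_tested


def zero_diploid_probability_aggregate(
    batches: Iterable[tuple[int, float]]
) -> float:
    """Product of zero-diploid probabilities over independent batches."""
    total = 1.0
    for n, d in batches:
        total *= zero_diploid_probability(n, d)
    return total


def power_from_simulation(
    sim: SimulationSummary,
    tested_per_generation: Mapping[str, int],
    require_males: bool = True,
) -> float:
    """Monte-Carlo probability of finding zero diploid males in a testing plan.

    For each replicate, the per-generation diploid fraction among males
    ``d_g`` is taken from the simulated counts, and the replicate's
    probability of an all-haploid test outcome is the product over
    generations of ``(1 - d_g) ** n_g``. The returned value is the mean
    over replicates; under a true CSD hypothesis, small values mean the
    observed absence of diploid males is strong evidence against it.

    A testing plan presupposes males to test: with ``require_males`` (the
    default) replicates lacking males at any requested generation —
    extinct lineages included — are excluded from the mean, mirroring an
    experiment that tested males which demonstrably existed. With
    ``require_males=False`` such generations contribute a factor of one.
    """
    unknown = set(tested_per_generation) - set(sim.generation_labels)
    if unknown:
        raise ValueError(f"unknown generation labels: {sorted(unknown)}")
    reps = sim.replicates
    probs = np.ones(sim.n_replicates)
    valid = np.ones(sim.n_replicates, dtype=bool)
    for label, n_tested in tested_per_generation.items():
        if n_tested < 0:
            raise ValueError("tested counts must be >= 0")
        gen = reps[reps["generation"] == label].set_index("replicate")
        males = (gen["n_haploid_male"] + gen["n_diploid_male"]).to_numpy(float)
        dip = gen["n_diploid_male"].to_numpy(float)
        d = np.divide(dip, males, out=np.zeros_like(dip), where=males > 0)
        valid &= males > 0
        probs *= (1.0 - d) ** n_tested
    if require_males:
        if not valid.any():
            raise ValueError("no replicate has males at every requested generation")
        return float(probs[valid].mean())
    return float(probs.mean())
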