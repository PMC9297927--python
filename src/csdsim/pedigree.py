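"""Stochastic individual-based simulation of the inbreeding experiment.

Each replicate follows a single breeding pair per generation through a
:class:`~csdsim.crosses.CrossScheme`: an outcross founds the line, then
mother-son and brother-sister crosses raise homozygosity at the CSD loci.
Brood size and fertilization proportion are drawn per brood from a
:class:`BroodModel`; each egg is independently fertilized with the brood's
proportion; sexes follow the CSD rule. Replicates record the operational sex
ratio (all males over all offspring) and the diploid sex ratio (diploid
males over diploid offspring) per generation, and percentile bands over
replicates summarize the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .crosses import CrossScheme, CrossStep
from .genetics import (
    ALLELE_A,
    ALLELE_B,
    ALLELE_C,
    NOVEL_ALLELE_BASE,
    CsdParams,
    Genotype,
    Individual,
    Sex,
)

__all__ = [
    "BroodModel",
    "GenerationSummary",
    "SimulationSummary",
    "Extinct",
    "init_f0",
    "produce_brood",
    "next_pair",
    "run_replicate",
    "run_simulation",
    "compare_to_observed",
]


class Extinct(Exception):
    """Raised when a brood lacks the sexes needed for the next cross."""


@dataclass(frozen=True)
class BroodModel:
    """Joint model of brood size and fertilization proportion.

    ``empirical`` resamples observed ``(brood_size, fertilization)`` pairs
    jointly with replacement, preserving any size-fertilization correlation.
    ``parametric`` draws brood size from a negative binomial
    (``mean``, ``dispersion``; variance ``mean + mean**2 / dispersion``) and
    the fertilization proportion from a Beta(``beta_a``, ``beta_b``).
    """

    source: str
    sizes: tuple[int, ...] = ()
    fertilizations: tuple[float, ...] = ()
    mean: float = 20.0
    dispersion: float = 5.0
    beta_a: float = 6.5
    beta_b: float = 3.5

    def __post_init__(self) -> None:
        if self.source not in ("empirical_table", "parametric"):
            raise ValueError("source must be 'empirical_table' or 'parametric'")
        if self.source == "empirical_table":
            if not self.sizes:
                raise ValueError("empirical brood model needs at least one pair")
            if len(self.sizes) != len(self.fertilizations):
                raise ValueError("sizes and fertilizations must pair up")
            if any(s < 0 for s in self.sizes):
                raise ValueError("brood sizes must be >= 0")
            if any(not 0.0 <= f <= 1.0 for f in self.fertilizations):
                raise ValueError("fertilization proportions must be in [0, 1]")
        else:
            if self.mean <= 0 or self.dispersion <= 0:
                raise ValueError("negative binomial needs mean > 0, dispersion > 0")
            if self.beta_a <= 0 or self.beta_b <= 0:
                raise ValueError("beta parameters must be > 0")

    @classmethod
    def empirical(cls, pairs: Sequence[tuple[int, float]]) -> "BroodModel":
        sizes, ferts = zip(*pairs)
        return cls(
            source="empirical_table",
            sizes=tuple(int(s) for s in sizes),
            fertilizations=tuple(float(f) for f in ferts),
        )

    @classmethod
    def parametric(
        cls,
        mean: float = 20.0,
        dispersion: float = 5.0,
        beta_a: float = 6.5,
        beta_b: float = 3.5,
    ) -> "BroodModel":
        return cls(
            source="parametric",
            mean=mean,
            dispersion=dispersion,
            beta_a=beta_a,
            beta_b=beta_b,
        )

    @classmethod
    def from_csv(cls, path) -> "BroodModel":
        """Empirical model from a CSV with columns brood_size,fertilization."""
        df = pd.read_csv(path)
        missing = {"brood_size", "fertilization"} - set(df.columns)
        if missing:
            raise ValueError(f"brood CSV missing columns: {sorted(missing)}")
        return cls.empirical(list(zip(df["brood_size"], df["fertilization"])))

    def sample(self, rng: np.random.Generator) -> tuple[int, float]:
        """Draw one (brood size, fertilization proportion) pair."""
        if self.source == "empirical_table":
            j = rng.integers(len(self.sizes))
            return self.sizes[j], self.fertilizations[j]
        p = self.dispersion / (self.dispersion + self.mean)
        size = int(rng.negative_binomial(self.dispersion, p))
        f = float(rng.beta(self.beta_a, self.beta_b))
        return size, f

    def mean_fertilization(self) -> float:
        if self.source == "empirical_table":
            return float(np.mean(self.fertilizations))
        return self.beta_a / (self.beta_a + self.beta_b)


@dataclass
class GenerationSummary:
    """Counts and ratios for one generation of one replicate."""

    generation_label: str
    n_female: int
    n_haploid_male: int
    n_diploid_male: int
    osr: float | None
    diploid_sr: float | None
    extinct: bool


@dataclass
class SimulationSummary:
    """Replicate-level table and percentile-band summary of a simulation run."""

    scheme_label: str
    generation_labels: list[str]
    n_replicates: int
    seed: int
    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: dict = field(default_factory=dict)
    diploid_genotype_counts: list[Counter] | None = None
    haploid_genotype_counts: list[Counter] | None = None


def init_f0(csd: CsdParams, rng=None) -> tuple[Individual, Individual]:
    """Founding outcross pair: fully heterozygous A/B female, unrelated C male.

    Every fertilized F1 egg is then heterozygous at every locus (A/C or B/C)
    and F1 sons are hemizygous A or B per locus.
    """
    k = csd.n_loci
    mother = Individual(
        id="F0-mother",
        genotype=Genotype.diploid(((ALLELE_A, ALLELE_B),) * k),
        sex=Sex.FEMALE,
    )
    father = Individual(
        id="F0-father",
        genotype=Genotype.haploid((ALLELE_C,) * k),
        sex=Sex.HAPLOID_MALE,
    )
    return mother, father


def _novel_stock_male(csd: CsdParams, generation: int) -> Individual:
    """Unrelated stock male with fresh alleles (control/outcross matings)."""
    g = Genotype.haploid((NOVEL_ALLELE_BASE + generation,) * csd.n_loci)
    return Individual(id=f"stock-{generation}", genotype=g, sex=Sex.HAPLOID_MALE)


def produce_brood(
    mother: Individual,
    father: Individual,
    brood_model: BroodModel,
    csd: CsdParams,
    rng: np.random.Generator,
) -> list[Individual]:
    """Produce one brood.

    Brood size ``n`` and fertilization proportion ``f`` are drawn once per
    brood; each egg is independently fertilized with probability ``f``
    (binomial thinning). Fertilized eggs fuse a maternal gamete with the
    sire's genotype; unfertilized eggs develop from the gamete alone.
    """
    if mother.genotype.ploidy != 2 or mother.sex is not Sex.FEMALE:
        raise ValueError("mother must be a diploid female")
    if father.genotype.ploidy != 1:
        raise ValueError("father must be haploid")
    size, f = brood_model.sample(rng)
    if size == 0:
        return []
    k = csd.n_loci
    fertilized = rng.random(size) < f
    picks = rng.integers(0, 2, size=(size, k))
    mloci = mother.genotype.loci
    pat = tuple(locus[0] for locus in father.genotype.loci)
    csd_on = csd.csd_enabled

    brood: list[Individual] = []
    for e in range(size):
        row = picks[e]
        gam = tuple(mloci[l][row[l]] for l in range(k))
        if fertilized[e]:
            loci = tuple(
                (g, p) if g <= p else (p, g) for g, p in zip(gam, pat)
            )
            if csd_on and all(a == b for a, b in loci):
                sex = Sex.DIPLOID_MALE
            else:
                sex = Sex.FEMALE
            genotype = Genotype(loci)
        else:
            genotype = Genotype(tuple((g,) for g in gam))
            sex = Sex.HAPLOID_MALE
        brood.append(
            Individual(
                id=e,
                genotype=genotype,
                sex=sex,
                mother_id=mother.id,
                father_id=father.id,
            )
        )
    return brood


def next_pair(
    brood: list[Individual],
    step: CrossStep,
    current_mother: Individual,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Select the parents of the next cross from a brood.

    Mother-son keeps the current mother and pairs her with a random haploid
    son; brother-sister draws a random female and a random haploid male from
    the same brood. Diploid males are never chosen as sires (haploid males
    are the ones randomly selected for crosses). Raises :class:`Extinct`
    when the required sexes are missing.
    """
    step = CrossStep(step)
    if step is CrossStep.OUTCROSS:
        raise ValueError("outcross pairs are not drawn from a brood")
    males = [ind for ind in brood if ind.sex is Sex.HAPLOID_MALE]
    if not males:
        raise Extinct("no haploid males available")
    son = males[rng.integers(len(males))]
    if step is CrossStep.MOTHER_SON:
        return current_mother, son
    females = [ind for ind in brood if ind.sex is Sex.FEMALE]
    if not females:
        raise Extinct("no females available")
    return females[rng.integers(len(females))], son


def _summarize_brood(label: str, brood: list[Individual]) -> GenerationSummary:
    n_f = n_h = n_d = 0
    for ind in brood:
        if ind.sex is Sex.FEMALE:
            n_f += 1
        elif ind.sex is Sex.HAPLOID_MALE:
            n_h += 1
        else:
            n_d += 1
    total = n_f + n_h + n_d
    n_dip = n_f + n_d
    return GenerationSummary(
        generation_label=label,
        n_female=n_f,
        n_haploid_male=n_h,
        n_diploid_male=n_d,
        osr=(n_h + n_d) / total if total else None,
        diploid_sr=n_d / n_dip if n_dip else None,
        extinct=False,
    )


def run_replicate(
    scheme: CrossScheme,
    csd: CsdParams,
    brood_model: BroodModel,
    rng: np.random.Generator,
    on_brood: Callable[[int, list[Individual]], None] | None = None,
) -> list[GenerationSummary]:
    """Simulate one replicate lineage; one GenerationSummary per cross.

    Once a brood lacks the sexes required for the next cross the lineage is
    extinct: later generations carry ``extinct=True`` and undefined ratios.
    """
    labels = scheme.generation_labels()
    mother, father = init_f0(csd)
    summaries: list[GenerationSummary] = []
    extinct = False
    for gi, step in enumerate(scheme.steps):
        if extinct:
            summaries.append(
                GenerationSummary(labels[gi], 0, 0, 0, None, None, True)
            )
            continue
        brood = produce_brood(mother, father, brood_model, csd, rng)
        summaries.append(_summarize_brood(labels[gi], brood))
        if on_brood is not None:
            on_brood(gi, brood)
        if gi + 1 < len(scheme.steps):
            nxt = scheme.steps[gi + 1]
            try:
                if nxt is CrossStep.OUTCROSS:
                    females = [i for i in brood if i.sex is Sex.FEMALE]
                    if not females:
                        raise Extinct("no females available")
                    mother = females[rng.integers(len(females))]
                    father = _novel_stock_male(csd, gi + 1)
                else:
                    mother, father = next_pair(brood, nxt, mother, rng)
            except Extinct:
                extinct = True
    return summaries


def run_simulation(
    scheme: CrossScheme,
    csd: CsdParams,
    brood_model: BroodModel,
    n_replicates: int,
    seed: int,
    track_genotypes: bool = False,
) -> SimulationSummary:
    """Run many replicate lineages and summarize with 95% percentile bands.

    Replicate ``r`` uses the deterministic substream
    ``SeedSequence(seed, spawn_key=(r,))``, so runs are reproducible and
    order-independent. Bands are 2.5/97.5 percentiles over replicates with a
    defined ratio at that generation (extinct or diploid-free replicates are
    excluded from the respective band and reported via the surviving count).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = scheme.generation_labels()
    n_gen = len(labels)
    dip_counts = [Counter() for _ in range(n_gen)] if track_genotypes else None
    hap_counts = [Counter() for _ in range(n_gen)] if track_genotypes else None

    def sink(gi: int, brood: list[Individual]) -> None:
        for ind in brood:
            if ind.genotype.ploidy == 2:
                dip_counts[gi][ind.genotype] += 1
            else:
                hap_counts[gi][ind.genotype] += 1

    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        for s in run_replicate(
            scheme, csd, brood_model, rng, on_brood=sink if track_genotypes else None
        ):
            rows.append(
                (
                    r,
                    s.generation_label,
                    s.n_female,
                    s.n_haploid_male,
                    s.n_diploid_male,
                    s.osr,
                    s.diploid_sr,
                    s.extinct,
                )
            )
    replicates = pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "generation",
            "n_female",
            "n_haploid_male",
            "n_diploid_male",
            "osr",
            "diploid_sr",
            "extinct",
        ],
    )

    summary_rows = []
    for label in labels:
        gen = replicates[replicates["generation"] == label]
        surviving = gen[~gen["extinct"]]
        osr = surviving["osr"].dropna()
        dsr = surviving["diploid_sr"].dropna()
        summary_rows.append(
            {
                "generation": label,
                "n_replicates_surviving": len(surviving),
                "mean_osr": osr.mean() if len(osr) else np.nan,
                "osr_lo": np.percentile(osr, 2.5) if len(osr) else np.nan,
                "osr_hi": np.percentile(osr, 97.5) if len(osr) else np.nan,
                "n_diploid_sr_defined": len(dsr),
                "mean_diploid_sr": dsr.mean() if len(dsr) else np.nan,
                "diploid_sr_lo": np.percentile(dsr, 2.5) if len(dsr) else np.nan,
                "diploid_sr_hi": np.percentile(dsr, 97.5) if len(dsr) else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return SimulationSummary(
        scheme_label=scheme.label,
        generation_labels=labels,
        n_replicates=n_replicates,
        seed=seed,
        replicates=replicates,
        summary=summary,
        config={
            "scheme": scheme.label,
            "steps": [s.value for s in scheme.steps],
            "n_loci": csd.n_loci,
            "csd_enabled": csd.csd_enabled,
            "brood_model": brood_model.source,
            "n_replicates": n_replicates,
            "seed": seed,
        },
        diploid_genotype_counts=dip_counts,
        haploid_genotype_counts=hap_counts,
    )


def compare_to_observed(sim: SimulationSummary, observed: pd.DataFrame) -> pd.DataFrame:
    """Overlap of observed confidence intervals with simulated bands.

    ``observed`` needs a ``generation`` column plus ``osr_lo``/``osr_hi``
    and/or ``diploid_sr_lo``/``diploid_sr_hi`` interval columns; generation
    labels must all occur in the simulation. Two intervals overlap when
    neither lies entirely above the other.
    """
    sim_by_gen = sim.summary.set_index("generation")
    unknown = set(observed["generation"]) - set(sim_by_gen.index)
    if unknown:
        raise ValueError(f"observed generations not in simulation: {sorted(unknown)}")

    def _overlap(lo1, hi1, lo2, hi2):
        if any(pd.isna(v) for v in (lo1, hi1, lo2, hi2)):
            return None
        return bool(lo1 <= hi2 and lo2 <= hi1)

    rows = []
    for _, obs in observed.iterrows():
        band = sim_by_gen.loc[obs["generation"]]
        row = {"generation": obs["generation"]}
        if "osr_lo" in observed.columns:
            row["osr_overlap"] = _overlap(
                obs["osr_lo"], obs["osr_hi"], band["osr_lo"], band["osr_hi"]
            )
        if "diploid_sr_lo" in observed.columns:
            row["diploid_sr_overlap"] = _overlap(
                obs["diploid_sr_lo"],
                obs["diploid_sr_hi"],
                band["diploid_sr_lo"],
                band["diploid_sr_hi"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
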