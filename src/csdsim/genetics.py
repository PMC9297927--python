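"""Genotypes, Mendelian transmission and the complementary sex determination rule.

Haplodiploid sexuals (arrhenotoky) make males from unfertilized haploid eggs
and females from fertilized diploid eggs. Under complementary sex
determination (CSD) the fertilized eggs are only female if they are
heterozygous at one or more CSD loci; diploids homozygous at *all* loci
develop as (usually sterile) diploid males, and all haploids are male.

This module holds the deterministic core: genotype containers, gamete
formation, the CSD rule, the closed-form egg-fate expectations for the three
classical scenarios (no CSD, CSD with inviable diploid males, CSD with viable
diploid males), and exact enumeration of offspring genotype distributions for
single crosses and whole inbreeding pedigrees. The exact pedigree propagation
is the oracle against which the stochastic simulator in
:mod:`csdsim.pedigree` is validated.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .crosses import CrossScheme, CrossStep

__all__ = [
    "Sex",
    "Genotype",
    "Individual",
    "CsdParams",
    "Table1Params",
    "SexProportions",
    "OffspringDistribution",
    "GenerationDistribution",
    "allele_name",
    "make_gamete",
    "fuse",
    "determine_sex",
    "gamete_distribution",
    "expected_proportions",
    "enumerate_cross",
    "pedigree_distributions",
    "homozygous_fraction_pedigree",
]

_ALLELE_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# Allele labels for the standard F0 outcross: a fully heterozygous A/B female
# mated to an unrelated C male, so every fertilized F1 egg is heterozygous.
ALLELE_A, ALLELE_B, ALLELE_C = 0, 1, 2
#: First label handed out to novel outcross sires (beyond A, B, C).
NOVEL_ALLELE_BASE = 3


def allele_name(allele: int) -> str:
    """Letter name for an allele label (``0 -> 'A'``; large labels ``'a<n>'``)."""
    if 0 <= allele < len(_ALLELE_NAMES):
        return _ALLELE_NAMES[allele]
    return f"a{allele}"


class Sex(str, Enum):
    FEMALE = "female"
    HAPLOID_MALE = "haploid_male"
    DIPLOID_MALE = "diploid_male"


@dataclass(frozen=True)
class Genotype:
    """Allelic state at ``k`` unlinked CSD loci.

    ``loci`` is a tuple of per-locus tuples holding one allele label
    (haploid) or two (diploid). Diploid pairs are unordered and stored
    sorted, so equal genotypes compare and hash equal.
    """

    loci: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        canon = []
        ploidy = None
        for locus in self.loci:
            t = tuple(locus)
            if len(t) == 2:
                if t[0] > t[1]:
                    t = (t[1], t[0])
            elif len(t) != 1:
                raise ValueError(f"locus must hold 1 or 2 alleles, got {locus!r}")
            if ploidy is None:
                ploidy = len(t)
            elif len(t) != ploidy:
                raise ValueError("mixed per-locus ploidy in genotype")
            canon.append(t)
        if not canon:
            raise ValueError("genotype needs at least one locus")
        object.__setattr__(self, "loci", tuple(canon))

    @classmethod
    def haploid(cls, alleles: Iterable[int]) -> "Genotype":
        return cls(tuple((a,) for a in alleles))

    @classmethod
    def diploid(cls, pairs: Iterable[tuple[int, int]]) -> "Genotype":
        return cls(tuple(tuple(p) for p in pairs))

    @property
    def ploidy(self) -> int:
        return len(self.loci[0])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def is_homozygous(self) -> bool:
        """True for diploids carrying identical alleles at every locus."""
        return self.ploidy == 2 and all(a == b for a, b in self.loci)

    def __str__(self) -> str:
        return ";".join("/".join(allele_name(a) for a in locus) for locus in self.loci)


@dataclass
class Individual:
    id: int | str
    genotype: Genotype
    sex: Sex
    mother_id: int | str | None = None
    father_id: int | str | None = None


@dataclass(frozen=True)
class CsdParams:
    """CSD configuration: number of loci and scenario flags.

    With ``csd_enabled=False`` every diploid develops as female, which is the
    null model for species without CSD. ``diploid_male_viable`` only matters
    downstream (adult counts); the sex rule itself is unaffected.
    """

    n_loci: int
    csd_enabled: bool = True
    diploid_male_viable: bool = True

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def make_gamete(parent: "Individual | Genotype", rng) -> Genotype:
    """Form a haploid gamete from a diploid parent.

    Loci segregate independently: at each locus one of the parent's two
    alleles is chosen uniformly.
    """
    genotype = parent.genotype if isinstance(parent, Individual) else parent
    if genotype.ploidy != 2:
        raise ValueError(
            "gametes are formed by diploid parents; haploid males transmit "
            "their whole genotype (use fuse directly)"
        )
    picks = rng.integers(0, 2, size=genotype.n_loci)
    return Genotype(tuple((locus[p],) for locus, p in zip(genotype.loci, picks)))


def fuse(maternal_gamete: Genotype, paternal_genotype: Genotype) -> Genotype:
    """Fertilization: combine two haploid genotypes into an unordered diploid."""
    if maternal_gamete.ploidy != 1 or paternal_genotype.ploidy != 1:
        raise ValueError("fuse requires two haploid genotypes")
    if maternal_gamete.n_loci != paternal_genotype.n_loci:
        raise ValueError("locus number mismatch between gametes")
    return Genotype(
        tuple(
            (m[0], p[0])
            for m, p in zip(maternal_gamete.loci, paternal_genotype.loci)
        )
    )


def determine_sex(genotype: Genotype, csd: CsdParams) -> Sex:
    """Apply the CSD rule.

    Haploids are male. Diploids are female when heterozygous at one or more
    loci and male when homozygous at all loci; with CSD disabled every
    diploid is female.
    """
    if genotype.n_loci != csd.n_loci:
        raise ValueError("genotype locus number does not match CsdParams")
    if genotype.ploidy == 1:
        return Sex.HAPLOID_MALE
    if not csd.csd_enabled:
        return Sex.FEMALE
    return Sex.DIPLOID_MALE if genotype.is_homozygous() else Sex.FEMALE


def gamete_distribution(genotype: Genotype) -> dict[Genotype, float]:
    """Exact gamete distribution of a diploid under independent segregation."""
    if genotype.ploidy != 2:
        raise ValueError("gamete distribution is defined for diploids")
    per_locus: list[list[tuple[int, float]]] = []
    for a, b in genotype.loci:
        if a == b:
            per_locus.append([(a, 1.0)])
        else:
            per_locus.append([(a, 0.5), (b, 0.5)])
    out: dict[Genotype, float] = {}
    for combo in itertools.product(*per_locus):
        g = Genotype(tuple((a,) for a, _ in combo))
        p = 1.0
        for _, q in combo:
            p *= q
        out[g] = out.get(g, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# Closed-form egg-fate expectations
# ---------------------------------------------------------------------------

SCENARIOS = ("no_csd", "csd_inviable_dm", "csd_viable_dm")


@dataclass(frozen=True)
class Table1Params:
    """Parameters of the closed-form scenario expectations.

    f : fertilization rate (fraction of eggs fertilized, i.e. diploid)
    h : chance a fertilized egg is homozygous at all CSD loci
    i : proportion of eggs that are inviable diploid males (inviable
        scenario only; when driven from the genotype model, ``i = h * f``)
    """

    f: float
    h: float = 0.0
    i: float = 0.0
    scenario: str = "no_csd"

    def __post_init__(self) -> None:
        for name in ("f", "h", "i"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "csd_inviable_dm" and self.i > self.f:
            raise ValueError("inviable diploid male fraction i cannot exceed f")


@dataclass(frozen=True)
class SexProportions:
    """Expected proportions of adult offspring classes and the sex ratio.

    In the inviable-diploid-male scenario the three proportions are relative
    to eggs laid and sum to ``1 - i``; the sex ratio is always computed on
    surviving adults.
    """

    p_female: float
    p_haploid_male: float
    p_diploid_male: float
    sex_ratio: float


def expected_proportions(params: Table1Params) -> SexProportions:
    """Closed-form class proportions and progeny sex ratio per scenario.

    no CSD:               F = f,        M = 1-f, D = 0,   SR = (1-f)
    CSD, inviable males:  F = f-i,      M = 1-f, D = 0,   SR = (1-f)/([f-i]+[1-f])
    CSD, viable males:    F = (1-h)f,   M = 1-f, D = hf,  SR = ([1-f]+hf)
    """
    f, h, i = params.f, params.h, params.i
    if params.scenario == "no_csd":
        female, hap, dip = f, 1.0 - f, 0.0
    elif params.scenario == "csd_viable_dm":
        female, hap, dip = (1.0 - h) * f, 1.0 - f, h * f
    else:  # csd_inviable_dm
        female, hap, dip = f - i, 1.0 - f, 0.0
    total = female + hap + dip
    if total == 0.0:
        raise ValueError("no surviving offspring: sex ratio undefined")
    return SexProportions(
        p_female=female,
        p_haploid_male=hap,
        p_diploid_male=dip,
        sex_ratio=(hap + dip) / total,
    )


# ---------------------------------------------------------------------------
# Exact enumeration of crosses and pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffspringDistribution:
    """Exact offspring distribution of a cross.

    ``probs`` maps ``(ploidy, genotype)`` to probability and sums to one.
    Derived scalars condition on ploidy where noted.
    """

    probs: dict[tuple[int, Genotype], float]
    p_homozygous_given_diploid: float | None
    p_female: float
    p_haploid_male: float
    p_diploid_male: float

    def diploid_distribution(self) -> dict[Genotype, float]:
        """Genotype distribution of fertilized (diploid) eggs, normalized."""
        dip = {g: p for (pl, g), p in self.probs.items() if pl == 2}
        total = sum(dip.values())
        if total == 0.0:
            return {}
        return {g: p / total for g, p in dip.items()}


def _check_distribution(dist: Mapping[Genotype, float], ploidy: int, name: str) -> None:
    if not dist:
        raise ValueError(f"{name} genotype distribution is empty")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} genotype distribution sums to {total}, not 1")
    for g in dist:
        if g.ploidy != ploidy:
            raise ValueError(f"{name} genotypes must have ploidy {ploidy}")


def enumerate_cross(
    mother_dist: Mapping[Genotype, float],
    father_dist: Mapping[Genotype, float],
    f: float,
    csd: CsdParams,
) -> OffspringDistribution:
    """Exact offspring distribution of a cross, marginalized over parents.

    A fraction ``f`` of eggs is fertilized (maternal gamete fused with the
    sire's haploid genotype); the rest develop from the maternal gamete
    alone. Gamete formation follows independent segregation exactly.
    """
    _check_distribution(mother_dist, 2, "mother")
    _check_distribution(father_dist, 1, "father")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fertilization rate must be in [0, 1]")

    probs: dict[tuple[int, Genotype], float] = defaultdict(float)
    for mg, pm in mother_dist.items():
        gametes = gamete_distribution(mg)
        if f < 1.0:
            for g, pg in gametes.items():
                probs[(1, g)] += pm * (1.0 - f) * pg
        if f > 0.0:
            for fg, pf in father_dist.items():
                for g, pg in gametes.items():
                    probs[(2, fuse(g, fg))] += pm * pf * f * pg

    p_hap = p_dip_male = p_fem = 0.0
    dip_total = homo_total = 0.0
    for (ploidy, g), p in probs.items():
        if ploidy == 1:
            p_hap += p
        else:
            dip_total += p
            if g.is_homozygous():
                homo_total += p
            if determine_sex(g, csd) is Sex.FEMALE:
                p_fem += p
            else:
                p_dip_male += p
    return OffspringDistribution(
        probs=dict(probs),
        p_homozygous_given_diploid=(homo_total / dip_total) if dip_total > 0 else None,
        p_female=p_fem,
        p_haploid_male=p_hap,
        p_diploid_male=p_dip_male,
    )


@dataclass(frozen=True)
class GenerationDistribution:
    """Exact genotype distributions of one pedigree generation's brood.

    ``diploid``/``haploid`` are conditional genotype distributions of
    fertilized and unfertilized eggs (each normalized to one);
    ``p_homozygous`` is the expected fraction of fertilized eggs homozygous
    at all loci, averaged over the parental-pair distribution.
    """

    label: str
    diploid: dict[Genotype, float]
    haploid: dict[Genotype, float]
    p_homozygous: float


# Exact propagation is exponential in loci; beyond this, use Monte Carlo.
_MAX_ENUM_LOCI = 5
_MAX_ENUM_GENERATIONS = 8


def _novel_sire(k: int, generation: int) -> Genotype:
    """Unrelated sire carrying fresh alleles at every locus.

    Emulates an infinite novel-allele supply: daughters of such a sire are
    guaranteed heterozygous, maximizing starting heterozygosity as in an
    outbred stock.
    """
    return Genotype.haploid((NOVEL_ALLELE_BASE + generation,) * k)


def pedigree_distributions(
    scheme: CrossScheme | Sequence[CrossStep | str],
    csd: CsdParams,
) -> list[GenerationDistribution]:
    """Exactly propagate parental genotype-pair distributions along a pedigree.

    The state is the joint distribution of (diploid mother, haploid sire)
    genotypes. Each generation, the brood distribution is computed per pair;
    the next pair is formed per the cross type, conditioning the new mother
    on being female (heterozygous at >= 1 locus under CSD) within her own
    brood — the infinite-brood limit of the stochastic experiment, in which
    lineages never go extinct.
    """
    steps = [CrossStep(s) for s in (scheme.steps if isinstance(scheme, CrossScheme) else scheme)]
    labels = (
        scheme.generation_labels()
        if isinstance(scheme, CrossScheme)
        else CrossScheme("adhoc", tuple(steps)).generation_labels()
    )
    if steps[0] is not CrossStep.OUTCROSS:
        raise ValueError("pedigree must begin with an outcross")
    if csd.n_loci > _MAX_ENUM_LOCI or len(steps) > _MAX_ENUM_GENERATIONS:
        raise ValueError(
            "exact enumeration guard exceeded (k <= 5, generations <= 8); "
            "use Monte Carlo (csdsim.pedigree.run_simulation)"
        )

    k = csd.n_loci
    mother0 = Genotype.diploid(((ALLELE_A, ALLELE_B),) * k)
    father0 = Genotype.haploid((ALLELE_C,) * k)
    state: dict[tuple[Genotype, Genotype], float] = {(mother0, father0): 1.0}

    out: list[GenerationDistribution] = []
    for gi, step in enumerate(steps):
        # Brood distribution produced by the current parental pairs.
        dip: dict[Genotype, float] = defaultdict(float)
        hap: dict[Genotype, float] = defaultdict(float)
        per_pair: dict[tuple[Genotype, Genotype], tuple[dict, dict]] = {}
        for (mother, sire), p in state.items():
            gametes = gamete_distribution(mother)
            daughters: dict[Genotype, float] = defaultdict(float)
            for g, pg in gametes.items():
                daughters[fuse(g, sire)] += pg
            per_pair[(mother, sire)] = (gametes, dict(daughters))
            for g, pg in gametes.items():
                hap[g] += p * pg
            for g, pg in daughters.items():
                dip[g] += p * pg
        p_homo = sum(p for g, p in dip.items() if g.is_homozygous())
        out.append(
            GenerationDistribution(
                label=labels[gi],
                diploid=dict(dip),
                haploid=dict(hap),
                p_homozygous=p_homo,
            )
        )

        if gi + 1 == len(steps):
            break
        nxt = steps[gi + 1]
        new_state: dict[tuple[Genotype, Genotype], float] = defaultdict(float)
        for (mother, sire), p in state.items():
            gametes, daughters = per_pair[(mother, sire)]
            if nxt is CrossStep.MOTHER_SON:
                # Same mother, mated to one of her sons.
                for son, ps in gametes.items():
                    new_state[(mother, son)] += p * ps
                continue
            # New mother: a female from this brood (conditioned within pair).
            females = {
                g: q
                for g, q in daughters.items()
                if determine_sex(g, csd) is Sex.FEMALE
            }
            fem_total = sum(females.values())
            if fem_total == 0.0:
                raise RuntimeError(
                    "parental pair with zero female offspring probability; "
                    "cannot condition (should not happen from an outcross)"
                )
            if nxt is CrossStep.BROTHER_SISTER:
                for d, pd in females.items():
                    for son, ps in gametes.items():
                        new_state[(d, son)] += p * (pd / fem_total) * ps
            else:  # later OUTCROSS: daughter mated to an unrelated novel sire
                sire_new = _novel_sire(k, gi + 1)
                for d, pd in females.items():
                    new_state[(d, sire_new)] += p * (pd / fem_total)
        state = dict(new_state)
    return out


def homozygous_fraction_pedigree(
    scheme: CrossScheme | Sequence[CrossStep | str],
    csd: CsdParams,
) -> list[float]:
    """Expected fraction of fertilized eggs homozygous at all loci, per generation.

    Under single-locus CSD this peaks at 0.5 (first reached the generation
    after a mother-son cross) and is lower, at matched generations, the more
    CSD loci there are.
    """
    return [g.p_homozygous for g in pedigree_distributions(scheme, csd)]
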