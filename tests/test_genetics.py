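"""Genotypes, segregation, the CSD rule and exact enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csdsim import (
    CrossScheme,
    CsdParams,
    Genotype,
    Sex,
    Table1Params,
    determine_sex,
    enumerate_cross,
    expected_proportions,
    fuse,
    gamete_distribution,
    homozygous_fraction_pedigree,
    make_gamete,
)
from csdsim.genetics import pedigree_distributions

A, B, C = 0, 1, 2


def test_genotype_canonicalizes_unordered_pairs():
    assert Genotype.diploid([(B, A)]) == Genotype.diploid([(A, B)])
    assert str(Genotype.diploid([(A, B), (C, C)])) == "A/B;C/C"


def test_genotype_rejects_mixed_ploidy_and_bad_loci():
    with pytest.raises(ValueError):
        Genotype(((A,), (A, B)))
    with pytest.raises(ValueError):
        Genotype(((A, B, C),))


class TestMakeGamete:
    def test_homozygous_parent_transmits_deterministically(self, rng):
        parent = Genotype.diploid([(A, A)])
        for _ in range(10):
            assert make_gamete(parent, rng) == Genotype.haploid([A])

    def test_heterozygous_parent_segregates_one_to_one(self, rng):
        # Empirical frequency within 3 SE of the Mendelian 1/2 at 10 000 draws.
        parent = Genotype.diploid([(A, B)])
        n = 10_000
        n_a = sum(make_gamete(parent, rng) == Genotype.haploid([A]) for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(n_a / n - 0.5) < 3 * se

    def test_two_locus_gamete_distribution_matches_enumeration(self, rng):
        parent = Genotype.diploid([(A, B), (C, C)])
        exact = gamete_distribution(parent)
        assert exact == {
            Genotype.haploid([A, C]): 0.5,
            Genotype.haploid([B, C]): 0.5,
        }
        n = 4000
        counts = {g: 0 for g in exact}
        for _ in range(n):
            counts[make_gamete(parent, rng)] += 1
        se = math.sqrt(0.25 / n)
        assert abs(counts[Genotype.haploid([A, C])] / n - 0.5) < 3 * se

    def test_haploid_parent_is_rejected(self, rng):
        with pytest.raises(ValueError):
            make_gamete(Genotype.haploid([A]), rng)


class TestFuse:
    def test_basic_fusion(self):
        assert fuse(Genotype.haploid([A]), Genotype.haploid([C])) == Genotype.diploid(
            [(A, C)]
        )
        assert fuse(Genotype.haploid([B]), Genotype.haploid([B])) == Genotype.diploid(
            [(B, B)]
        )

    def test_symmetry(self):
        x, y = Genotype.haploid([A, C]), Genotype.haploid([B, A])
        assert fuse(x, y) == fuse(y, x)

    def test_locus_number_mismatch(self):
        with pytest.raises(ValueError):
            fuse(Genotype.haploid([A]), Genotype.haploid([A, B]))


@pytest.mark.parametrize(
    "genotype, k, expected",
    [
        (Genotype.haploid([A]), 1, Sex.HAPLOID_MALE),
        (Genotype.diploid([(A, B)]), 1, Sex.FEMALE),
        (Genotype.diploid([(A, A)]), 1, Sex.DIPLOID_MALE),
        # Heterozygosity at one of several loci suffices for femaleness.
        (Genotype.diploid([(A, A), (B, C)]), 2, Sex.FEMALE),
        (Genotype.diploid([(A, A), (C, C)]), 2, Sex.DIPLOID_MALE),
    ],
)
def test_determine_sex_csd_rule(genotype, k, expected):
    assert determine_sex(genotype, CsdParams(n_loci=k)) is expected


def test_determine_sex_without_csd_makes_all_diploids_female():
    csd = CsdParams(n_loci=1, csd_enabled=False)
    assert determine_sex(Genotype.diploid([(A, A)]), csd) is Sex.FEMALE
    dist = enumerate_cross(
        {Genotype.diploid([(A, B)]): 1.0}, {Genotype.haploid([A]): 1.0}, 0.7, csd
    )
    assert dist.p_diploid_male == 0.0


class TestExpectedProportions:
    def test_full_fertilization_no_csd_gives_all_female(self):
        out = expected_proportions(Table1Params(f=1.0, scenario="no_csd"))
        assert out.sex_ratio == 0.0 and out.p_female == 1.0

    @pytest.mark.parametrize("scenario", ["no_csd", "csd_inviable_dm", "csd_viable_dm"])
    def test_zero_fertilization_gives_all_male(self, scenario):
        out = expected_proportions(Table1Params(f=0.0, h=0.5, i=0.0, scenario=scenario))
        assert out.sex_ratio == 1.0

    def test_viable_diploid_male_scenario_closed_form(self):
        out = expected_proportions(Table1Params(f=0.6, h=0.5, scenario="csd_viable_dm"))
        assert out.p_female == pytest.approx(0.30)
        assert out.p_haploid_male == pytest.approx(0.40)
        assert out.p_diploid_male == pytest.approx(0.30)
        assert out.sex_ratio == pytest.approx(0.70)

    def test_viable_scenario_matches_egg_fate_monte_carlo(self, rng):
        # Independent per-egg oracle: fertilize with f, then homozygose with h.
        n = 1_000_000
        fert = rng.random(n) < 0.6
        homo = rng.random(n) < 0.5
        sr_mc = (~fert | (fert & homo)).mean()
        out = expected_proportions(Table1Params(f=0.6, h=0.5, scenario="csd_viable_dm"))
        assert abs(sr_mc - out.sex_ratio) < 3 * math.sqrt(0.25 / n)

    def test_inviable_scenario_sex_ratio_on_survivors(self):
        out = expected_proportions(
            Table1Params(f=0.6, h=0.5, i=0.3, scenario="csd_inviable_dm")
        )
        assert out.p_female == pytest.approx(0.3)
        assert out.sex_ratio == pytest.approx(0.4 / 0.7)
        # Survivor proportions sum to 1 - i.
        total = out.p_female + out.p_haploid_male + out.p_diploid_male
        assert total == pytest.approx(1.0 - 0.3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Table1Params(f=1.2)
        with pytest.raises(ValueError):
            Table1Params(f=0.3, i=0.5, scenario="csd_inviable_dm")


@settings(max_examples=200, derandomize=True)
@given(
    f=st.floats(0.01, 1.0),
    h=st.floats(0.0, 1.0),
    scenario=st.sampled_from(["no_csd", "csd_viable_dm"]),
)
def test_viable_scenario_proportions_sum_to_one(f, h, scenario):
    out = expected_proportions(Table1Params(f=f, h=h, scenario=scenario))
    assert out.p_female + out.p_haploid_male + out.p_diploid_male == pytest.approx(1.0)
    assert 0.0 <= out.sex_ratio <= 1.0


class TestEnumerateCross:
    def test_mother_son_type_cross_gives_half_homozygous(self, k1):
        dist = enumerate_cross(
            {Genotype.diploid([(A, B)]): 1.0}, {Genotype.haploid([A]): 1.0}, 1.0, k1
        )
        assert dist.probs[(2, Genotype.diploid([(A, A)]))] == pytest.approx(0.5)
        assert dist.probs[(2, Genotype.diploid([(A, B)]))] == pytest.approx(0.5)
        assert dist.p_homozygous_given_diploid == pytest.approx(0.5)

    def test_outcross_has_no_homozygotes(self, k1):
        dist = enumerate_cross(
            {Genotype.diploid([(A, B)]): 1.0}, {Genotype.haploid([C]): 1.0}, 1.0, k1
        )
        assert dist.p_homozygous_given_diploid == 0.0

    def test_two_loci_homozygosity_is_product_of_per_locus(self):
        dist = enumerate_cross(
            {Genotype.diploid([(A, B), (A, B)]): 1.0},
            {Genotype.haploid([A, A]): 1.0},
            1.0,
            CsdParams(n_loci=2),
        )
        assert dist.p_homozygous_given_diploid == pytest.approx(0.25)

    def test_empty_distribution_rejected(self, k1):
        with pytest.raises(ValueError):
            enumerate_cross({}, {Genotype.haploid([A]): 1.0}, 0.5, k1)


@settings(max_examples=100, derandomize=True)
@given(
    data=st.data(),
    k=st.integers(1, 3),
    f=st.floats(0.0, 1.0),
)
def test_offspring_distribution_sums_to_one(data, k, f):
    alleles = st.integers(0, 3)
    mother = Genotype.diploid(
        [tuple(sorted(data.draw(st.tuples(alleles, alleles)))) for _ in range(k)]
    )
    father = Genotype.haploid([data.draw(alleles) for _ in range(k)])
    dist = enumerate_cross({mother: 1.0}, {father: 1.0}, f, CsdParams(n_loci=k))
    assert sum(dist.probs.values()) == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(k=st.integers(1, 5))
def test_homozygosity_is_per_locus_probability_to_the_k(k):
    # Fully heterozygous mother x son-type sire sharing one allele per locus:
    # per-locus homozygosity 1/2, so p^k overall.
    mother = Genotype.diploid([(A, B)] * k)
    father = Genotype.haploid([A] * k)
    dist = enumerate_cross({mother: 1.0}, {father: 1.0}, 1.0, CsdParams(n_loci=k))
    assert dist.p_homozygous_given_diploid == pytest.approx(0.5**k, abs=1e-12)


class TestPedigreeEnumeration:
    def test_mother_son_generation_reaches_one_half(self, heterotoma, k1):
        fracs = homozygous_fraction_pedigree(heterotoma, k1)
        assert fracs[0] == 0.0  # outcross: no homozygotes possible
        assert fracs[1] == pytest.approx(0.5)

    def test_first_brother_sister_generations_hand_values(self, clavipes):
        # Hand enumeration over F1 sib pairs: sister A/C or B/C, brother A or
        # B, each combination 1/4; half the combinations share an allele and
        # then give 1/2 homozygous eggs -> 1/4. For two loci the sib-pair
        # locus states are independent -> (1/4)^2.
        assert homozygous_fraction_pedigree(clavipes, CsdParams(1))[1] == pytest.approx(
            0.25
        )
        assert homozygous_fraction_pedigree(clavipes, CsdParams(2))[1] == pytest.approx(
            1 / 16
        )

    @pytest.mark.parametrize("preset", ["heterotoma", "clavipes"])
    def test_never_exceeds_one_half_under_single_locus_csd(self, preset):
        fracs = homozygous_fraction_pedigree(CrossScheme.preset(preset), CsdParams(1))
        assert all(f <= 0.5 + 1e-12 for f in fracs)

    @pytest.mark.parametrize("preset", ["heterotoma", "clavipes"])
    def test_decreases_with_number_of_loci(self, preset):
        scheme = CrossScheme.preset(preset, n_brother_sister=3)
        by_k = {
            k: homozygous_fraction_pedigree(scheme, CsdParams(k)) for k in (1, 2, 3)
        }
        for g in range(1, len(scheme.steps)):
            assert by_k[1][g] > by_k[2][g] > by_k[3][g]

    def test_enumeration_guard(self, heterotoma):
        with pytest.raises(ValueError, match="Monte Carlo"):
            homozygous_fraction_pedigree(heterotoma, CsdParams(6))
        long_scheme = CrossScheme.preset("heterotoma", n_brother_sister=8)
        with pytest.raises(ValueError, match="Monte Carlo"):
            homozygous_fraction_pedigree(long_scheme, CsdParams(1))

    def test_generation_distributions_are_normalized(self, clavipes, k1):
        for gen in pedigree_distributions(clavipes, k1):
            assert sum(gen.diploid.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(gen.haploid.values()) == pytest.approx(1.0, abs=1e-12)
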