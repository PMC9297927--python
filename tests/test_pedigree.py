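"""Stochastic inbreeding simulator: broods, pair selection, replicate runs."""

import math

import numpy as np
import pandas as pd
import pytest

from csdsim import (
    BroodModel,
    CrossScheme,
    CrossStep,
    CsdParams,
    Extinct,
    Genotype,
    Sex,
    compare_to_observed,
    init_f0,
    next_pair,
    produce_brood,
    run_replicate,
    run_simulation,
)

A, B, C = 0, 1, 2


def fixed_brood(size, f):
    return BroodModel.empirical([(size, f)])


class TestInitF0:
    @pytest.mark.parametrize("k", [1, 3])
    def test_founders_maximize_heterozygosity(self, k):
        mother, father = init_f0(CsdParams(n_loci=k))
        assert mother.genotype == Genotype.diploid([(A, B)] * k)
        assert father.genotype == Genotype.haploid([C] * k)

    def test_f1_diploids_all_heterozygous_and_sons_a_or_b(self, rng):
        csd = CsdParams(n_loci=3)
        mother, father = init_f0(csd)
        brood = produce_brood(mother, father, fixed_brood(400, 0.5), csd, rng)
        for ind in brood:
            if ind.genotype.ploidy == 2:
                assert ind.sex is Sex.FEMALE  # A/C or B/C at every locus
                assert not ind.genotype.is_homozygous()
            else:
                assert all(a in (A, B) for (a,) in ind.genotype.loci)


class TestProduceBrood:
    def test_zero_fertilization_gives_only_haploid_males(self, rng, k1):
        mother, father = init_f0(k1)
        brood = produce_brood(mother, father, fixed_brood(50, 0.0), k1, rng)
        assert all(ind.sex is Sex.HAPLOID_MALE for ind in brood)

    def test_outcross_full_fertilization_gives_only_females(self, rng, k1):
        mother, father = init_f0(k1)
        brood = produce_brood(mother, father, fixed_brood(50, 1.0), k1, rng)
        assert all(ind.sex is Sex.FEMALE for ind in brood)

    def test_mother_son_cross_yields_half_diploid_males(self, rng, k1):
        # The enumeration oracle gives exactly 1/2 homozygous fertilized eggs.
        mother, _ = init_f0(k1)
        son = next(
            i
            for i in produce_brood(mother, init_f0(k1)[1], fixed_brood(60, 0.0), k1, rng)
        )
        n = 10_000
        brood = produce_brood(mother, son, fixed_brood(n, 1.0), k1, rng)
        frac = sum(ind.sex is Sex.DIPLOID_MALE for ind in brood) / n
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_empty_brood_allowed(self, rng, k1):
        mother, father = init_f0(k1)
        assert produce_brood(mother, father, fixed_brood(0, 0.5), k1, rng) == []


class TestNextPair:
    def test_single_pair_brood_is_forced(self, rng, k1):
        mother, father = init_f0(k1)
        brood = [
            produce_brood(mother, father, fixed_brood(1, 1.0), k1, rng)[0],
            produce_brood(mother, father, fixed_brood(1, 0.0), k1, rng)[0],
        ]
        new_mother, new_father = next_pair(brood, CrossStep.BROTHER_SISTER, mother, rng)
        assert new_mother is brood[0] and new_father is brood[1]

    def test_mother_son_keeps_current_mother(self, rng, k1):
        mother, father = init_f0(k1)
        brood = produce_brood(mother, father, fixed_brood(20, 0.5), k1, rng)
        new_mother, new_father = next_pair(brood, CrossStep.MOTHER_SON, mother, rng)
        assert new_mother is mother
        assert new_father.sex is Sex.HAPLOID_MALE

    def test_missing_sex_signals_extinction(self, rng, k1):
        mother, father = init_f0(k1)
        all_female = produce_brood(mother, father, fixed_brood(10, 1.0), k1, rng)
        with pytest.raises(Extinct):
            next_pair(all_female, CrossStep.BROTHER_SISTER, mother, rng)


class TestRunReplicate:
    def test_no_csd_means_no_diploid_males_ever(self, rng, heterotoma):
        csd = CsdParams(n_loci=1, csd_enabled=False)
        summaries = run_replicate(heterotoma, csd, fixed_brood(30, 0.6), rng)
        for s in summaries:
            assert s.n_diploid_male == 0
            if not s.extinct:
                # OSR equals the realized unfertilized fraction of the brood.
                total = s.n_female + s.n_haploid_male
                assert s.osr == pytest.approx(s.n_haploid_male / total)

    def test_extinct_generations_carry_flag_and_undefined_ratios(self, rng, heterotoma, k1):
        summaries = run_replicate(heterotoma, k1, fixed_brood(1, 1.0), rng)
        # Single all-female brood: mother-son cross is impossible.
        assert any(s.extinct for s in summaries)
        for s in summaries:
            if s.extinct:
                assert s.osr is None and s.diploid_sr is None


class TestRunSimulation:
    def test_single_replicate_bands_collapse(self, heterotoma, k1):
        sim = run_simulation(heterotoma, k1, fixed_brood(40, 0.7), 1, seed=3)
        row = sim.summary.iloc[0]
        assert row["osr_lo"] == row["osr_hi"] == row["mean_osr"]

    def test_seed_reproducibility(self, heterotoma, k1, small_brood_model):
        sim1 = run_simulation(heterotoma, k1, small_brood_model, 50, seed=9)
        sim2 = run_simulation(heterotoma, k1, small_brood_model, 50, seed=9)
        pd.testing.assert_frame_equal(sim1.replicates, sim2.replicates)
        pd.testing.assert_frame_equal(sim1.summary, sim2.summary)

    def test_f1_osr_matches_no_csd_closed_form(self, heterotoma, k1, small_brood_model):
        # F1 diploids are all heterozygous females, so E[OSR] = E[1 - f].
        n_rep = 3000
        sim = run_simulation(heterotoma, k1, small_brood_model, n_rep, seed=17)
        f1 = sim.summary.iloc[0]
        expected = 1.0 - small_brood_model.mean_fertilization()
        assert abs(f1["mean_osr"] - expected) < 3 * 0.2 / math.sqrt(n_rep)

    def test_diploid_sr_centred_on_half_and_decreasing_in_loci(self, heterotoma):
        sims = {
            k: run_simulation(
                heterotoma.truncated(4),
                CsdParams(k),
                fixed_brood(30, 0.7),
                600,
                seed=23,
            )
            for k in (1, 2, 10)
        }
        ms = {k: s.summary.set_index("generation").loc["M-S"] for k, s in sims.items()}
        assert abs(ms[1]["mean_diploid_sr"] - 0.5) < 0.03
        for gen in ("M-S", "B-S 1", "B-S 2"):
            means = {
                k: s.summary.set_index("generation").loc[gen, "mean_diploid_sr"]
                for k, s in sims.items()
            }
            assert means[1] > means[2] > means[10]
            assert means[10] >= 0.0

    def test_extinction_increases_as_broods_shrink(self, heterotoma, k1):
        def extinct_fraction(mean):
            bm = BroodModel.parametric(mean=mean, dispersion=5.0)
            sim = run_simulation(heterotoma, k1, bm, 300, seed=31)
            last = sim.summary.iloc[-1]
            return 1.0 - last["n_replicates_surviving"] / 300

        assert extinct_fraction(3.0) > extinct_fraction(20.0)


class TestBroodModel:
    def test_empirical_round_trip_via_csv(self, tmp_path, rng):
        df = pd.DataFrame({"brood_size": [5, 10], "fertilization": [0.2, 0.9]})
        path = tmp_path / "broods.csv"
        df.to_csv(path, index=False)
        model = BroodModel.from_csv(path)
        for _ in range(20):
            size, f = model.sample(rng)
            assert (size, f) in {(5, 0.2), (10, 0.9)}

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            BroodModel.empirical([])
        with pytest.raises(ValueError):
            BroodModel.empirical([(5, 1.5)])
        with pytest.raises(ValueError):
            BroodModel.parametric(mean=-1.0)


class TestCompareToObserved:
    def test_exact_match_overlaps(self, heterotoma, k1, small_brood_model):
        sim = run_simulation(heterotoma, k1, small_brood_model, 200, seed=41)
        obs = sim.summary[["generation"]].copy()
        obs["osr_lo"] = sim.summary["mean_osr"]
        obs["osr_hi"] = sim.summary["mean_osr"]
        report = compare_to_observed(sim, obs)
        assert report["osr_overlap"].all()

    def test_zero_diploid_sr_outside_band_after_mother_son(self, heterotoma, k1):
        # Large broods: the simulated diploid-SR band after the M-S cross
        # sits around 1/2 and cannot contain an observed value of zero.
        sim = run_simulation(heterotoma, k1, fixed_brood(60, 0.7), 400, seed=43)
        obs = pd.DataFrame(
            {"generation": ["M-S"], "diploid_sr_lo": [0.0], "diploid_sr_hi": [0.0]}
        )
        report = compare_to_observed(sim, obs)
        assert not report["diploid_sr_overlap"].iloc[0]

    def test_unknown_generation_label_is_an_error(self, heterotoma, k1):
        sim = run_simulation(heterotoma, k1, fixed_brood(10, 0.5), 10, seed=5)
        obs = pd.DataFrame({"generation": ["nope"], "osr_lo": [0.1], "osr_hi": [0.2]})
        with pytest.raises(ValueError):
            compare_to_observed(sim, obs)


def test_band_plot_smoke(heterotoma, k1, small_brood_model):
    import matplotlib

    matplotlib.use("Agg")
    from csdsim.plotting import plot_simulation_bands

    sim = run_simulation(heterotoma, k1, small_brood_model, 30, seed=2)
    ax = plot_simulation_bands(sim, which="diploid_sr")
    assert ax.get_ylabel() == "diploid sex ratio"
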