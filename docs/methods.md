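# Methods

## The genetic model

Individuals carry `k` unlinked CSD loci. Diploids hold an unordered allele
pair per locus (stored sorted, so genotypes are canonical and hashable);
haploids hold one allele. Gametes form by independent segregation: each
locus contributes one of the parent's two alleles with probability 1/2.
Fertilization fuses a maternal gamete with the sire's (haploid) genotype.
The sex rule: haploid → male; diploid heterozygous at ≥ 1 locus → female;
diploid homozygous at all loci → diploid male. With CSD disabled every
diploid is female, which is the null model for species without CSD.
Diploid males are fully viable by default, are counted as males in sex
ratios, but are never chosen as sires (crosses select haploid males), and
triploidy is not modelled.

Every pedigree starts from a maximal-heterozygosity outcross: an A/B female
at every locus mated to an unrelated C male, so all fertilized F1 eggs are
heterozygous (A/C or B/C) and F1 sons are hemizygous A or B. Later
outcrosses (control lineages) use sires drawn from an infinite novel-allele
supply, guaranteeing heterozygous daughters — the idealization of an
outbred stock culture.

## Closed-form egg-fate expectations

For a single brood with fertilization rate `f`, all-locus homozygosity
chance `h` and inviable-diploid-male fraction `i`, the expected adult
proportions are:

| scenario | female | haploid male | diploid male | sex ratio |
|---|---|---|---|---|
| no CSD | f | 1−f | 0 | 1−f |
| CSD, inviable ♂♂ | f−i | 1−f | 0 | (1−f)/([f−i]+[1−f]) |
| CSD, viable ♂♂ | (1−h)f | 1−f | hf | (1−f)+hf |

In the inviable scenario the proportions are relative to eggs laid (they
sum to 1−i) and the sex ratio is computed on survivors. When driven from
the genotype model, i = hf; the parameter is nevertheless free, because the
table treats it as a free symbol.

## Exact pedigree enumeration

`pedigree_distributions` propagates the *joint* distribution of
(mother, sire) genotype pairs along a cross scheme. Per pair, the brood's
diploid and haploid genotype distributions follow from exact gamete
enumeration; the next pair is built per cross type (mother–son keeps the
mother and draws a son from her gametes; brother–sister draws a daughter —
conditioned within her own brood on being female — and a son). This is the
infinite-brood limit of the experiment: conditioning is per parental pair
and lineages never go extinct. The expected fraction of fertilized eggs
homozygous at all loci is read off each generation's diploid distribution
before sex conditioning.

Enumeration is exponential in `k`; it is guarded at k ≤ 5 and ≤ 8
generations and refers callers to the Monte-Carlo simulator beyond that.
Key exact values: 1/2 the generation after an M-S cross at k = 1 (and at
every later B-S generation of that scheme); 1/4 and 1/16 at the first B-S
generation of the B-S-first scheme for k = 1 and k = 2; the fraction never
exceeds 1/2 at any generation of any M-S/B-S scheme and decreases in `k`
at fixed generation.

## The stochastic simulator

Each replicate is one lineage, one breeding pair per generation (the
experiments mated single females; population-level designs are out of
scope). Per brood, size `N` and fertilization proportion `f` are drawn
jointly from the brood model — empirical (joint resampling with
replacement, preserving the size–fertilization correlation) or parametric
(negative binomial size: mean, dispersion; Beta fertilization) — and each
of the `N` eggs is independently fertilized with probability `f` (binomial
thinning; the simplest generative reading of "sampled fertilization
proportions"). Missing sexes at pair-selection time mark the replicate
extinct from that generation on; extinct generations carry undefined
ratios, stay in the replicate count, and summaries report survivors per
generation. Percentile bands (2.5/97.5 over replicates with a defined
ratio) summarize each generation, matching a 95% CI over replicate broods.
Replicate `r` uses the deterministic substream `SeedSequence(seed,
spawn_key=(r,))`, so results are bit-reproducible and independent of
execution order.

Because each replicate contributes a single brood per generation, the
diploid-SR band is a *per-brood* predictive interval. Its lower edge is
zero whenever the chance that one brood contains no diploid males —
E[(1−f/2)^N] under sl-CSD — exceeds 2.5%. With mean brood sizes around 10
that chance is ~4–8% for any realistic dispersion (it is bounded below by
the Poisson/fixed-f limit e^(−0.325·E[N])), so small-brood designs cannot
exclude a diploid-male-free brood even under sl-CSD; at mean 20 the band
excludes zero. This is the power limitation the aggregate zero-diploid
calculus (below) is designed to overcome.

## Detection power

P(no diploid males among n tested) = (1−d)^n, with `d` the expected diploid
fraction among males, multiplied over independent batches.
`power_from_simulation` estimates the same quantity from replicate
simulations using each replicate's realized per-generation `d`. Replicates
without males at a requested generation are excluded by default (a testing
plan presupposes males to test; the experiment sampled males that existed);
`require_males=False` keeps them as factor-one contributions. The
Monte-Carlo value converges to the closed form as broods grow and `d`
concentrates; at small broods it is dominated by broods that by chance
contain no diploid males, and is reported as such.

## Brood statistics

All-male broods (males but zero female adults) are the signature of unmated
mothers under arrhenotoky and are excluded before sex-ratio analysis;
broods with no adults at all are a separate "no-offspring" category, so
kept + excluded = total. Proportions carry exact Clopper–Pearson 95%
intervals (small brood counts). Two-proportion comparisons default to the
conditional exact (Fisher) test; the large-sample option is the pooled
normal test *with continuity correction*, which tracks the exact test to
within ~1% at n ≥ 500 (the uncorrected z differs by 10–20% there).
Emergence proportions divide adult wasps and non-emerged host pupae by the
total of scored host outcomes (adults + emerged flies + unemerged pupae) by
default; the recorded host count is available as an alternative
denominator. No multiple-testing correction is applied inside the module.

## Titer and thelytoky mechanism

Relative Wolbachia titer is 2 × *gssb*/*ef1a* quantity (the factor 2
corrects for the two host-gene copies per diploid cell), or
2 × E^(Ct_ef1a − Ct_gssb) from cycle thresholds with amplification
efficiency E (default 2.0, perfect doubling). The titer is scale-invariant
in the two quantities.

Egg fate in thelytokous females is titer-dependent: diploidization with
probability p_dip(titer), then (two-step variant) feminization with
p_fem(titer); non-diploidized eggs are haploid males, diploidized
non-feminized eggs are diploid males. Both responses are non-decreasing
logistics in log titer, p(t) = t^s/(t^s + θ^s) — the minimal monotone
family containing the sharp-threshold story (s → ∞ gives a step at θ; the
data motivating the model say only that a critical titer is required).
The one-step variant feminizes every diploidized egg, so it produces no
diploid males at any titer; a separated two-step model produces only
diploid males for titers between the two thresholds.

`classify_mechanism` reads a dose-response table: any diploid male found
demonstrates separated thresholds (`two_step_separated`). With zero diploid
males, the separated alternative is scored through the males tested in
mixed-sex dose rows — under a sharp separated alternative those broods
straddle the thresholds and carry diploid males at expected fraction
`d_alternative` (default 0.5) — and the verdict is
`one_step_or_coincident` when (1−d)^n ≤ α, else `inconclusive`. The joint
verdict is deliberate: titer manipulation cannot distinguish one-step
induction from a two-step mechanism whose thresholds coincide.

## Synthetic data

The generators emulate the structure of the experiments' raw tables, not
any particular dataset. Brood records: per group (inbred / control, the
latter re-outcrossed each generation), `n_families` lineages run through
the scheme; each generation yields one record. Unmated draws (probability
`p_unmated`, default 0.5 — observed all-male brood rates ranged roughly
45–90%) are recorded as all-male broods while the lineage continues from a
mated brood: the record stands for a sister female that failed to mate.
Defaults: negative-binomial brood size mean 20, dispersion 5
(overdispersion as in real brood-size boxplots); fertilization Beta(6.5,
3.5), mean 0.65, matching outcross sex ratios near 0.3–0.35; baseline
pupal mortality 0.05 for both sexes. Inbreeding depression is a geometric
survival multiplier on diploid females of inbred generation g
(survival m^g); dead wasps are added to the unemerged-pupa count and sexed
in the dissection columns, reproducing the mostly-female dead-wasp
signature without modelling deleterious loci. The
`n_diploid_male_adults` column is a ground-truth channel standing in for a
flow-cytometry ploidy assay. qPCR tables put titers on a decreasing
logistic curve in dose (plateau 6.2, the untreated-female range; half-fall
at 0.2 mg/g) with log-normal noise.

What the generators do *not* emulate: host-population dynamics and
superparasitism, family structure beyond single-female lineages,
between-strain variation, measurement error in sexing adults, and any
fitted inbreeding-depression effect size (the multiplier is illustrative).
Passing tests therefore show the pipeline's statistics are correct under
the stated generative assumptions, not that those assumptions exhaust real
data.

## Statistical choices worth noting

- Group sex-ratio comparisons on generated data use a rank test
  (Mann–Whitney) on per-brood ratios: per-brood fertilization is
  beta-distributed, so pooled-count exact tests are anti-conservative
  under the null (measured p ≈ 2×10⁻⁴ between identically generated
  groups).
- Bands are percentile-based, not normal-approximation; with one replicate
  they collapse to that replicate's values.
- Tie-breaks and degenerate inputs: zero-size broods are allowed (flagged
  no-offspring); zero-adult records never count as all-male; ratios with
  empty denominators are undefined (`None`/NaN), never zero.

## Problem sizes

The validation suite runs the oracle-equivalence check at 20 000 replicates
(k ∈ {1, 2}, three generations, total-variation tolerance 0.01), band
comparisons at 2 000 replicates, mechanism recovery over 500 seeded
datasets per variant, and the null pipeline at 200 families per group —
sizes at which every stochastic tolerance is several standard errors wide.
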