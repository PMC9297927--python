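# csdsim

Simulation and detection statistics for **complementary sex determination
(CSD)** in haplodiploid insects, with a titer-threshold model of
endosymbiont-induced thelytoky.

In haplodiploids (arrhenotoky), unfertilized eggs develop as haploid males
and fertilized eggs as diploid females. Under CSD, a fertilized egg is only
female if it is heterozygous at one (sl-CSD) or at least one of several
(ml-CSD) sex loci; diploids homozygous at *all* loci develop as **diploid
males**. Inbreeding raises homozygosity, so multi-generation mother–son
(M-S) and brother–sister (B-S) crosses are the classical assay: under CSD
they should inflate the progeny sex ratio and produce detectable diploid
males. `csdsim` provides the quantitative machinery for that assay, built
for parasitoid wasps such as *Leptopilina heterotoma* and *L. clavipes*:

- **Exact expectations** (`csdsim.genetics`) — Mendelian gamete and
  offspring genotype enumeration; the closed forms for expected offspring
  class proportions given fertilization rate *f*, all-locus homozygosity
  chance *h* and inviable-diploid-male fraction *i*
  (e.g. with viable diploid males, sex ratio = ([1−f]+hf)/([1−h]f+[1−f]+hf));
  and exact propagation of parental genotype-pair distributions along a
  pedigree, giving the per-generation expected fraction of fertilized eggs
  homozygous at all *k* loci. Under sl-CSD this fraction is exactly 1/2 the
  generation after an M-S cross and never exceeds 1/2 in any M-S/B-S scheme.
- **Stochastic simulator** (`csdsim.pedigree`) — replicated individual-based
  lineages through an inbreeding scheme, with brood sizes and fertilization
  proportions drawn from an empirical table or a negative-binomial/beta
  model, reporting operational and diploid sex ratios with 95% percentile
  bands over replicates.
- **Brood statistics** (`csdsim.broods`) — all-male brood classification and
  exclusion (unmated haplodiploid females produce all-male broods), exact
  binomial intervals and 2×2 tests, and the detection-power calculus
  P(no diploid males among n tested) = (1−d)^n.
- **Thelytoky mechanism** (`csdsim.titer`) — relative Wolbachia titer
  (2 × *gssb* / *ef1a*), a logistic titer-threshold egg-fate model, and a
  classifier separating a two-step mechanism with distinct diploidization
  and feminization thresholds (diploid males at intermediate titers) from
  one-step induction or coincident thresholds (none, ever).
- **Synthetic data** (`csdsim.synth`) — generators for brood-record, qPCR
  and dose-response tables with known ground truth.

## Worked example

Simulate the M-S + 6×B-S inbreeding design under sl-CSD (one locus) with
10 000 replicate lineages, brood sizes negative binomial (mean 20) and
fertilization Beta(6.5, 3.5):

```python
from csdsim import BroodModel, CrossScheme, CsdParams, run_simulation
from csdsim.broods import power_from_simulation, zero_diploid_probability

bm = BroodModel.parametric(mean=20, dispersion=5, beta_a=6.5, beta_b=3.5)
sim = run_simulation(CrossScheme.preset("heterotoma"), CsdParams(n_loci=1),
                     bm, 10_000, seed=42)
print(sim.summary.round(3).to_string(index=False))
```

```
generation  n_replicates_surviving  mean_osr  osr_lo  osr_hi  n_diploid_sr_defined  mean_diploid_sr  diploid_sr_lo  diploid_sr_hi
  outcross                   10000     0.350   0.000   0.750                  9972            0.000          0.000          0.000
       M-S                    9707     0.673   0.385   0.936                  9687            0.498          0.143          0.857
     B-S 1                    9219     0.673   0.385   0.933                  9195            0.497          0.143          0.846
     ...
     B-S 6                    7132     0.676   0.400   0.949                  7114            0.500          0.143          0.857
```

The F1 (outcross) generation has no diploid males — every fertilized egg is
heterozygous — and a mean operational sex ratio of 0.35 = E[1−f]. From the
M-S generation on, half the fertilized eggs are expected homozygous, so the
mean diploid sex ratio sits at 0.50 and its 95% band (0.14–0.86) excludes
zero: observing *no* diploid males in such an experiment is incompatible
with sl-CSD. The power calculus makes that quantitative:

```python
print(power_from_simulation(sim, {"B-S 1": 80}))   # 0.0201
print(zero_diploid_probability(80, 0.5))           # 8.27e-25
```

The Monte-Carlo value (0.02) is the chance that 80 males tested from a
*single* brood per replicate are all haploid — dominated by small broods
that happen to contain no diploid males — while the closed form is the
probability when the tested males independently carry the expected diploid
fraction d = 1/2, as when testing is spread over many broods.

The same machinery runs from the shell:

```sh
csdsim simulate-csd --config config.yaml --out-dir out/
csdsim brood-stats --in broods.csv --out-dir out/
csdsim mechanism --in dose_response.csv --out-dir out/
```

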