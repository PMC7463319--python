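# fragdrift

Population genetics of fragmented plant populations: microsatellite
diversity and structure statistics, pairwise relatedness and spatial
genetic autocorrelation, replicated Wright–Fisher drift simulation with
population mixing, the heterozygosity-excess bottleneck test, and
climate-suitability-change utilities — plus synthetic-data generators that
reproduce the statistical structure every analysis assumes, so the whole
stack is testable without any field data.

## Who it is for

Conservation geneticists working with small, isolated remnant populations
of outcrossing plants (the motivating system is remnant *Banksia
marginata* stands on the Victorian Volcanic Plains, genotyped at 10
microsatellite loci). The package answers the questions such surveys pose:
How much diversity does each remnant hold, and how related are its
members? How strongly are remnants differentiated (F<sub>ST</sub>), and is
there isolation by distance? Have remnants been through recent
bottlenecks? How fast will a remnant of effective size N<sub>e</sub> lose
heterozygosity and alleles, and how much does mixing remnants help? And
how will each site's climate suitability change?

## The models at the core

* **Drift**: a founding panmictic pool (random union of gametes from a
  genotype sample, N = 500 at t = 1) is resampled at constant N for
  non-overlapping generations. Expected heterozygosity decays as
  E[H<sub>e</sub>(t)] = H<sub>e</sub>(1)·(1 − 1/2N)<sup>t−1</sup>, the
  module's analytic oracle; allele number decays faster because rare
  alleles are lost first. Half-life = first generation at which the
  100-replicate mean halves.
* **Structure**: Weir & Cockerham (1984) variance components; θ =
  Σa / Σ(a+b+c) over alleles and loci, CI by bootstrap over loci,
  pairwise significance by label permutation with p = (hits+1)/(B+1).
* **Relatedness**: Queller–Goodnight, Lynch–Ritland and Loiselle
  estimators; maximum-likelihood relationship classification over
  (k₀,k₁,k₂) IBD-mode mixtures for U/HS/FS/PO.
* **Spatial autocorrelation**: Smouse–Peakall multivariate r over
  "equal sample size" distance classes with coordinate-permutation null
  envelopes; per-class mean relatedness with the standard class
  diagnostics (>100 pairs, participation >50%, CV of participation <1).
* **Bottleneck**: coalescent simulation of equilibrium gene diversity
  conditioned on the observed allele count under IAM/SMM/TPM
  (Cornuet–Luikart conditioning), one-tailed Wilcoxon signed-rank across
  loci in the excess direction, mode-shift indicator.
* **Climate niche**: Cohen's κ and κ-maximising threshold, binary niche
  overlap normalised by the current niche, Schoener's D, and per-site
  Δ-CSI = 100·(CSI<sub>future</sub> − CSI<sub>current</sub>)/CSI<sub>current</sub>.

## Worked example

```python
import numpy as np
from fragdrift.synthetic import study_spectra, generate_population, \
    MetapopSpec, generate_metapopulation
from fragdrift.diversity import diversity_summary, wc_fstatistics
from fragdrift.drift import found_panmictic, simulate_constant_n, SimConfig, half_life

# a population matched to the high-diversity remnant profile
spectra = study_spectra(10, 6.6, 0.69, seed=11)
pop = generate_population(500, spectra, seed=12)
print(diversity_summary(pop).table.round(3))

pool = found_panmictic(pop, 500, seed=13)
for n in (20, 100):
    traj = simulate_constant_n(pool, SimConfig(n=n, generations=200,
                                               replicates=100, seed=100 + n))
    print(f"N={n}: He half-life {half_life(traj, 'he')} generations, "
          f"allele half-life {half_life(traj, 'alleles')} generations")

g = generate_metapopulation(MetapopSpec(n_pops=22, n_per_pop=25, fst=0.14,
                                        spectra=tuple(map(tuple, spectra)), seed=14))
res = wc_fstatistics(g, seed=15)
print(f"theta = {res.theta:.3f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]")
```

prints

```
        n    A    r     He     Ho    Fis
pop1  500  6.6  6.6  0.687  0.692 -0.007
N=20: He half-life 30 generations, allele half-life 12 generations
N=100: He half-life 141 generations, allele half-life 59 generations
theta = 0.132  95% CI [0.110, 0.152]
```

The summary row shows the generated population hits its target profile
(6.6 alleles per locus, He ≈ 0.69, F<sub>IS</sub> ≈ 0). At effective size
20 the population loses half its heterozygosity in ~30 generations and
half its alleles in ~12; at N = 100 the half-lives stretch to ~141 and
~59 generations — small remnants erode fast. The 22-population
Balding–Nichols sample generated at F = 0.14 returns a Weir–Cockerham θ
whose CI covers the generating value.

A command-line interface wraps the same functions
(`fragdrift stats|fst|ibd|relate|autocorr|simulate|simulate-mix|bottleneck|niche|synth|run`);
`fragdrift run --config run.yaml` executes the full pipeline with a
manifest and derived per-stage seeds.

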