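# popdrift

Population-genetic impact assessment of sudden demographic disturbances,
built around multi-year microsatellite monitoring of intertidal mud-snail
populations hit by a tsunami.  The package asks, from diploid genotype
tables sampled before and after an event: did the disturbance leave a
detectable genetic signature?

It is aimed at population geneticists and monitoring programs with
Genepop-style microsatellite data from repeated yearly surveys of the same
sites, and at methodologists who want a fully simulatable test bed: a
forward Wright–Fisher generator with known demographic truth drives every
analysis stage.

## What it computes

**Bottleneck signatures within a sample**

- *Heterozygosity excess.*  For each locus with `k` observed alleles in a
  sample of `n` gene copies, the mutation–drift-equilibrium distribution of
  expected heterozygosity conditional on `k` is simulated with a coalescent
  under a two-phase mutation model (TPM; 10 % multistep mutations by
  default, geometric step size, mean 2.8 repeats).  The standardized excess
  `DH = (He − mean Heq)/SD(Heq)` is combined over loci with a one-tailed
  Wilcoxon signed-rank test (exact null enumeration up to 25 loci).  After a
  bottleneck rare alleles vanish faster than gene diversity decays, so
  `He > Heq` is the signature.
- *M-ratio.*  `M = k/(r + 1)` with `r` the allele-size range in repeat
  units; bottlenecks punch gaps into the size ladder and lower M.

**Standardized before/after comparison across years**

- *Hierarchical rarefaction.*  Both periods are standardized to the same
  number of yearly samples (`years per block`) and the same number of
  individuals (43 by default; smaller samples are excluded), drawing
  without replacement at both levels over 1,000 iterations; rarefied
  allelic richness and M-ratio changes are assessed with an exact
  two-tailed sign test across loci.
- Closed-form rarefaction is also available:
  `E[A_g] = Σ_i (1 − C(n−n_i, g)/C(n, g))`.

**Temporal effective population size**

- A Bayesian temporal method: allele-frequency drift between yearly samples
  taken generations apart estimates `N_before` (oldest sample) and
  `N_after` (newest) under an exponential growth/decline trajectory
  `N(t) = N_before (N_after/N_before)^{t/T}`, with cumulative drift
  `F(t) = 1 − Π_g (1 − 1/(2N(g)))`.  The likelihood is a
  Dirichlet-multinomial drift model that integrates the baseline sample's
  Dirichlet posterior (so baseline sampling noise is not mistaken for
  drift).  Random-walk Metropolis on `(ln N_before, ln N_after)` with a
  uniform-on-log prior up to `N = 5000`, several chains, Gelman–Rubin
  convergence checks, highest-posterior-density intervals, and the Bayes
  factor `BF = #(N_before > N_after)/#(N_before < N_after)` read on
  Jeffreys' scale (>10 strong, 3–10 substantial, 0.33–3 none, <0.33 false
  detection).

**Synthetic data**

- `popdrift.simulate` is a forward Wright–Fisher simulator of diploid
  microsatellites under the same TPM, with per-site Ne trajectories, a
  six-site/seven-year sampling design (2005–2015, ~43 individuals per
  site-year, 3-year generation time) and instantaneous crash scenarios of
  ~60 %, ~88 % and ~99 % at the 2011 generation.

## Worked example

Simulate one site crashing from Ne 500 to 60 at the 2011 generation and run
both detectors:

```python
import numpy as np
from popdrift import (GenotypeDataset, Locus, MCMCSettings, MutationModel,
                      bayes_factor, heterozygosity_excess_test,
                      posterior_summary, prepare_temporal_counts,
                      rate_of_change, run_mcmc, simulate_site,
                      make_study_design)
from popdrift.simulate import crash_scenario

mutation = MutationModel(rate=5e-3, p_multistep=0.10)
design = make_study_design(n_default=43)
scenario = crash_scenario("Mangokuura", ne_pre=500, ne_post=60,
                          crash_generation=1, span_generations=3)
samples = simulate_site(scenario, mutation, n_loci=14, design=design, seed=42)

dataset = GenotypeDataset(loci=[Locus(f"L{j+1:02d}") for j in range(14)])
for s in samples.values():
    dataset.add(s)

res = heterozygosity_excess_test(samples[2015], mutation, reps=1000, seed=7)
print(f"heterozygosity excess (2015): one-tailed Wilcoxon P = {res.p_value:.4f}")

data = prepare_temporal_counts(dataset, "Mangokuura", generation_time=3)
post = run_mcmc(data, MCMCSettings(iterations=50_000, n_runs=3,
                                   thinning=10, seed=1))
verdict = bayes_factor(post)
est = posterior_summary(post)
pre, after = est["n_before"]["mode"], est["n_after"]["mode"]
print(f"N_before = {pre:.1f}, N_after = {after:.1f}, "
      f"rate of change = {rate_of_change(pre, after)}%")
print(f"Bayes factor = {verdict.bayes_factor:.1f} ({verdict.category}), "
      f"max R-hat = {max(verdict.r_hat.values()):.3f}")
```

Output:

```
heterozygosity excess (2015): one-tailed Wilcoxon P = 0.0290
N_before = 1521.5, N_after = 16.7, rate of change = -98.9%
Bayes factor = 832.3 (strong), max R-hat = 1.001
```

The excess test flags the bottleneck (P < 0.05 two generations after the
crash), and the temporal posterior puts essentially all mass on a severe
decline — `N_after`'s 90 % HPD is [7.2, 36.3] against a truth of 60, while
`N_before` is only loosely bounded by two pre-crash sampling generations.

A thin CLI wraps the library: `popdrift simulate`, `popdrift diversity`,
`popdrift bottleneck-test`, `popdrift rarefy-compare`, `popdrift
temporal-ne`, `popdrift convert` (Genepop ↔ delimited table).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the full six-site monitoring design (three crash sites, three
stable; 14 loci; 2005–2015 surveys with the 12-individual 2013 exception)
and recomputes every stage end to end: per-site diversity, the
heterozygosity-excess test on the final-year samples, hierarchical
rarefaction with sign tests (1,000 iterations), and the temporal-Ne
posterior with rates of change, Bayes factors and Jeffreys categories,
printing a site-by-site summary.  The JSON result object is written to
`--out`.  MCMC length is reduced relative to the reference settings
(5 × 10⁶-iteration runs) to keep the script under a minute; pass
`--mcmc-iterations` to lengthen it.
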