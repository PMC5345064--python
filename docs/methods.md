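# Methods

This note documents the models behind `popdrift`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results should know
about.

## Data model

Genotypes are unordered diploid allele-size pairs (bp) per individual and
locus; a cell is missing as a unit and every statistic is complete-case
per locus.  Conversion to repeat units, `(size − offset)/repeat_unit`,
happens only where the repeat ladder matters (M-ratio, mutation models);
incongruent sizes — imperfect repeats — are reported as errors, never
silently rounded.  Genepop files use the 3-digit dialect; population
labels of the form `<site>_<year>` carry the sampling metadata, since the
format has no metadata slot.

## Mutation model

Two-phase model (TPM): a mutation is a ±1-repeat step with probability
`1 − p_multistep`, otherwise a ±Geometric step.

| parameter        | default | meaning / rationale                          |
|------------------|---------|----------------------------------------------|
| `rate` (μ)       | 5×10⁻⁴  | per-copy per-generation probability; typical microsatellite rate |
| `p_multistep`    | 0.10    | conventional TPM multistep fraction          |
| `multistep_mean` | 2.8     | geometric mean step (repeats), a conventional TPM parameterization; only the 10 % fraction is pinned by the reference analysis |
| `reflection_floor` | 5 repeats | mutations mirror-reflect; keeps sizes positive |

The same law drives the forward simulator and the equilibrium coalescent,
which keeps the heterozygosity-excess null consistent with the generator.

## Forward simulator

Discrete non-overlapping Wright–Fisher generations; each locus is a panel
of `2·Ne` gene copies; every child copy picks a uniform parental copy.
Burn-in is `10 × max(Ne)` generations from a monomorphic founder state,
validated against the strict-stepwise closed form
`He = 1 − 1/√(1+8Neμ)`.  Calendar years map to generations backward from
the newest sample, `round((anchor − year)/3)`; years landing in the same
generation are drawn independently from it (sampling is non-destructive,
without replacement within a draw).

Because census and effective size coincide in a WF population, a yearly
sample cannot exceed the current Ne; `feasible_design()` clips sample
sizes to the contemporaneous Ne after severe simulated crashes ("sample
what is there").  Real surveys do not face this: census N ≫ Ne.

**What the generator emulates:** the six-site, seven-year design
(2005, 2006, 2010, 2012–2015), ~43 individuals per site-year with a
deliberate 12-individual exception, 14 unlinked loci, a 3-year generation
time, and instantaneous crashes of ~60 %, ~88 %, ~99 % at the 2011
generation at three sites.  **What it does not:** migration between sites
(the species is a direct developer with negligible gene flow), selection,
age structure/overlapping generations, locus-specific mutation rates, and
genotyping artefacts (null alleles, allelic dropout).  A green recovery
test therefore certifies the statistical machinery under the stated
model, not robustness to those realities.

**Test/acceptance world:** tests simulate at μ = 5×10⁻³ with Ne = 500,
i.e. θ = 4Neμ = 10, which reproduces the reference data's "4–23 alleles
per locus" (θ = 1 gives ~3).  This is the study's own diversity scale —
Ne ≈ 5×10³ at μ = 5×10⁻⁴ — rescaled so the 10×Ne burn-in fits a test
budget; θ, not μ and Ne separately, controls every statistic used.

A practical finding encoded in the tests: a sample taken in the founding
generation of a crash is statistically indistinguishable from a pre-crash
sample of the same depth (the founders are an i.i.d. draw from the
parental pool).  Bottleneck signatures in samples require ≥ 2 WF
generations at the reduced Ne, so directional checks read the final
survey year.

## Heterozygosity-excess test

Per polymorphic locus, the equilibrium distribution of `He` conditional
on sample size and observed allele count `k` is simulated by a top-down
coalescent (exponential inter-node times, Poisson mutations per lineage,
TPM steps).  Conditioning on `k` uses the classic two-step scheme: θ is
calibrated by bisection on log θ (common random numbers; tolerance 0.25
alleles on the Monte-Carlo mean) so that `E[k] = k_obs`, then only
replicates with realized `k = k_obs` are retained; a retention rate below
1 % triggers a warning.  Loci are combined by a Wilcoxon signed-rank test
on `He − mean(Heq)`, one-tailed for excess; the exact null is enumerated
by the rank-sum generating polynomial (ties get average ranks, zeros are
dropped) up to 25 informative loci, beyond which a continuity-corrected
normal approximation is used.

**Known anti-conservatism.**  The conditional null of `He` given `k` is
left-skewed, so `P(He > mean Heq | k) ≈ 0.55–0.60` rather than 0.5 *at
equilibrium*.  A signed-rank test centred on the mean therefore rejects
"excess" more often than its nominal level even when data are drawn from
the exact conditional null (measured ≈ 0.10–0.18 at α = 0.05 for 14 loci
and 43 diploids, across θ from 4 to 16).  This is a property of the
classic construction, kept as the default for fidelity; the companion
sign test in the original method corrects for it by estimating the null
excess proportion from the same simulations.
`heterozygosity_excess_test(..., statistic="null_cdf")` ranks the
per-locus null CDF values `P(Heq < He) − ½` instead, which is symmetric
under the null and therefore calibrated, at the cost of departing from
the classic statistic.  Significant excess p-values from the default
statistic should be read against this inflation.

## Hierarchical rarefaction

Two-level standardization per iteration and period: draw
`years_per_block` yearly samples without replacement, then 43 individuals
without replacement within each, pool, and compute per-locus allele
number and M-ratio on pooled counts (the pool is treated as one
standardized sample, including its pooled size range).  The year subset
is redrawn every iteration — that is what hierarchically rarefying the
*populations* means; a fixed-subset variant would understate
between-year variance.  Yearly samples below the 43-individual standard
are excluded up front.  February samples count as ordinary "before"
years: winter timing affects density surveys, not genotypes.

Change is assessed with an exact two-tailed binomial sign test whose unit
is the *locus* (sign of the mean after-minus-before difference over
iterations).  Iterations resample the same individuals and are not
independent; using them as the unit would pseudo-replicate.  With 14 loci
the test only reaches P < 0.05 at a 12:2 split (P = 0.013), so it is
deliberately blunt.  When every yearly sample has exactly 43 individuals
and a period has no spare years, that period's draw is the full data and
its SD is 0; this is the designed behaviour of standardization, not a
bug.

## Temporal Ne

Trajectory: `N(t) = N_before (N_after/N_before)^{(t−½)/T}` per
generation; the midpoint exponent makes cumulative drift
`F(t) = 1 − Π(1 − 1/(2N))` exactly invariant under time reversal of the
trajectory.  Likelihood per locus: the oldest sample's counts give a
Dirichlet(1 + y₀) baseline posterior (mean p, concentration A₀ = n₀+K);
each later sample is Dirichlet-multinomial around p at effective drift

    F′(t) = F(t) + (1 − F(t)) / (A₀ + 1),

the moment-matched integral over the baseline posterior.  The 1/(A₀+1)
term is essential: without it the baseline's sampling noise appears as
drift common to all later samples, which an exponential trajectory can
only explain as a sharp early decline followed by growth — stable
simulated sites then fit `N_before ≈ 50, N_after ≈ 3000`.  With it,
stable sites give Bayes factors ≈ 1.  All sampling times enter the
likelihood (an endpoints-only flag exists); years collapsing to one
generation are pooled.

Inference: random-walk Metropolis on `(ln N_before, ln N_after)`,
Gaussian proposals (SD 0.5), uniform prior on ln Ne over [ln 2, ln 5000]
(2 is the smallest valid diploid WF size; 5000 is the reference ceiling,
and posterior pile-up at it is reported as a boundary diagnostic, not an
error).  Five chains of 10⁶ iterations, thinning 10, first half
discarded are the reference settings; tests and the acceptance script
shorten chains, which widens Monte-Carlo error but does not move the
posterior.  Convergence uses the classical potential scale reduction
factor on ln Ne ((n−1)/n·W + B/n over W; note it equals √((n−1)/n), not
exactly 1, for identical chains), flagged at 1.1.  Point estimates:
Gaussian-KDE mode on the log scale (the single-value convention of the
reference table is unstated), with median and mean also reported; HPD
intervals are the minimal-width sorted-sample windows and are nested
across mass levels by construction.  The Bayes factor is the posterior
draw-count ratio across the `N_before = N_after` diagonal, ties excluded,
`∞` reported as strong support when no growth draws exist.

`MCMCSettings.importance_samples` (reference value 100) is retained for
configuration fidelity; the pseudo-likelihood needs no importance
sampling, and the field is reserved as the Monte-Carlo depth of an
optional simulated-likelihood variant.

## Degenerate inputs and tie-breaks

- Monomorphic loci: He = Ho = 0, M = 1; excluded from the excess test
  (Heq undefined at k = 1).
- Wilcoxon with all-zero differences: p = 1.  Sign test with all-zero
  locus differences: p = 1 with a warning; fewer than 5 informative loci
  warns of negligible power.
- `F ≥ 1` in the drift model is floored at 1 − 10⁻⁹ with a warning;
  `F′ < 10⁻⁹` degenerates analytically to multinomial resampling.
- Rarefaction seed reuse across comparisons at the same site is detected
  and warned (pseudo-replication guard).
- Acceptance rates outside [1 %, 90 %] trigger a retuning warning
  (prior-only runs sit at ≈ 90 % by construction).

## Known limitations

- The temporal likelihood is a drift-diffusion approximation, not the
  full genealogical importance-sampling likelihood of the reference
  implementation; absolute Ne values carry its biases (moderate declines
  two generations before the last sample are often unresolvable — as in
  the reference analysis, where one such site's Bayes factor fell below
  the support threshold).
- The default heterozygosity-excess statistic is anti-conservative (see
  above); its type-I error is the one red acceptance check, kept red by
  design.
- One-repeat generation mapping treats all loci as evolving at one rate;
  real loci vary.
- Rarefaction p-values are exact only as binomial sign tests; they ignore
  correlation among loci induced by shared demography.
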