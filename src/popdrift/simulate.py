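"""Forward-time Wright-Fisher simulator of diploid microsatellite genotypes.

The simulator produces temporally sampled genotype data under a two-phase
mutation model (TPM) and an arbitrary per-generation Ne trajectory, so that
bottleneck statistics and temporal Ne estimators can be exercised against a
known truth.  It emulates a six-site, seven-year intertidal monitoring
design: yearly samples of ~43 snails per site, 14 microsatellite loci,
a 3-year generation time, and an instantaneous demographic crash at a
subset of sites in 2011.

Model
-----
Each locus is an unlinked panel of ``2*Ne`` gene copies whose states are
allele sizes in repeat units.  Every generation each child copy picks a
uniform random parental copy (standard WF resampling; generations are
discrete and non-overlapping).  A copy mutates with probability ``rate``
per generation; a mutation is a single +-1 repeat step with probability
``1 - p_multistep``, otherwise a +-Geometric step (mean ``multistep_mean``
repeats), reflecting off ``reflection_floor`` so sizes stay positive.

Sampling is non-destructive: drawing individuals for a yearly sample does
not remove them from the breeding population.  Calendar years map to
generation indices counted backward from the newest sample,
``round((anchor_year - year) / generation_time)``; years that collapse to
the same index are drawn (independently) from the same generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import GenotypeDataset, Locus, PopulationSample

__all__ = [
    "MutationModel",
    "DemographyScenario",
    "SamplingDesign",
    "constant_scenario",
    "crash_scenario",
    "make_study_design",
    "make_study_scenarios",
    "simulate_site",
    "simulate_dataset",
]

#: calendar years of the monitoring surveys
STUDY_YEARS = (2005, 2006, 2010, 2012, 2013, 2014, 2015)
#: years per generation observed for the mud snail
GENERATION_TIME = 3
#: calendar year of the disturbance
TSUNAMI_YEAR = 2011

#: study sites; the first three crashed (tsunami / subsidence), magnitudes
#: follow the observed Ne rates of change (-60.3%, -87.7%, -98.7%)
STUDY_SITES = (
    "Nagatsuraura",
    "Mangokuura",
    "Torinoumi",
    "Katsugigaura",
    "Sokanzan",
    "Matsukawaura",
)
DEFAULT_CRASH_FRACTIONS = {
    "Nagatsuraura": 0.603,
    "Mangokuura": 0.877,
    "Torinoumi": 0.987,
}


@dataclass(frozen=True)
class MutationModel:
    """Two-phase microsatellite mutation law.

    rate:
        Per-copy per-generation mutation probability (default 5e-4, a
        typical microsatellite rate).
    p_multistep:
        Fraction of mutations that are multistep (0 gives the strict
        stepwise model, SMM); 0.10 is the conventional TPM setting used
        here.
    multistep_mean:
        Mean of the geometric step-size law for multistep mutations, in
        repeats (sign is symmetric).
    reflection_floor:
        Minimum allele size in repeat units; mutations reflect off it.
    """

    rate: float = 5e-4
    p_multistep: float = 0.10
    multistep_mean: float = 2.8
    reflection_floor: int = 5

    def __post_init__(self) -> None:
        # rate 0 is allowed as a degenerate no-mutation model (useful for
        # validating drift-only behaviour); realistic rates are well below 5%
        if not 0.0 <= self.rate <= 0.05:
            raise ValueError(f"rate must be in [0, 0.05], got {self.rate}")
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must be in [0, 1]")
        if self.multistep_mean < 1.0:
            raise ValueError("multistep_mean must be >= 1 repeat")

    def draw_steps(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Signed repeat-unit displacements for ``n`` mutations."""
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        multi = rng.random(n) < self.p_multistep
        steps = np.ones(n, dtype=np.int64)
        n_multi = int(multi.sum())
        if n_multi:
            steps[multi] = rng.geometric(1.0 / self.multistep_mean, n_multi)
        signs = rng.integers(0, 2, n) * 2 - 1
        return steps * signs


@dataclass(frozen=True)
class DemographyScenario:
    """Per-generation diploid Ne trajectory for one site.

    ``trajectory`` maps backward generation index (0 = generation of the
    newest sample) to Ne.  ``crash_generation`` optionally records the
    index at which an instantaneous decline was imposed.
    """

    site: str
    trajectory: dict[int, int]
    crash_generation: int | None = None

    def __post_init__(self) -> None:
        if not self.trajectory:
            raise ValueError("empty trajectory")
        for g, ne in self.trajectory.items():
            if ne < 2:
                raise ValueError(f"Ne must be >= 2 (generation {g}: {ne})")
        span = sorted(self.trajectory)
        if span != list(range(span[0], span[-1] + 1)) or span[0] != 0:
            raise ValueError("trajectory must cover generations 0..max without gaps")

    @property
    def max_generation(self) -> int:
        return max(self.trajectory)

    def ne_at(self, backward_generation: int) -> int:
        """Ne at a backward index; indices beyond the span use the oldest value."""
        g = min(backward_generation, self.max_generation)
        return self.trajectory[g]


@dataclass(frozen=True)
class SamplingDesign:
    """Which calendar years are sampled, and how deeply."""

    sample_years: tuple[int, ...]
    n_per_sample: dict[tuple[str, int], int] = field(default_factory=dict)
    n_default: int = 43
    generation_time: int = GENERATION_TIME
    anchor_year: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_years:
            raise ValueError("no sample years")
        anchor = self.anchor_year if self.anchor_year is not None else max(self.sample_years)
        if any(y > anchor for y in self.sample_years):
            raise ValueError("sample years must not postdate the anchor year")
        object.__setattr__(self, "anchor_year", anchor)

    def generation_index(self, year: int) -> int:
        """Backward generation index of a calendar year (0 = anchor)."""
        return int(round((self.anchor_year - year) / self.generation_time))

    def sample_size(self, site: str, year: int) -> int:
        return self.n_per_sample.get((site, year), self.n_default)

    def with_override(self, site: str, year: int, n: int) -> "SamplingDesign":
        """Return a copy with one (site, year) sample size overridden."""
        overrides = dict(self.n_per_sample)
        overrides[(site, year)] = n
        return replace(self, n_per_sample=overrides)


def make_study_design(n_default: int = 43, *, anchor_year: int = 2015) -> SamplingDesign:
    """The monitoring design: seven yearly samples, 3-year generations.

    One deliberately undersized sample (12 individuals, the Mangokuura 2013
    situation) can be added with ``with_override`` to exercise the
    exclusion rule of the rarefaction comparison.
    """
    return SamplingDesign(sample_years=STUDY_YEARS, n_default=n_default,
                          anchor_year=anchor_year)


def constant_scenario(site: str, ne: int, span_generations: int) -> DemographyScenario:
    return DemographyScenario(
        site=site, trajectory={g: ne for g in range(span_generations + 1)}
    )


def crash_scenario(site: str, ne_pre: int, ne_post: int, crash_generation: int,
                   span_generations: int) -> DemographyScenario:
    """Instantaneous decline: Ne = ne_post for indices <= crash_generation."""
    traj = {
        g: (ne_post if g <= crash_generation else ne_pre)
        for g in range(span_generations + 1)
    }
    return DemographyScenario(site=site, trajectory=traj,
                              crash_generation=crash_generation)


def make_study_scenarios(
    base_ne: int = 500,
    crash_fractions: dict[str, float] | None = None,
    design: SamplingDesign | None = None,
) -> dict[str, DemographyScenario]:
    """Six site scenarios: three crashes (~60%, ~88%, ~99%) and three stable.

    The crash lands at the generation containing the 2011 disturbance
    (index 1 under the default design).  Crash magnitudes default to the
    observed Ne rates of change and are configurable per site.
    """
    design = design or make_study_design()
    fractions = dict(DEFAULT_CRASH_FRACTIONS)
    if crash_fractions:
        fractions.update(crash_fractions)
    span = max(design.generation_index(y) for y in design.sample_years)
    crash_gen = design.generation_index(TSUNAMI_YEAR)
    scenarios: dict[str, DemographyScenario] = {}
    for site in STUDY_SITES:
        if site in fractions:
            ne_post = max(2, int(round(base_ne * (1.0 - fractions[site]))))
            scenarios[site] = crash_scenario(site, base_ne, ne_post,
                                             crash_gen, span)
        else:
            scenarios[site] = constant_scenario(site, base_ne, span)
    return scenarios


def feasible_design(
    design: SamplingDesign, scenarios: dict[str, DemographyScenario],
) -> SamplingDesign:
    """Clip per-(site, year) sample sizes to the contemporaneous Ne.

    In a WF simulator the census and effective sizes coincide, so a yearly
    sample cannot exceed the current Ne -- unlike a field survey, where the
    census population is typically much larger than Ne.  After a severe
    simulated crash the standard sampling depth may be infeasible; this
    helper emulates "sample what is there".
    """
    overrides = dict(design.n_per_sample)
    for site, scenario in scenarios.items():
        for year in design.sample_years:
            ne = scenario.ne_at(design.generation_index(year))
            n = design.sample_size(site, year)
            if n > ne:
                overrides[(site, year)] = ne
    return replace(design, n_per_sample=overrides)


def _evolve(state: np.ndarray, ne_children: int, mutation: MutationModel,
            rng: np.random.Generator) -> np.ndarray:
    """One WF generation: resample 2*ne_children copies per locus, mutate."""
    n_loci = state.shape[0]
    n_copies = 2 * ne_children
    parents = rng.integers(0, state.shape[1], size=(n_loci, n_copies))
    child = state[np.arange(n_loci)[:, None], parents]
    hits = rng.random((n_loci, n_copies)) < mutation.rate
    n_hits = int(hits.sum())
    if n_hits:
        steps = mutation.draw_steps(n_hits, rng)
        child[hits] = child[hits] + steps
        # mirror-reflect at the floor so sizes stay >= reflection_floor
        low = child < mutation.reflection_floor
        child[low] = 2 * mutation.reflection_floor - child[low]
    return child


def _draw_sample(state: np.ndarray, site: str, year: int, n: int,
                 loci: list[Locus], rng: np.random.Generator) -> PopulationSample:
    """Draw n diploid individuals without replacement (non-destructive)."""
    ne = state.shape[1] // 2
    if n > ne:
        raise ValueError(
            f"sample of {n} individuals exceeds population size {ne} "
            f"({site} {year})"
        )
    chosen = rng.choice(ne, size=n, replace=False)
    # individual i owns gene copies (2i, 2i+1); convert repeats -> bp
    geno = np.empty((n, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        reps = state[j]
        geno[:, j, 0] = reps[2 * chosen] * locus.repeat_unit + locus.size_offset
        geno[:, j, 1] = reps[2 * chosen + 1] * locus.repeat_unit + locus.size_offset
    ids = [f"{site}_{year}" if i == 0 else f"{site}_{year}_i{i + 1}"
           for i in range(n)]
    return PopulationSample(site=site, year=year, individual_ids=ids,
                            genotypes=geno)


def simulate_site(
    scenario: DemographyScenario,
    mutation: MutationModel,
    n_loci: int,
    design: SamplingDesign,
    seed: int | np.random.SeedSequence,
    *,
    loci: list[Locus] | None = None,
    founder_repeats: int = 30,
    burn_in_factor: int = 10,
) -> dict[int, PopulationSample]:
    """Simulate one site and return {year: PopulationSample}.

    A burn-in of ``burn_in_factor * max(Ne)`` generations from a
    monomorphic founder state precedes the sampled span, long enough to
    approach mutation-drift equilibrium.  With a fixed seed the output is
    bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    loci = loci or [Locus(f"L{j + 1:02d}") for j in range(n_loci)]
    if len(loci) != n_loci:
        raise ValueError("loci list length must equal n_loci")

    years_by_gen: dict[int, list[int]] = {}
    for year in design.sample_years:
        g = design.generation_index(year)
        if g < 0:
            raise ValueError(f"year {year} postdates the anchor year")
        years_by_gen.setdefault(g, []).append(year)
    max_g = max(years_by_gen)
    if scenario.max_generation < max_g:
        raise ValueError(
            f"trajectory spans {scenario.max_generation} generations but the "
            f"design needs {max_g}"
        )

    ne_ancient = scenario.ne_at(max_g)
    burn_in = burn_in_factor * max(scenario.trajectory.values())
    state = np.full((n_loci, 2 * ne_ancient), founder_repeats, dtype=np.int64)
    for _ in range(burn_in):
        state = _evolve(state, ne_ancient, mutation, rng)

    samples: dict[int, PopulationSample] = {}
    for g in range(max_g, -1, -1):
        if g < max_g:
            state = _evolve(state, scenario.ne_at(g), mutation, rng)
        for year in sorted(years_by_gen.get(g, [])):
            n = design.sample_size(scenario.site, year)
            samples[year] = _draw_sample(state, scenario.site, year, n, loci, rng)
    return samples


def simulate_dataset(
    scenarios: dict[str, DemographyScenario],
    mutation: MutationModel,
    n_loci: int,
    design: SamplingDesign,
    seed: int,
) -> GenotypeDataset:
    """Simulate every site independently into one GenotypeDataset."""
    loci = [Locus(f"L{j + 1:02d}") for j in range(n_loci)]
    dataset = GenotypeDataset(loci=loci, samples={})
    children = np.random.SeedSequence(seed).spawn(len(scenarios))
    for child, site in zip(children, sorted(scenarios)):
        site_samples = simulate_site(scenarios[site], mutation, n_loci,
                                     design, child, loci=loci)
        for sample in site_samples.values():
            dataset.add(sample)
    return dataset
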