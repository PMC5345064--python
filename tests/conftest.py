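"""Shared fixtures: hand-built and simulated genotype datasets."""

from __future__ import annotations

import numpy as np
import pytest

from popdrift import (
    GenotypeDataset,
    Locus,
    MutationModel,
    PopulationSample,
    make_study_design,
    make_study_scenarios,
    simulate_dataset,
)
from popdrift.simulate import feasible_design


@pytest.fixture
def tpm() -> MutationModel:
    """Default two-phase model (10% multistep)."""
    return MutationModel()


@pytest.fixture
def tpm_rich() -> MutationModel:
    """TPM at theta = 4*500*5e-3 = 10 for Ne=500: reproduces the study's
    per-locus allele counts (roughly 5-16 per sample) at a burn-in length
    that stays testable."""
    return MutationModel(rate=5e-3)


def make_random_dataset(
    site_years: dict[tuple[str, int], int],
    n_loci: int = 3,
    seed: int = 0,
    n_alleles: int = 6,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Random genotypes on a dinucleotide ladder; no demography implied."""
    rng = np.random.default_rng(seed)
    loci = [Locus(f"L{j + 1:02d}") for j in range(n_loci)]
    ds = GenotypeDataset(loci=loci, samples={})
    ladder = 100 + 2 * np.arange(n_alleles)
    for (site, year), n in sorted(site_years.items()):
        geno = rng.choice(ladder, size=(n, n_loci, 2)).astype(np.int32)
        if missing_rate > 0:
            miss = rng.random((n, n_loci)) < missing_rate
            geno[miss] = 0
        ids = [f"{site}_{year}" if i == 0 else f"{site}_{year}_i{i + 1}"
               for i in range(n)]
        ds.add(PopulationSample(site=site, year=year, individual_ids=ids,
                                genotypes=geno))
    return ds


@pytest.fixture(scope="session")
def study_dataset_small():
    """Full 6-site x 7-year design at reduced scale (Ne 60, 15 ind, 5 loci).

    Sample sizes are clipped to the contemporaneous Ne at severely crashed
    sites (a Wright-Fisher feasibility constraint).
    """
    design = make_study_design(n_default=15)
    scenarios = make_study_scenarios(base_ne=60, design=design)
    design = feasible_design(design, scenarios)
    mutation = MutationModel(rate=5e-3)
    ds = simulate_dataset(scenarios, mutation, n_loci=5, design=design, seed=13)
    expected_total = sum(
        design.sample_size(site, year)
        for site in scenarios
        for year in design.sample_years
    )
    return ds, design, expected_total
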