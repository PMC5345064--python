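"""Hierarchical rarefaction of diversity indices before vs after a disturbance.

Monitoring designs rarely balance themselves: the number of yearly samples
and the number of individuals per sample differ between the pre- and
post-disturbance periods.  This module standardizes both levels at once:

* per iteration and period, draw ``years_per_block`` yearly samples
  without replacement from the period's usable years;
* within each drawn yearly sample, draw ``n_individuals`` individuals
  without replacement;
* pool the drawn individuals into one standardized population sample and
  compute, per locus, the allele number and the M-ratio (on pooled counts
  and pooled size range).

Across 1,000 such iterations the per-period mean +- SD of the across-locus
means is reported, and the change is assessed with an exact two-tailed
sign test on the *loci*: each locus contributes the sign of its mean
(over iterations) after-minus-before difference.  Using loci -- not
iterations -- as the unit avoids pseudo-replication, since iterations
resample the same individuals.

Yearly samples smaller than ``n_individuals`` are excluded up front (the
43-individual standard excludes, e.g., a 12-individual sample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .diversity import m_ratio
from .genotype_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodDesign",
    "RarefactionResult",
    "build_period_design",
    "hierarchical_rarefy",
    "sign_test_change",
]

_SEEDS_SEEN: set[tuple[str, int]] = set()


@dataclass(frozen=True)
class PeriodDesign:
    """Standardized before/after resampling layout for one site."""

    site: str
    before_years: tuple[int, ...]
    after_years: tuple[int, ...]
    years_per_block: int
    n_individuals: int = 43
    iterations: int = 1000
    excluded: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.before_years or not self.after_years:
            raise ValueError("each period needs at least one usable year")
        if self.years_per_block > min(len(self.before_years),
                                      len(self.after_years)):
            raise ValueError("years_per_block exceeds a period's year count")
        if self.years_per_block < 1 or self.iterations < 1:
            raise ValueError("years_per_block and iterations must be >= 1")

    @property
    def pool_size(self) -> int:
        """Individuals pooled per period per iteration."""
        return self.n_individuals * self.years_per_block

    @property
    def samples_in_total(self) -> int:
        """Individuals entering one iteration across both periods."""
        return self.pool_size * 2


def build_period_design(
    dataset: GenotypeDataset,
    site: str,
    tsunami_year: int = 2011,
    n_individuals: int = 43,
    iterations: int = 1000,
) -> PeriodDesign:
    """Derive the before/after design for a site from the data at hand.

    Usable years have at least ``n_individuals`` individuals; smaller
    samples are excluded and logged.  ``before`` is every usable year
    strictly before the disturbance, ``after`` every usable year from the
    following calendar year on, and ``years_per_block`` is the smaller
    period's year count (so both periods are standardized to the same
    number of yearly samples).
    """
    years = dataset.years(site)
    if not years:
        raise ValueError(f"site {site!r} not present in dataset")
    usable, excluded = [], []
    for y in years:
        n = dataset.samples[(site, y)].n_individuals
        if n >= n_individuals:
            usable.append(y)
        else:
            excluded.append((y, n))
            logger.info(
                "excluding %s %d from rarefaction: %d < %d individuals",
                site, y, n, n_individuals,
            )
    before = tuple(y for y in usable if y < tsunami_year)
    after = tuple(y for y in usable if y >= tsunami_year + 1)
    if not before or not after:
        raise ValueError(
            f"site {site!r}: no usable years on one side of {tsunami_year} "
            f"(before={before}, after={after})"
        )
    return PeriodDesign(
        site=site,
        before_years=before,
        after_years=after,
        years_per_block=min(len(before), len(after)),
        n_individuals=n_individuals,
        iterations=iterations,
        excluded=tuple(excluded),
    )


@dataclass
class RarefactionResult:
    """Per-iteration rarefied indices and their before/after summaries.

    ``richness`` and ``m`` have shape (iterations, 2) with columns
    (before, after) holding across-locus means; ``locus_richness`` and
    ``locus_m`` keep the underlying per-locus values, shape
    (iterations, 2, n_loci).
    """

    design: PeriodDesign
    locus_names: list[str]
    richness: np.ndarray
    m: np.ndarray
    locus_richness: np.ndarray
    locus_m: np.ndarray

    @property
    def locus_mean_diff_richness(self) -> np.ndarray:
        """Per-locus mean (over iterations) after-minus-before richness."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.locus_richness[:, 1] -
                              self.locus_richness[:, 0], axis=0)

    @property
    def locus_mean_diff_m(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.locus_m[:, 1] - self.locus_m[:, 0], axis=0)

    def summary(self) -> dict:
        out = {}
        for name, arr in (("richness", self.richness), ("m_ratio", self.m)):
            out[name] = {
                "before": (float(arr[:, 0].mean()), float(arr[:, 0].std(ddof=0))),
                "after": (float(arr[:, 1].mean()), float(arr[:, 1].std(ddof=0))),
            }
        return out


def _pool_stats(
    pools: np.ndarray, dataset: GenotypeDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Across-locus allele number and M-ratio of one pooled draw.

    ``pools`` is the stacked genotype array (n_pooled, n_loci, 2).
    Returns per-locus (k, M) arrays; loci with no data give NaN.
    """
    n_loci = pools.shape[1]
    k = np.full(n_loci, np.nan)
    m = np.full(n_loci, np.nan)
    for j in range(n_loci):
        cells = pools[:, j, :]
        present = cells[cells[:, 0] != MISSING].ravel()
        if present.size == 0:
            continue
        sizes = np.unique(present)
        k[j] = sizes.size
        locus = dataset.loci[j]
        m[j] = m_ratio({int(s): 1 for s in sizes}, locus)
    return k, m


def hierarchical_rarefy(
    dataset: GenotypeDataset, design: PeriodDesign, seed: int,
) -> RarefactionResult:
    """Run the two-level resampling scheme for one site.

    Both levels draw strictly without replacement; the year subset is
    redrawn every iteration.  Reusing a seed for another comparison at the
    same site is flagged as a pseudo-replication hazard.
    """
    guard_key = (design.site, int(seed))
    if guard_key in _SEEDS_SEEN:
        warnings.warn(
            f"seed {seed} already used for site {design.site!r}; reusing "
            f"seeds across comparisons pseudo-replicates the resampling",
            RuntimeWarning,
        )
    _SEEDS_SEEN.add(guard_key)

    rng = np.random.default_rng(seed)
    n_loci = len(dataset.loci)
    periods = (design.before_years, design.after_years)
    # sort genotype arrays into deterministic year order up front
    geno = {
        y: dataset.samples[(design.site, y)].genotypes
        for y in design.before_years + design.after_years
    }
    richness = np.empty((design.iterations, 2))
    m = np.empty((design.iterations, 2))
    locus_richness = np.empty((design.iterations, 2, n_loci))
    locus_m = np.empty((design.iterations, 2, n_loci))
    for it in range(design.iterations):
        for p, years in enumerate(periods):
            chosen_years = rng.choice(len(years), size=design.years_per_block,
                                      replace=False)
            blocks = []
            for yi in sorted(chosen_years):
                g = geno[years[yi]]
                rows = rng.choice(g.shape[0], size=design.n_individuals,
                                  replace=False)
                blocks.append(g[rows])
            pool = np.concatenate(blocks, axis=0)
            assert pool.shape[0] == design.pool_size
            k_loc, m_loc = _pool_stats(pool, dataset)
            locus_richness[it, p] = k_loc
            locus_m[it, p] = m_loc
            richness[it, p] = np.nanmean(k_loc)
            m[it, p] = np.nanmean(m_loc)
    return RarefactionResult(
        design=design,
        locus_names=[loc.name for loc in dataset.loci],
        richness=richness,
        m=m,
        locus_richness=locus_richness,
        locus_m=locus_m,
    )


def sign_test_change(result: RarefactionResult) -> dict[str, float]:
    """Exact two-tailed sign test per index, with loci as the unit.

    Each locus contributes the sign of its mean after-minus-before
    difference; zero differences are dropped.  Returns
    ``{"richness": p, "m_ratio": p}``.
    """
    out = {}
    for name, diffs in (
        ("richness", result.locus_mean_diff_richness),
        ("m_ratio", result.locus_mean_diff_m),
    ):
        d = diffs[~np.isnan(diffs)]
        nonzero = d[d != 0]
        if nonzero.size == 0:
            warnings.warn(f"all per-locus {name} differences are zero",
                          RuntimeWarning)
            out[name] = 1.0
            continue
        if nonzero.size < 5:
            warnings.warn(
                f"only {nonzero.size} informative loci for the {name} sign "
                f"test; power is negligible",
                RuntimeWarning,
            )
        n_pos = int((nonzero > 0).sum())
        out[name] = float(
            binomtest(n_pos, nonzero.size, 0.5, alternative="two-sided").pvalue
        )
    return out
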