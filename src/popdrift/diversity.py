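"""Per-locus diversity statistics: heterozygosity, M-ratio, rarefied richness.

All statistics operate on allele-count maps (allele size in bp -> number of
gene copies), the output of :func:`popdrift.genotype_io.allele_counts`, so
missing genotypes are already excluded (complete-case per locus).

The M-ratio is Garza & Williamson's bottleneck indicator: the number of
observed alleles divided by the number of occupiable size classes in the
observed range, ``M = k / (r + 1)`` with the range ``r`` expressed in
repeat units.  Bottlenecks knock out interior size classes faster than they
shrink the range, pushing M down.

Rarefied allelic richness standardizes allele counts to a common sampling
depth ``g`` gene copies, either by Monte-Carlo resampling without
replacement or by the exact hypergeometric ("hurdle") formula
``E[A_g] = sum_i 1 - C(n - n_i, g) / C(n, g)``.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import GenotypeDataset, Locus, allele_counts

__all__ = [
    "expected_heterozygosity",
    "observed_heterozygosity",
    "m_ratio",
    "rarefied_richness_exact",
    "rarefied_richness_resample",
    "diversity_table",
]


def expected_heterozygosity(counts: Mapping[int, int]) -> float:
    """Nei's unbiased expected heterozygosity (gene diversity).

    He = n/(n-1) * (1 - sum p_i^2), with n the number of gene copies.
    Requires n >= 2; a monomorphic locus gives 0.
    """
    n = sum(counts.values())
    if n < 2:
        raise ValueError(f"need >= 2 gene copies for He, got {n}")
    p = np.array(list(counts.values()), dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def observed_heterozygosity(genotype_cells: np.ndarray) -> float:
    """Fraction of non-missing diploid cells with two distinct alleles.

    ``genotype_cells`` is the (n_individuals, 2) slice for one locus.
    """
    present = genotype_cells[genotype_cells[:, 0] != 0]
    if len(present) == 0:
        raise ValueError("no non-missing genotypes")
    return float(np.mean(present[:, 0] != present[:, 1]))


def m_ratio(counts: Mapping[int, int], locus: Locus) -> float:
    """Garza-Williamson M = k / (r + 1), range r in repeat units.

    Allele sizes must be congruent modulo the locus repeat unit (after
    subtracting the flanking offset); an imperfect repeat makes the size
    ladder ill-defined and is reported as an error naming the alleles.
    """
    if not counts:
        raise ValueError("empty allele-count map")
    sizes = sorted(counts)
    bad = [s for s in sizes if (s - locus.size_offset) % locus.repeat_unit != 0]
    if bad:
        raise ValueError(
            f"locus {locus.name}: allele size(s) {bad} not congruent with "
            f"repeat unit {locus.repeat_unit} (offset {locus.size_offset}); "
            f"possible imperfect repeat"
        )
    k = len(sizes)
    r = (sizes[-1] - sizes[0]) // locus.repeat_unit
    return k / (r + 1)


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness_exact(counts: Mapping[int, int], g: int) -> float:
    """Expected distinct alleles in a g-gene-copy subsample (hurdle formula).

    E[A_g] = sum_i [1 - C(n - n_i, g) / C(n, g)]; exact, no Monte Carlo.
    """
    n = sum(counts.values())
    if not 1 <= g <= n:
        raise ValueError(f"depth g={g} outside [1, {n}]")
    ni = np.array(list(counts.values()), dtype=float)
    with np.errstate(invalid="ignore"):
        log_miss = _log_comb(n - ni, g) - _log_comb(float(n), g)
    miss = np.where(n - ni < g, 0.0, np.exp(log_miss))
    return float(np.sum(1.0 - miss))


def rarefied_richness_resample(
    counts: Mapping[int, int], g: int, iterations: int,
    seed: int | np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo rarefied richness: mean and SD over iterations.

    Each iteration draws ``g`` gene copies uniformly without replacement
    and counts distinct alleles.  The SD is the empirical SD across
    iterations (matching the "+- SD" presentation of rarefied indices).
    """
    n = sum(counts.values())
    if not 1 <= g <= n:
        raise ValueError(f"depth g={g} outside [1, {n}]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.repeat(np.fromiter(counts.keys(), dtype=np.int64),
                     np.fromiter(counts.values(), dtype=np.int64))
    # row-wise random subsets of size g via partial argsort of uniforms
    keys = rng.random((iterations, n))
    idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
    draws = np.sort(pool[idx], axis=1)
    distinct = 1 + (np.diff(draws, axis=1) != 0).sum(axis=1)
    return float(distinct.mean()), float(distinct.std(ddof=0))


def diversity_table(
    dataset: GenotypeDataset,
    g_depth: int | None = None,
    iterations: int = 1000,
    seed: int = 0,
    resample: bool = False,
) -> pd.DataFrame:
    """Per-(site, year, locus) diversity summary.

    Columns: n_genes, k, Ho, He, size range r (repeat units), M-ratio, and
    -- when ``g_depth`` is given and attainable -- rarefied richness A_g
    (exact hurdle formula; with ``resample=True`` also the Monte-Carlo
    mean and SD at ``iterations`` draws).  Monomorphic loci get
    He = Ho = 0, M = 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in dataset.sorted_samples():
        for j, locus in enumerate(dataset.loci):
            counts = allele_counts(sample, j)
            if not counts:
                continue
            n = sum(counts.values())
            sizes = sorted(counts)
            r = (sizes[-1] - sizes[0]) // locus.repeat_unit
            row = {
                "site": sample.site,
                "year": sample.year,
                "locus": locus.name,
                "n_genes": n,
                "k": len(counts),
                "Ho": observed_heterozygosity(sample.genotypes[:, j, :]),
                "He": expected_heterozygosity(counts) if n >= 2 else np.nan,
                "r": r,
                "M": m_ratio(counts, locus),
            }
            if g_depth is not None:
                attainable = g_depth <= n
                row["A_g"] = (rarefied_richness_exact(counts, g_depth)
                              if attainable else np.nan)
                if resample:
                    if attainable:
                        mean, sd = rarefied_richness_resample(
                            counts, g_depth, iterations, rng)
                        row["A_g_mc"], row["A_g_sd"] = mean, sd
                    else:
                        row["A_g_mc"] = row["A_g_sd"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
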