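"""Data model and I/O for multi-site, multi-year diploid microsatellite genotypes.

The universal container is :class:`GenotypeDataset`: an ordered list of
:class:`Locus` descriptors plus a collection of :class:`PopulationSample`
objects keyed by ``(site, year)``.  Alleles are stored as raw fragment sizes
in base pairs, exactly as a genotyper reports them; conversion to repeat
units happens only inside statistics that need it (M-ratio, mutation
models), via ``(size - size_offset) / repeat_unit``.

Two text formats are supported:

* the classic Genepop dialect (3-digit allele codes, ``000`` = missing),
  the de-facto interchange format of population-genetic tools;
* a flat delimited table with columns ``site, year, individual_id`` and two
  columns per locus, convenient for spreadsheets.

A genotype cell is missing as a unit: one-sided missing (one allele typed,
the other not) is rejected at construction.  Missing alleles are encoded as
``0`` internally.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "Locus",
    "PopulationSample",
    "GenotypeDataset",
    "GenepopFormatError",
    "read_genepop",
    "write_genepop",
    "read_table",
    "write_table",
    "allele_counts",
    "check_repeat_congruence",
]


class GenepopFormatError(ValueError):
    """Raised when a Genepop file violates the dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name:
        Locus identifier.
    repeat_unit:
        Base pairs per repeat (>= 1).  A dinucleotide locus has
        ``repeat_unit=2``.
    size_offset:
        Base pairs of flanking sequence included in reported allele sizes;
        ``0`` if alleles are already expressed in repeat units.
    """

    name: str
    repeat_unit: int = 2
    size_offset: int = 0

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError(f"repeat_unit must be >= 1, got {self.repeat_unit}")
        if self.size_offset < 0:
            raise ValueError(f"size_offset must be >= 0, got {self.size_offset}")

    def to_repeat_units(self, size: int) -> float:
        """Convert an allele size in bp to repeat units."""
        return (size - self.size_offset) / self.repeat_unit


@dataclass
class PopulationSample:
    """Diploid genotypes of one site in one sampling year.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)`` with allele sizes
    in bp and 0 marking a missing cell (both slots zero).
    """

    site: str
    year: int
    individual_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int32)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_individuals, n_loci, 2)")
        if g.shape[0] < 1:
            raise ValueError("a sample needs at least one individual")
        if len(self.individual_ids) != g.shape[0]:
            raise ValueError("individual_ids length does not match genotypes")
        one_sided = (g == MISSING).sum(axis=2) == 1
        if one_sided.any():
            i, l = np.argwhere(one_sided)[0]
            raise ValueError(
                f"one-sided missing genotype for individual "
                f"{self.individual_ids[i]!r} at locus index {l}; a cell is "
                f"missing as a unit"
            )
        self.genotypes = g

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def key(self) -> tuple[str, int]:
        return (self.site, self.year)


@dataclass
class GenotypeDataset:
    """All samples of a study, sharing one ordered locus list."""

    loci: list[Locus]
    samples: dict[tuple[str, int], PopulationSample] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, sample in self.samples.items():
            if key != sample.key:
                raise ValueError(f"sample keyed {key} reports key {sample.key}")
            if sample.n_loci != len(self.loci):
                raise ValueError(
                    f"sample {key} has {sample.n_loci} loci, dataset has "
                    f"{len(self.loci)}"
                )

    def add(self, sample: PopulationSample) -> None:
        if sample.key in self.samples:
            raise ValueError(f"duplicate sample key {sample.key}")
        if sample.n_loci != len(self.loci):
            raise ValueError("locus count mismatch")
        self.samples[sample.key] = sample

    def sites(self) -> list[str]:
        return sorted({s for s, _ in self.samples})

    def years(self, site: str) -> list[int]:
        return sorted(y for s, y in self.samples if s == site)

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(name)

    def total_individuals(self) -> int:
        return sum(s.n_individuals for s in self.samples.values())

    def sorted_samples(self) -> list[PopulationSample]:
        return [self.samples[k] for k in sorted(self.samples)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if self.loci != other.loci or set(self.samples) != set(other.samples):
            return False
        for k, s in self.samples.items():
            o = other.samples[k]
            if s.individual_ids != o.individual_ids:
                return False
            if not np.array_equal(s.genotypes, o.genotypes):
                return False
        return True


def allele_counts(sample: PopulationSample, locus_index: int) -> dict[int, int]:
    """Count gene copies per allele size at one locus, missing cells dropped.

    The counts sum to ``2 * n`` where ``n`` is the number of individuals
    with a non-missing genotype at the locus.
    """
    cells = sample.genotypes[:, locus_index, :]
    present = cells[cells[:, 0] != MISSING]
    return dict(Counter(present.ravel().tolist()))


def check_repeat_congruence(dataset: GenotypeDataset) -> list[str]:
    """Report alleles inconsistent with their locus repeat structure.

    Returns human-readable messages, one per offending (locus, allele size);
    violations are reported, never silently corrected.
    """
    offenders: dict[str, set[int]] = {}
    for sample in dataset.samples.values():
        for i, locus in enumerate(dataset.loci):
            for size in allele_counts(sample, i):
                if (size - locus.size_offset) % locus.repeat_unit != 0:
                    offenders.setdefault(locus.name, set()).add(size)
    return [
        f"locus {name}: allele size(s) {sorted(sizes)} not congruent with "
        f"repeat structure"
        for name, sizes in sorted(offenders.items())
    ]


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)
_SITE_YEAR_RE = re.compile(r"^(?P<site>.+?)[_-](?P<year>\d{4})$")


def _parse_cell(token: str, width: int, line_no: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenepopFormatError(
            f"line {line_no}: genotype token {token!r} is not a "
            f"{2 * width}-digit code"
        )
    a1, a2 = int(token[:width]), int(token[width:])
    if (a1 == 0) != (a2 == 0):
        raise GenepopFormatError(
            f"line {line_no}: one-sided missing genotype {token!r}"
        )
    return a1, a2


def read_genepop(path, repeat_units: dict[str, int] | None = None) -> GenotypeDataset:
    """Read a Genepop text file (2- or 3-digit allele codes).

    Population labels matching ``<site>_<year>`` (or ``<site>-<year>``) --
    taken from the identifier of the first individual in each POP block --
    become dataset keys; other labels get sequential ``popN`` sites with
    the block index as a stand-in year.

    ``repeat_units`` optionally maps locus names to bp-per-repeat (Genepop
    itself carries no locus metadata; default dinucleotide, 2 bp).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopFormatError("empty file")

    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw)]
    # line 1 is the title; locus names follow until the first POP
    locus_names: list[str] = []
    body_start = None
    for idx, (no, ln) in enumerate(lines[1:], start=1):
        if _POP_RE.match(ln):
            body_start = idx
            break
        if ln:
            locus_names.extend(t.strip() for t in ln.split(",") if t.strip())
    if body_start is None:
        if not locus_names:
            raise GenepopFormatError("no locus names found")
        # header-only file: loci but no populations
        repeat_units = repeat_units or {}
        loci = [Locus(n, repeat_units.get(n, 2)) for n in locus_names]
        return GenotypeDataset(loci=loci, samples={})

    repeat_units = repeat_units or {}
    loci = [Locus(n, repeat_units.get(n, 2)) for n in locus_names]
    n_loci = len(loci)

    blocks: list[list[tuple[int, str]]] = []
    for no, ln in lines[body_start:]:
        if _POP_RE.match(ln):
            blocks.append([])
        elif ln:
            if not blocks:
                raise GenepopFormatError(f"line {no}: data before first POP")
            blocks[-1].append((no, ln))

    width: int | None = None
    dataset = GenotypeDataset(loci=loci, samples={})
    for b_idx, block in enumerate(blocks):
        if not block:
            raise GenepopFormatError(f"POP block {b_idx + 1} is empty")
        ids: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        for no, ln in block:
            if "," not in ln:
                raise GenepopFormatError(
                    f"line {no}: expected 'id , genotypes' with a comma"
                )
            ident, _, geno = ln.partition(",")
            tokens = geno.split()
            if len(tokens) != n_loci:
                raise GenepopFormatError(
                    f"line {no}: {len(tokens)} genotypes for {n_loci} loci"
                )
            if width is None:
                tok_len = len(tokens[0])
                if tok_len == 4:
                    width = 2
                elif tok_len == 6:
                    width = 3
                else:
                    raise GenepopFormatError(
                        f"line {no}: unknown allele-code width "
                        f"(token length {tok_len}, expected 4 or 6)"
                    )
            ids.append(ident.strip())
            rows.append([_parse_cell(t, width, no) for t in tokens])
        label = ids[0]
        m = _SITE_YEAR_RE.match(label)
        if m:
            site, year = m.group("site"), int(m.group("year"))
        else:
            site, year = f"pop{b_idx + 1}", b_idx + 1
        genotypes = np.array(rows, dtype=np.int32)
        dataset.add(
            PopulationSample(site=site, year=year, individual_ids=ids,
                             genotypes=genotypes)
        )
    return dataset


def write_genepop(dataset: GenotypeDataset, path, title: str = "popdrift dataset") -> None:
    """Write a 3-digit Genepop file; populations sorted by (site, year)."""
    max_size = 0
    for sample in dataset.samples.values():
        if sample.genotypes.size:
            max_size = max(max_size, int(sample.genotypes.max()))
    if max_size > 999:
        raise ValueError(
            f"allele size {max_size} does not fit the 3-digit Genepop code; "
            f"recode alleles (e.g. subtract flanking length or express in "
            f"repeat units) before writing"
        )
    out: list[str] = [title]
    out.extend(loc.name for loc in dataset.loci)
    for sample in dataset.sorted_samples():
        out.append("POP")
        for i, ident in enumerate(sample.individual_ids):
            cells = "".join(
                f" {a1:03d}{a2:03d}" for a1, a2 in sample.genotypes[i]
            )
            out.append(f"{ident} ,{cells}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def write_table(dataset: GenotypeDataset, path) -> None:
    """Write the delimited dialect: site, year, individual_id, 2 cols/locus."""
    records = []
    for sample in dataset.sorted_samples():
        for i, ident in enumerate(sample.individual_ids):
            rec: dict = {"site": sample.site, "year": sample.year,
                         "individual_id": ident}
            for j, locus in enumerate(dataset.loci):
                a1, a2 = sample.genotypes[i, j]
                rec[f"{locus.name}.1"] = int(a1)
                rec[f"{locus.name}.2"] = int(a2)
            records.append(rec)
    cols = ["site", "year", "individual_id"]
    for locus in dataset.loci:
        cols += [f"{locus.name}.1", f"{locus.name}.2"]
    pd.DataFrame.from_records(records, columns=cols).to_csv(path, sep="\t",
                                                            index=False)


def read_table(path, repeat_units: dict[str, int] | None = None) -> GenotypeDataset:
    """Read the delimited dialect written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t")
    fixed = {"site", "year", "individual_id"}
    locus_cols = [c for c in df.columns if c not in fixed]
    names = []
    for c in locus_cols:
        base = c.rsplit(".", 1)[0]
        if base not in names:
            names.append(base)
    repeat_units = repeat_units or {}
    loci = [Locus(n, repeat_units.get(n, 2)) for n in names]
    dataset = GenotypeDataset(loci=loci, samples={})
    for (site, year), grp in df.groupby(["site", "year"], sort=True):
        geno = np.stack(
            [grp[[f"{n}.1", f"{n}.2"]].to_numpy(dtype=np.int32) for n in names],
            axis=1,
        )
        dataset.add(
            PopulationSample(site=str(site), year=int(year),
                             individual_ids=[str(x) for x in grp["individual_id"]],
                             genotypes=geno)
        )
    return dataset
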