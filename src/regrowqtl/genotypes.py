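"""Core data containers for F2 marker/phenotype data.

Genotype calls use a fixed internal vocabulary: ``AA`` is the homozygote for
the Zea diploperennis (perennial teosinte) allele, ``BB`` the homozygote for
the maize allele, ``AB`` the heterozygote.  The field's conventional numeric
coding (1 = Zd homozygote, 2 = maize homozygote, 3 = heterozygote) is treated
strictly as an IO dialect: arithmetic on the raw codes is a trap because the
heterozygote sorts last.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

# Internal call codes (int8).  MISSING deliberately negative so that
# comparisons like ``calls == AA`` never collide with it.
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

CALL_NAMES = {AA: "AA", AB: "AB", BB: "BB", MISSING: "MISSING"}

#: numeric IO dialect: 1 <-> AA, 2 <-> BB, 3 <-> AB
NUMERIC_TO_CALL = {1: AA, 2: BB, 3: AB}
CALL_TO_NUMERIC = {v: k for k, v in NUMERIC_TO_CALL.items()}

R = "R"
NR = "NR"
#: numeric phenotype coding: 1 <-> R (regrowth), 2 <-> NR (non-regrowth)
NUMERIC_TO_STATUS = {1: R, 2: NR}
STATUS_TO_NUMERIC = {R: 1, NR: 2}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def chromosome_sort_key(label: str):
    """Natural ordering for chromosome labels ('2' before '10')."""
    return (0, int(label)) if label.isdigit() else (1, label)


@dataclass(frozen=True, order=True)
class MarkerLocus:
    """A biallelic SNP with a 1-based physical position.

    Sort order is (chromosome, position_bp), which is the canonical marker
    order everywhere in the package.
    """

    chromosome: str
    position_bp: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise DataError(f"marker {self.id!r}: position_bp must be >= 1, "
                            f"got {self.position_bp}")
        if not self.id:
            object.__setattr__(self, "id",
                               f"S{self.chromosome}_{self.position_bp}")


class GenotypeMatrix:
    """Plants x markers grid of genotype calls.

    Parameters
    ----------
    plants
        Ordered plant identifiers (rows).
    markers
        Ordered :class:`MarkerLocus` (columns), non-decreasing by
        (chromosome, position_bp).
    calls
        int8 array of shape (n_plants, n_markers) over
        {AA, AB, BB, MISSING}.
    """

    def __init__(self, plants: Sequence[str], markers: Sequence[MarkerLocus],
                 calls: np.ndarray) -> None:
        self.plants = list(plants)
        self.markers = list(markers)
        self.calls = np.asarray(calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.plants), len(self.markers)
        if self.calls.shape != (n, m):
            raise DataError(f"calls shape {self.calls.shape} != "
                            f"({n} plants, {m} markers)")
        if len(set(self.plants)) != n:
            dup = [p for p, c in Counter(self.plants).items() if c > 1]
            raise DataError(f"duplicate plant ids: {dup}")
        ids = [mk.id for mk in self.markers]
        if len(set(ids)) != m:
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise DataError(f"duplicate marker ids: {dup}")
        # markers must be grouped by chromosome with non-decreasing
        # positions within each group (chromosome label order is free)
        seen_chroms: set[str] = set()
        prev_chrom, prev_pos = None, -1
        for mk in self.markers:
            if mk.chromosome != prev_chrom:
                if mk.chromosome in seen_chroms:
                    raise DataError(f"chromosome {mk.chromosome!r} markers "
                                    "are not contiguous")
                seen_chroms.add(mk.chromosome)
                prev_chrom, prev_pos = mk.chromosome, -1
            if mk.position_bp < prev_pos:
                raise DataError(f"markers on chromosome {mk.chromosome!r} "
                                "not sorted by position_bp")
            prev_pos = mk.position_bp
        bad = ~np.isin(self.calls, (AA, AB, BB, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(f"invalid call {self.calls[i, j]} at plant "
                            f"{self.plants[i]!r}, marker {self.markers[j].id!r}")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [mk.id for mk in self.markers]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for mk in self.markers:
            seen.setdefault(mk.chromosome, None)
        return list(seen)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping marker columns selected by bool mask or index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        else:
            index = index.astype(np.intp)
        return GenotypeMatrix(self.plants,
                              [self.markers[j] for j in index],
                              self.calls[:, index])

    def take_plants(self, plant_ids: Iterable[str]) -> "GenotypeMatrix":
        pos = {p: i for i, p in enumerate(self.plants)}
        idx = [pos[p] for p in plant_ids]
        return GenotypeMatrix([self.plants[i] for i in idx], self.markers,
                              self.calls[idx, :])

    def site_missingness(self) -> np.ndarray:
        """Fraction of MISSING calls per marker."""
        return (self.calls == MISSING).mean(axis=0)

    def site_allele_counts(self) -> np.ndarray:
        """(n_markers, 2) counts of (Zd, maize) alleles from non-missing calls."""
        zd = 2 * (self.calls == AA).sum(0) + (self.calls == AB).sum(0)
        mz = 2 * (self.calls == BB).sum(0) + (self.calls == AB).sum(0)
        return np.stack([zd, mz], axis=1)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-site MAF over called alleles; sites with no calls get 0."""
        counts = self.site_allele_counts()
        tot = counts.sum(1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts.min(1) / tot
        return np.where(tot > 0, freq, 0.0)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.plants == other.plants
                and self.markers == other.markers
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return (f"GenotypeMatrix({self.n_plants} plants x "
                f"{self.n_markers} markers)")


class PhenotypeTable:
    """Mapping plant id -> regrowth status ('R' or 'NR')."""

    def __init__(self, statuses: Mapping[str, str]) -> None:
        bad = {p: s for p, s in statuses.items() if s not in (R, NR)}
        if bad:
            raise DataError(f"invalid phenotype statuses: {bad}")
        self._statuses = dict(statuses)

    def __getitem__(self, plant: str) -> str:
        return self._statuses[plant]

    def __contains__(self, plant: str) -> bool:
        return plant in self._statuses

    def __len__(self) -> int:
        return len(self._statuses)

    def __iter__(self):
        return iter(self._statuses)

    def items(self):
        return self._statuses.items()

    def plants(self) -> list[str]:
        return list(self._statuses)

    def counts(self) -> tuple[int, int, int]:
        """(n_total, n_R, n_NR)."""
        n_r = sum(1 for s in self._statuses.values() if s == R)
        return len(self._statuses), n_r, len(self._statuses) - n_r

    def as_binary(self, plants: Sequence[str]) -> np.ndarray:
        """y = 1 for R, 0 for NR, in the given plant order."""
        return np.array([1 if self._statuses[p] == R else 0 for p in plants],
                        dtype=np.int64)

    def subset(self, plants: Iterable[str]) -> "PhenotypeTable":
        return PhenotypeTable({p: self._statuses[p] for p in plants})

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, PhenotypeTable)
                and self._statuses == other._statuses)


def summarize_phenotypes(p: PhenotypeTable) -> tuple[int, int, int]:
    """Tally a phenotype table: (n_total, n_R, n_NR)."""
    return p.counts()


@dataclass
class Dataset:
    """A genotype matrix joined with a phenotype table over common plants."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    @classmethod
    def join(cls, genotypes: GenotypeMatrix,
             phenotypes: PhenotypeTable) -> "Dataset":
        """Inner-join on plant id; drops are logged with counts."""
        common = [p for p in genotypes.plants if p in phenotypes]
        g_only = [p for p in genotypes.plants if p not in phenotypes]
        p_only = [p for p in phenotypes.plants()
                  if p not in set(genotypes.plants)]
        if g_only or p_only:
            log.info("dataset join dropped %d genotyped-only and %d "
                     "phenotyped-only plants", len(g_only), len(p_only))
        if not common:
            raise DataError("genotype and phenotype plant sets are disjoint")
        return cls(genotypes.take_plants(common), phenotypes.subset(common))

    @property
    def plants(self) -> list[str]:
        return self.genotypes.plants

    def phenotype_binary(self) -> np.ndarray:
        return self.phenotypes.as_binary(self.genotypes.plants)


@dataclass
class ValidationReport:
    """Report-only consistency check of a genotype/phenotype pair."""

    n_matched: int
    genotyped_only: list[str]
    phenotyped_only: list[str]
    site_missingness: np.ndarray
    site_allele_counts: np.ndarray
    marker_ids: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"matched plants: {self.n_matched}",
                 f"genotyped only: {len(self.genotyped_only)}",
                 f"phenotyped only: {len(self.phenotyped_only)}"]
        if len(self.site_missingness):
            lines.append(f"mean site missingness: "
                         f"{self.site_missingness.mean():.4f}")
        return "\n".join(lines)


def validate_dataset(genotypes: GenotypeMatrix,
                     phenotypes: PhenotypeTable) -> ValidationReport:
    """Cross-check plant sets and per-site statistics without mutating data."""
    gset = set(genotypes.plants)
    matched = [p for p in genotypes.plants if p in phenotypes]
    return ValidationReport(
        n_matched=len(matched),
        genotyped_only=[p for p in genotypes.plants if p not in phenotypes],
        phenotyped_only=[p for p in phenotypes.plants() if p not in gset],
        site_missingness=genotypes.site_missingness(),
        site_allele_counts=genotypes.site_allele_counts(),
        marker_ids=genotypes.marker_ids(),
    )
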