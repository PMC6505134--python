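"""Synthetic F2 / backcross populations with GBS-like genotype noise.

The generator emulates the data the downstream stages consume: a biparental
cross between two fully inbred parents (Zd = AA at every site, maize = BB),
an F1 that is AB everywhere, and progeny produced by simulated meiosis with
no crossover interference — crossover counts are Poisson with mean equal to
the chromosome map length in Morgans and positions uniform in genetic
distance, so the recombination fraction between two positions follows
Haldane's map function in expectation.

Regrowth phenotypes follow the complementary-dominant model: a plant regrows
iff it carries at least one Zd allele at *every* causal locus.  A
misclassification probability ``delta`` (regrowable plants scored NR, e.g.
through dormancy or transplant loss) and an optional reverse error are
applied on top.  GBS-like noise — per-site missingness drawn from a Beta
distribution and symmetric genotyping error — is applied after phenotyping.

Physical and genetic coordinates are coupled uniformly per chromosome
(default 1 cM/Mbp), matching the default map convention of the genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (AA, AB, BB, MISSING, Dataset, GenotypeMatrix,
                        MarkerLocus, NR, PhenotypeTable, R)

__all__ = [
    "Chromosome", "GenomeSpec", "CausalModel", "NoiseSpec", "TruthRecord",
    "default_genome", "default_causal_model", "simulate_gamete",
    "simulate_f2_population", "simulate_backcross", "simulate_selfed_family",
    "apply_gbs_noise",
]


@dataclass(frozen=True)
class Chromosome:
    label: str
    length_bp: int
    map_length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.map_length_cM < 0:
            raise ValueError(f"chromosome {self.label}: lengths must be "
                             "positive")

    def cm(self, position_bp) -> np.ndarray:
        """Genetic position under the uniform bp<->cM coupling."""
        return np.asarray(position_bp, dtype=float) \
            * (self.map_length_cM / self.length_bp)


@dataclass
class GenomeSpec:
    """Chromosome layout plus marker placement.

    Markers are either evenly spaced (``markers_per_chromosome``) or given
    explicitly per chromosome label (``marker_positions``, 1-based bp).
    """

    chromosomes: list[Chromosome]
    markers_per_chromosome: int = 50
    marker_positions: Mapping[str, Sequence[int]] | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate chromosome labels")
        for chrom in self.chromosomes:
            for bp in self.positions_for(chrom.label):
                if not 1 <= bp <= chrom.length_bp:
                    raise ValueError(f"marker at {chrom.label}:{bp} outside "
                                     f"chromosome of {chrom.length_bp} bp")

    def chromosome(self, label: str) -> Chromosome:
        for c in self.chromosomes:
            if c.label == label:
                return c
        raise KeyError(f"no chromosome {label!r}")

    def positions_for(self, label: str) -> list[int]:
        if self.marker_positions is not None:
            return sorted(int(p) for p in self.marker_positions.get(label, ()))
        chrom = self.chromosome(label)
        m = self.markers_per_chromosome
        return [int(round(chrom.length_bp * (i + 1) / (m + 1)))
                for i in range(m)]

    def marker_loci(self) -> list[MarkerLocus]:
        loci = []
        for chrom in self.chromosomes:
            for bp in self.positions_for(chrom.label):
                loci.append(MarkerLocus(chrom.label, bp))
        return loci


def default_genome(n_chromosomes: int = 10, length_bp: int = 100_000_000,
                   cm_per_mbp: float = 1.0,
                   markers_per_chromosome: int = 50) -> GenomeSpec:
    """Ten 100-Mbp / 100-cM chromosomes by default (1 cM/Mbp)."""
    chroms = [Chromosome(str(i + 1), length_bp,
                         length_bp * 1e-6 * cm_per_mbp)
              for i in range(n_chromosomes)]
    return GenomeSpec(chroms, markers_per_chromosome)


@dataclass(frozen=True)
class CausalModel:
    """k dominant complementary regrowth loci plus phenotype scoring noise."""

    loci: tuple[tuple[str, int], ...] = (("2", 33_041_409), ("7", 4_284_633))
    mode: str = "complementary_dominant"
    misclassification_delta: float = 0.0  # truly regrowable scored NR
    reverse_error: float = 0.0            # non-regrowable scored R

    def __post_init__(self) -> None:
        if self.mode != "complementary_dominant":
            raise ValueError(f"unsupported mode {self.mode!r}")
        if not self.loci:
            raise ValueError("need at least one causal locus")
        for p in (self.misclassification_delta, self.reverse_error):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.loci)


def default_causal_model(**kw) -> CausalModel:
    return CausalModel(**kw)


@dataclass(frozen=True)
class NoiseSpec:
    """GBS-style genotype noise.

    ``site_missing_rate`` fixes one missing rate for every site; when None,
    each site draws its rate from Beta(a, b) (defaults mean 10%, reflecting
    locus-to-locus GBS depth variation).  ``genotype_error_rate`` replaces a
    true call (AB -> random homozygote, homozygote -> AB).  ``distortion``
    maps (chromosome, position_bp) -> beta, the probability that a
    heterozygous parent transmits the maize allele there (0.5 = Mendelian).
    """

    site_missing_rate: float | None = None
    missing_beta: tuple[float, float] = (1.0, 9.0)
    genotype_error_rate: float = 0.0
    distortion: Mapping[tuple[str, int], float] | None = None

    def __post_init__(self) -> None:
        if self.site_missing_rate is not None \
                and not 0 <= self.site_missing_rate <= 1:
            raise ValueError("site_missing_rate must be in [0, 1]")
        if not 0 <= self.genotype_error_rate <= 1:
            raise ValueError("genotype_error_rate must be in [0, 1]")
        for beta in (self.distortion or {}).values():
            if not 0 < beta < 1:
                raise ValueError("distortion beta must be in (0, 1)")


NO_NOISE = NoiseSpec(site_missing_rate=0.0)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every simulated population."""

    seed: int
    causal_loci: list[tuple[str, int]]
    causal_genotypes: np.ndarray      # (n_plants, k) calls at causal loci
    true_regrowable: np.ndarray       # (n_plants,) bool, pre-misclassification
    plants: list[str]
    site_missing_rates: np.ndarray | None = None
    n_missing_applied: np.ndarray | None = None
    n_errors_applied: np.ndarray | None = None

    def phenotype_from_truth(self) -> np.ndarray:
        return self.true_regrowable

    def to_frame(self) -> pd.DataFrame:
        cols = {"plant": self.plants,
                "true_regrowable": self.true_regrowable.astype(int)}
        for j, (chrom, bp) in enumerate(self.causal_loci):
            cols[f"causal_{chrom}_{bp}"] = self.causal_genotypes[:, j]
        return pd.DataFrame(cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Meiosis engine
# ---------------------------------------------------------------------------

def _gamete_hap_sources(n_gametes: int, chrom: Chromosome,
                        query_cm: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Which parental haplotype (0/1) each gamete carries at each query.

    Crossovers form a Poisson process of rate 1/100 per cM along the
    chromosome; the carried haplotype flips at each crossover, starting from
    a fair random choice.  Fully vectorised: crossovers are scattered into
    the bins between query positions and cumulated.
    """
    m = len(query_cm)
    counts = rng.poisson(chrom.map_length_cM / 100.0, n_gametes)
    starts = rng.integers(0, 2, n_gametes)
    if m == 0:
        return np.zeros((n_gametes, 0), dtype=np.int8)
    total = int(counts.sum())
    if total:
        pos = rng.uniform(0.0, chrom.map_length_cM, total)
        gidx = np.repeat(np.arange(n_gametes), counts)
        bins = np.searchsorted(query_cm, pos, side="left")
        scat = np.zeros((n_gametes, m + 1), dtype=np.int32)
        np.add.at(scat, (gidx, bins), 1)
        below = np.cumsum(scat[:, :m], axis=1)
    else:
        below = np.zeros((n_gametes, m), dtype=np.int32)
    return ((starts[:, None] + below) % 2).astype(np.int8)


def _f1_gamete_alleles(n_gametes: int, chrom: Chromosome,
                       query_cm: np.ndarray, rng: np.random.Generator,
                       distortion_beta: np.ndarray | None = None,
                       distortion_idx: np.ndarray | None = None) -> np.ndarray:
    """Alleles (0 = Zd, 1 = maize) transmitted by the F1 at query positions.

    The F1 haplotypes are all-Zd and all-maize, so the allele equals the
    haplotype source.  Transmission distortion is imposed by rejection
    sampling: a gamete is accepted with probability proportional to
    prod(beta if maize else 1-beta) over the distorted loci, which preserves
    the linkage structure around them.
    """
    hap = _gamete_hap_sources(n_gametes, chrom, query_cm, rng)
    if distortion_beta is None or len(distortion_beta) == 0:
        return hap
    wmax = np.prod(np.maximum(distortion_beta, 1 - distortion_beta))
    pending = np.arange(n_gametes)
    for _ in range(10_000):
        alleles = hap[pending][:, distortion_idx]
        w = np.prod(np.where(alleles == 1, distortion_beta,
                             1 - distortion_beta), axis=1) / wmax
        keep = rng.uniform(size=len(pending)) < w
        pending = pending[~keep]
        if len(pending) == 0:
            return hap
        hap[pending] = _gamete_hap_sources(len(pending), chrom, query_cm, rng)
    raise RuntimeError("distortion rejection sampling did not terminate")


def simulate_gamete(parent_haplotypes: Mapping[str, np.ndarray],
                    genome: GenomeSpec, rng: np.random.Generator,
                    query_positions: Mapping[str, Sequence[int]] | None = None,
                    ) -> dict[str, np.ndarray]:
    """One haploid chromosome set from a phased parent.

    ``parent_haplotypes`` maps chromosome label -> (2, m) allele array at
    the query positions (defaults to the genome's marker grid).
    """
    out = {}
    for chrom in genome.chromosomes:
        if query_positions is not None:
            pos = np.asarray(sorted(query_positions.get(chrom.label, ())))
        else:
            pos = np.asarray(genome.positions_for(chrom.label))
        haps = np.asarray(parent_haplotypes[chrom.label])
        if haps.shape != (2, len(pos)):
            raise ValueError(f"chromosome {chrom.label}: phased parent shape "
                             f"{haps.shape} != (2, {len(pos)})")
        src = _gamete_hap_sources(1, chrom, chrom.cm(pos), rng)[0]
        out[chrom.label] = haps[src, np.arange(len(pos))]
    return out


# ---------------------------------------------------------------------------
# Population simulators
# ---------------------------------------------------------------------------

def _query_grid(genome: GenomeSpec, causal: CausalModel):
    """Per-chromosome union of marker and causal positions.

    Returns (per-chromosome positions, marker index pairs, causal index
    pairs in causal.loci order).
    """
    grid: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        pos = set(genome.positions_for(chrom.label))
        for c_label, c_bp in causal.loci:
            if c_label == chrom.label:
                if not 1 <= c_bp <= chrom.length_bp:
                    raise ValueError(f"causal locus {c_label}:{c_bp} outside "
                                     "chromosome")
                pos.add(int(c_bp))
        grid[chrom.label] = np.asarray(sorted(pos))
    known = {c.label for c in genome.chromosomes}
    for c_label, _ in causal.loci:
        if c_label not in known:
            raise ValueError(f"causal locus on unknown chromosome {c_label!r}")
    return grid


def _assemble(genome: GenomeSpec, causal: CausalModel,
              geno_by_chrom: dict[str, np.ndarray], prefix: str,
              ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Split the per-grid genotype calls into marker matrix + causal calls."""
    n = next(iter(geno_by_chrom.values())).shape[0]
    plants = [f"{prefix}-{i + 1:04d}" for i in range(n)]
    loci, cols = [], []
    causal_calls = np.zeros((n, causal.k), dtype=np.int8)
    grid = _query_grid(genome, causal)
    for chrom in genome.chromosomes:
        pos = grid[chrom.label]
        calls = geno_by_chrom[chrom.label]
        marker_set = set(genome.positions_for(chrom.label))
        for j, bp in enumerate(pos):
            if bp in marker_set:
                loci.append(MarkerLocus(chrom.label, int(bp)))
                cols.append(calls[:, j])
            for ci, (c_label, c_bp) in enumerate(causal.loci):
                if c_label == chrom.label and c_bp == bp:
                    causal_calls[:, ci] = calls[:, j]
    matrix = GenotypeMatrix(plants, loci,
                            np.stack(cols, axis=1) if cols
                            else np.zeros((n, 0), dtype=np.int8))
    return matrix, causal_calls


def _phenotype(causal_calls: np.ndarray, causal: CausalModel,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(scored R/NR bool, true regrowability bool)."""
    regrowable = (causal_calls != BB).all(axis=1)
    scored = regrowable.copy()
    n = len(scored)
    if causal.misclassification_delta > 0:
        flip = rng.uniform(size=n) < causal.misclassification_delta
        scored &= ~flip
    if causal.reverse_error > 0:
        flip = rng.uniform(size=n) < causal.reverse_error
        scored |= ~regrowable & flip
    return scored, regrowable


def _distortion_arrays(noise: NoiseSpec | None, chrom_label: str,
                       pos: np.ndarray):
    if noise is None or not noise.distortion:
        return None, None
    betas, idx = [], []
    for (c, bp), beta in noise.distortion.items():
        if c == chrom_label:
            j = np.searchsorted(pos, bp)
            if j >= len(pos) or pos[j] != bp:
                raise ValueError(f"distorted locus {c}:{bp} is not on the "
                                 "simulation grid")
            betas.append(beta)
            idx.append(j)
    if not betas:
        return None, None
    return np.asarray(betas), np.asarray(idx)


def _simulate_cross(n: int, genome: GenomeSpec, causal: CausalModel,
                    noise: NoiseSpec | None, seed: int, prefix: str,
                    recurrent: int | None) -> tuple[Dataset, TruthRecord]:
    """Shared core: F2 (recurrent=None) or backcross to allele 0/1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_meiosis, rng_pheno, rng_noise = (np.random.default_rng(s)
                                         for s in ss.spawn(3))
    grid = _query_grid(genome, causal)
    geno = {}
    for chrom in genome.chromosomes:
        pos = grid[chrom.label]
        cm = chrom.cm(pos)
        betas, idx = _distortion_arrays(noise, chrom.label, pos)
        g1 = _f1_gamete_alleles(n, chrom, cm, rng_meiosis, betas, idx)
        if recurrent is None:
            g2 = _f1_gamete_alleles(n, chrom, cm, rng_meiosis, betas, idx)
        else:
            g2 = np.full_like(g1, recurrent)
        # allele sum 0/1/2 maps to AA/AB/BB because AA=0, AB=1, BB=2
        geno[chrom.label] = (g1 + g2).astype(np.int8)
    matrix, causal_calls = _assemble(genome, causal, geno, prefix)
    scored, regrowable = _phenotype(causal_calls, causal, rng_pheno)
    truth = TruthRecord(seed=seed, causal_loci=list(causal.loci),
                        causal_genotypes=causal_calls,
                        true_regrowable=regrowable, plants=matrix.plants)
    if noise is not None:
        matrix, audit = apply_gbs_noise(matrix, noise, rng_noise)
        truth.site_missing_rates = audit["rates"]
        truth.n_missing_applied = audit["n_missing"]
        truth.n_errors_applied = audit["n_errors"]
    phen = PhenotypeTable({p: (R if s else NR)
                           for p, s in zip(matrix.plants, scored)})
    return Dataset(matrix, phen), truth


def simulate_f2_population(n: int, genome: GenomeSpec | None = None,
                           causal: CausalModel | None = None,
                           noise: NoiseSpec | None = None,
                           seed: int = 0) -> tuple[Dataset, TruthRecord]:
    """F2 progeny of (Zd x maize) F1 selfing, with phenotype and noise."""
    genome = genome or default_genome()
    causal = causal or CausalModel()
    return _simulate_cross(n, genome, causal, noise, seed, "F2", None)


def simulate_backcross(n: int, genome: GenomeSpec | None = None,
                       causal: CausalModel | None = None,
                       direction: str = "to_Zd",
                       noise: NoiseSpec | None = None,
                       seed: int = 0) -> tuple[Dataset, TruthRecord]:
    """F1 x recurrent parent.  'to_Zd' fixes a Zd allele in every gamete."""
    genome = genome or default_genome()
    causal = causal or CausalModel()
    if direction not in ("to_Zd", "to_maize"):
        raise ValueError(f"direction must be to_Zd or to_maize, "
                         f"got {direction!r}")
    recurrent = 0 if direction == "to_Zd" else 1
    return _simulate_cross(n, genome, causal, noise, seed,
                           "BC" + direction[3:], recurrent)


def simulate_selfed_family(parent_calls_at_causal: Sequence[int], n: int,
                           genome: GenomeSpec | None = None,
                           causal: CausalModel | None = None,
                           seed: int = 0) -> np.ndarray:
    """Phenotypes of one selfed family, given the parent's causal genotypes.

    Only the causal loci matter for the family segregation ratio; loci where
    the parent is homozygous are fixed, heterozygous loci segregate 1:2:1.
    Returns a bool array of scored regrowth (no genotype matrix).
    """
    genome = genome or default_genome()
    causal = causal or CausalModel()
    if len(parent_calls_at_causal) != causal.k:
        raise ValueError("need one parent call per causal locus")
    ss = np.random.SeedSequence(seed)
    rng_meiosis, rng_pheno = (np.random.default_rng(s) for s in ss.spawn(2))
    calls = np.zeros((n, causal.k), dtype=np.int8)
    for j, parent_call in enumerate(parent_calls_at_causal):
        if parent_call in (AA, BB):
            calls[:, j] = parent_call
        elif parent_call == AB:
            # unlinked single locus: two independent fair transmissions
            calls[:, j] = (rng_meiosis.integers(0, 2, n)
                           + rng_meiosis.integers(0, 2, n))
        else:
            raise ValueError(f"invalid parent call {parent_call}")
    scored, _ = _phenotype(calls, causal, rng_pheno)
    return scored


def apply_gbs_noise(g: GenotypeMatrix, noise: NoiseSpec,
                    rng: np.random.Generator,
                    ) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Apply genotyping error then missingness; returns (matrix, audit).

    The audit dict records the drawn per-site missing rates and the number
    of missing/error events applied per site.
    """
    calls = g.calls.copy()
    n, m = calls.shape
    n_err = np.zeros(m, dtype=np.int64)
    if noise.genotype_error_rate > 0 and m:
        err = rng.uniform(size=calls.shape) < noise.genotype_error_rate
        err &= calls != MISSING
        het = calls == AB
        # heterozygote miscalled as a random homozygote; homozygote as AB
        rand_hom = rng.integers(0, 2, size=calls.shape).astype(np.int8) * 2
        calls = np.where(err & het, rand_hom,
                         np.where(err & ~het, AB, calls)).astype(np.int8)
        n_err = err.sum(axis=0)
    if noise.site_missing_rate is not None:
        rates = np.full(m, float(noise.site_missing_rate))
    else:
        a, b = noise.missing_beta
        rates = rng.beta(a, b, size=m)
    miss = rng.uniform(size=calls.shape) < rates[None, :] if m else \
        np.zeros_like(calls, dtype=bool)
    calls = np.where(miss, np.int8(MISSING), calls).astype(np.int8)
    audit = {"rates": rates, "n_missing": miss.sum(axis=0),
             "n_errors": n_err}
    return GenotypeMatrix(g.plants, g.markers, calls), audit
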