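"""SNP filtration cascade for F2 genotype matrices.

Four stages, applied in a fixed order:

1. site filters — minimum call-rate (site coverage) and minor allele
   frequency, counting alleles from non-missing calls;
2. missingness filter with heterozygote imputation — sites missing in more
   than ``max_missing`` of plants are dropped, remaining missing calls are
   imputed to AB (both alleles present in the cross, so the heterozygote is
   the non-committal call);
3. model-constrained contingency chi-square — observed R/NR x AA/AB/BB
   counts per SNP against the expectations of the two-locus complementary
   (9:7) model; SNPs consistent with the model (chi2 below the critical
   value) are kept;
4. haplotype-cluster collapsing — runs of neighbouring SNPs (within a bp
   window) with identical genotype vectors collapse to their first member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import (AA, AB, BB, MISSING, Dataset, GenotypeMatrix,
                        MarkerLocus)
from .segregation import (ConditionalGenotypeDist, SegModel, chi2_critical,
                          conditional_genotype_probs)


@dataclass(frozen=True)
class FilterConfig:
    min_site_coverage: float = 0.2
    min_maf: float = 0.01
    max_missing: float = 0.2
    model_chi2_threshold: float = chi2_critical(4, 0.05)  # 9.49
    cluster_window_bp: int = 100

    def __post_init__(self) -> None:
        for name in ("min_site_coverage", "min_maf", "max_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cluster_window_bp < 0:
            raise ValueError("cluster_window_bp must be >= 0")


def site_filters(g: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Drop sites with call rate < min_site_coverage or MAF < min_maf."""
    called = 1.0 - g.site_missingness()
    keep = (called >= cfg.min_site_coverage) \
        & (g.minor_allele_frequency() >= cfg.min_maf)
    return g.take_markers(keep)


def missingness_filter_impute(g: GenotypeMatrix,
                              cfg: FilterConfig) -> GenotypeMatrix:
    """Drop sites missing in more than max_missing of plants (strict >),
    then impute every remaining MISSING call as heterozygote."""
    keep = g.site_missingness() <= cfg.max_missing
    out = g.take_markers(keep)
    calls = np.where(out.calls == MISSING, np.int8(AB), out.calls)
    return GenotypeMatrix(out.plants, out.markers, calls.astype(np.int8))


@dataclass
class SnpModelFit:
    """Per-SNP contingency fit to the conditional genotype expectations."""

    marker: MarkerLocus
    observed: np.ndarray        # (2, 3): rows R, NR; cols AA, AB, BB
    expected: np.ndarray        # same shape
    chi2: float                 # +inf when an E=0 cell has observations
    df: int = 4
    keep: bool = False


def model_fit_filter(d: Dataset,
                     dist_R: ConditionalGenotypeDist | None = None,
                     dist_NR: ConditionalGenotypeDist | None = None,
                     cfg: FilterConfig | None = None) -> list[SnpModelFit]:
    """Contingency chi-square of each SNP against the 9:7-model expectations.

    Observed counts are the 6 cells (R/NR x AA/AB/BB); expected counts are
    subpopulation size times the conditional genotype probability.  Cells
    with E = 0 contribute nothing when empty but force rejection when
    occupied (the statistic's limit is +inf).  df = 4 (6 cells minus the two
    subpopulation-total constraints), matching the 9.49 critical value.

    Requires an imputed (MISSING-free) genotype matrix.
    """
    cfg = cfg or FilterConfig()
    model = SegModel(2)
    dist_R = dist_R or conditional_genotype_probs("R", model)
    dist_NR = dist_NR or conditional_genotype_probs("NR", model)
    g = d.genotypes
    if (g.calls == MISSING).any():
        raise ValueError("model_fit_filter requires an imputed matrix "
                         "(run missingness_filter_impute first)")
    y = d.phenotype_binary()
    n_R, n_NR = int(y.sum()), int((1 - y).sum())
    if n_R < 1 or n_NR < 1:
        raise ValueError("both phenotype classes must be non-empty")
    exp = np.array([[n_R * p for p in dist_R.as_floats()],
                    [n_NR * p for p in dist_NR.as_floats()]])
    fits = []
    obs_R = np.stack([(g.calls[y == 1] == c).sum(axis=0)
                      for c in (AA, AB, BB)], axis=1)
    obs_NR = np.stack([(g.calls[y == 0] == c).sum(axis=0)
                       for c in (AA, AB, BB)], axis=1)
    for j, mk in enumerate(g.markers):
        obs = np.stack([obs_R[j], obs_NR[j]]).astype(float)
        zero = exp == 0
        if (obs[zero] > 0).any():
            chi2 = np.inf
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(zero, 0.0, (obs - exp) ** 2
                                 / np.where(zero, 1.0, exp))
            chi2 = float(terms.sum())
        fits.append(SnpModelFit(mk, obs, exp.copy(), chi2,
                                keep=chi2 < cfg.model_chi2_threshold))
    return fits


def apply_model_filter(d: Dataset,
                       cfg: FilterConfig | None = None,
                       ) -> tuple[Dataset, list[SnpModelFit]]:
    """Run model_fit_filter and subset the dataset to the kept SNPs."""
    fits = model_fit_filter(d, cfg=cfg)
    keep = np.array([f.keep for f in fits])
    return Dataset(d.genotypes.take_markers(keep), d.phenotypes), fits


@dataclass
class SnpCluster:
    """A run of identical neighbouring SNPs collapsed to its first member."""

    representative: MarkerLocus
    members: list[MarkerLocus]

    @property
    def span_bp(self) -> int:
        return self.members[-1].position_bp - self.members[0].position_bp


def collapse_clusters(g: GenotypeMatrix, cfg: FilterConfig | None = None,
                      ) -> tuple[GenotypeMatrix, list[SnpCluster]]:
    """Collapse same-haplotype neighbours within the bp window.

    Left-to-right sweep per chromosome: a marker joins the open cluster iff
    its genotype vector equals the cluster signature and it lies within
    ``cluster_window_bp`` of the cluster's *first* member; otherwise a new
    cluster opens.  The output matrix keeps the first member of each
    cluster.
    """
    cfg = cfg or FilterConfig()
    clusters: list[SnpCluster] = []
    open_cluster: SnpCluster | None = None
    open_sig: np.ndarray | None = None
    for j, mk in enumerate(g.markers):
        col = g.calls[:, j]
        joins = (open_cluster is not None
                 and mk.chromosome == open_cluster.representative.chromosome
                 and mk.position_bp - open_cluster.representative.position_bp
                 <= cfg.cluster_window_bp
                 and np.array_equal(col, open_sig))
        if joins:
            open_cluster.members.append(mk)  # type: ignore[union-attr]
        else:
            open_cluster = SnpCluster(mk, [mk])
            open_sig = col
            clusters.append(open_cluster)
    keep_ids = {c.representative.id for c in clusters}
    keep = np.array([mk.id in keep_ids for mk in g.markers])
    return g.take_markers(keep), clusters


@dataclass
class CascadeResult:
    """Products of the full filtration cascade."""

    after_site: Dataset
    after_impute: Dataset
    after_model: Dataset
    after_collapse: Dataset
    model_fits: list[SnpModelFit]
    clusters: list[SnpCluster]
    survivor_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def _per_chrom_counts(g: GenotypeMatrix) -> dict[str, int]:
    counts: dict[str, int] = {}
    for mk in g.markers:
        counts[mk.chromosome] = counts.get(mk.chromosome, 0) + 1
    return counts


def run_filter_cascade(d: Dataset,
                       cfg: FilterConfig | None = None) -> CascadeResult:
    """site -> missingness/impute -> model chi-square -> cluster collapse,
    with a per-chromosome survivor-count report per stage."""
    cfg = cfg or FilterConfig()
    g1 = site_filters(d.genotypes, cfg)
    d1 = Dataset(g1, d.phenotypes)
    g2 = missingness_filter_impute(g1, cfg)
    d2 = Dataset(g2, d.phenotypes)
    d3, fits = apply_model_filter(d2, cfg)
    g4, clusters = collapse_clusters(d3.genotypes, cfg)
    d4 = Dataset(g4, d.phenotypes)
    counts = {"input": _per_chrom_counts(d.genotypes),
              "site": _per_chrom_counts(g1),
              "missingness": _per_chrom_counts(g2),
              "model": _per_chrom_counts(d3.genotypes),
              "cluster": _per_chrom_counts(g4)}
    return CascadeResult(d1, d2, d3, d4, fits, clusters, counts)
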