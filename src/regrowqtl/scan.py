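"""Binary-trait single-locus genome scan for an F2 intercross.

The scan follows the classical interval-mapping recipe for a binary trait:

1. a genetic map places markers in cM (default convention: 1 cM/Mbp from
   the physical positions; an EM-estimated map from the genotype data is
   available for validation on simulated data);
2. conditional genotype probabilities w_ig = P(g_i = g | marker data) are
   computed at markers and at inserted pseudomarkers (grid spacing bounded
   by ``step``) with a 3-state hidden Markov chain along each chromosome —
   state prior 1/4 : 1/2 : 1/4, transitions from the recombination fraction
   of two independent meioses, and a symmetric genotyping-error emission
   model with total error probability ``error_prob``;
3. at every position the penetrances pi_g = P(y = 1 | g) of a single-QTL
   Bernoulli mixture are estimated by EM, and the LOD score is the log10
   likelihood ratio against the no-QTL null (common penetrance = mean(y));
4. genome-wide significance comes from a permutation test: phenotypes are
   shuffled across plants, the scan re-run, and the (1 - alpha) quantile of
   the maximum-LOD null distribution taken as threshold;
5. a significant locus interval spans the first to the last *observed*
   marker (pseudomarkers excluded) with LOD at or above the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotypes import (AA, AB, BB, MISSING, Dataset, GenotypeMatrix,
                        MarkerLocus, PhenotypeTable)

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane_r(d_cm) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, no interference."""
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def haldane_d(r) -> np.ndarray | float:
    """Recombination fraction -> map distance (cM); requires r < 0.5."""
    rr = np.asarray(r, dtype=float)
    if (rr < 0).any() or (rr >= 0.5).any():
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return float(d) if np.isscalar(r) else d


def f2_transition(r: float) -> np.ndarray:
    """3x3 genotype transition matrix across one interval (two meioses)."""
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


@dataclass
class GeneticMap:
    """Per-chromosome marker order and genetic positions (cM)."""

    mode: str
    chromosomes: list[str]
    marker_ids: dict[str, list[str]]
    cm: dict[str, np.ndarray]
    bp: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            if (np.diff(self.cm[c]) < 0).any():
                raise ValueError(f"chromosome {c}: cM positions decrease")


def _pair_r_ml(counts: np.ndarray) -> float:
    """ML recombination fraction from a 3x3 joint genotype count table."""
    def nll(r: float) -> float:
        joint = F2_PRIOR[:, None] * f2_transition(r)
        with np.errstate(divide="ignore"):
            ll = counts * np.log(np.maximum(joint, 1e-300))
        return -float(ll.sum())

    res = minimize_scalar(nll, bounds=(1e-6, 0.49999 - 1e-9),
                          method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def build_genetic_map(markers: list[MarkerLocus],
                      mode: str = "physical_1cM_per_Mbp",
                      genotypes: GenotypeMatrix | None = None) -> GeneticMap:
    """Place markers on a genetic map.

    ``physical_1cM_per_Mbp`` converts bp to cM directly (cM = bp * 1e-6).
    ``em_estimated`` estimates each adjacent-pair recombination fraction by
    maximum likelihood over the F2 joint genotype distribution and chains
    the Haldane-converted distances, anchoring each chromosome at 0 cM.
    """
    chroms: list[str] = []
    by_chrom: dict[str, list[MarkerLocus]] = {}
    for mk in markers:
        if mk.chromosome not in by_chrom:
            chroms.append(mk.chromosome)
            by_chrom[mk.chromosome] = []
        elif chroms[-1] != mk.chromosome:
            raise ValueError(f"chromosome {mk.chromosome!r} markers are "
                             "not contiguous")
        if by_chrom[mk.chromosome] \
                and mk.position_bp < by_chrom[mk.chromosome][-1].position_bp:
            raise ValueError(f"markers on chromosome {mk.chromosome!r} not "
                             "sorted by position")
        by_chrom[mk.chromosome].append(mk)
    ids = {c: [mk.id for mk in mks] for c, mks in by_chrom.items()}
    bp = {c: np.array([mk.position_bp for mk in mks])
          for c, mks in by_chrom.items()}
    if mode == "physical_1cM_per_Mbp":
        cm = {c: bp[c] * 1e-6 for c in chroms}
    elif mode == "em_estimated":
        if genotypes is None:
            raise ValueError("em_estimated mode needs a genotype matrix")
        col = {mk.id: j for j, mk in enumerate(genotypes.markers)}
        cm = {}
        for c, mks in by_chrom.items():
            pos = [0.0]
            for left, right in zip(mks, mks[1:]):
                a = genotypes.calls[:, col[left.id]]
                b = genotypes.calls[:, col[right.id]]
                ok = (a != MISSING) & (b != MISSING)
                counts = np.zeros((3, 3))
                np.add.at(counts, (a[ok], b[ok]), 1.0)
                r = _pair_r_ml(counts)
                pos.append(pos[-1] + haldane_d(min(r, 0.499999)))
            cm[c] = np.asarray(pos)
    else:
        raise ValueError(f"unknown map mode {mode!r}")
    return GeneticMap(mode, chroms, ids, cm, bp)


@dataclass(frozen=True)
class ScanConfig:
    step: float = 1.0            # max grid spacing, cM
    error_prob: float = 1e-4     # genotyping error allowance in the HMM
    em_tolerance: float = 1e-8   # log-likelihood change at convergence
    em_max_iter: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not 0 <= self.error_prob < 0.5:
            raise ValueError("error_prob must be in [0, 0.5)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class GenoProbTable:
    """Conditional genotype probabilities on the evaluation grid.

    ``positions`` has one row per grid point with columns chromosome, cm,
    position_bp (-1 for pseudomarkers), marker_id ('' for pseudomarkers)
    and is_marker.  ``probs`` is (n_plants, n_positions, 3) over
    (AA, AB, BB), each triple summing to 1.
    """

    plants: list[str]
    positions: pd.DataFrame
    probs: np.ndarray
    error_prob: float


def _grid_for_chrom(cm: np.ndarray, bp: np.ndarray, ids: list[str],
                    step: float):
    """Insert pseudomarkers so adjacent grid spacing <= step, evenly."""
    g_cm, g_bp, g_id, g_marker = [], [], [], []
    for j in range(len(cm)):
        g_cm.append(float(cm[j]))
        g_bp.append(int(bp[j]))
        g_id.append(ids[j])
        g_marker.append(True)
        if j + 1 < len(cm):
            gap = cm[j + 1] - cm[j]
            n_extra = max(0, math.ceil(gap / step) - 1)
            for t in range(1, n_extra + 1):
                g_cm.append(float(cm[j] + gap * t / (n_extra + 1)))
                g_bp.append(-1)
                g_id.append("")
                g_marker.append(False)
    return g_cm, g_bp, g_id, g_marker


def calc_genoprob(d: Dataset | GenotypeMatrix, gmap: GeneticMap,
                  cfg: ScanConfig | None = None) -> GenoProbTable:
    """Forward-backward genotype posteriors along each chromosome.

    Markers may carry MISSING calls (uninformative emission).  The emission
    model allows a total genotyping-error probability ``error_prob``, split
    evenly between the two wrong genotype classes.
    """
    cfg = cfg or ScanConfig()
    g = d.genotypes if isinstance(d, Dataset) else d
    eps = cfg.error_prob
    col = {mk.id: j for j, mk in enumerate(g.markers)}
    n = g.n_plants
    rows = {"chromosome": [], "cm": [], "position_bp": [], "marker_id": [],
            "is_marker": []}
    prob_blocks = []
    emit = np.full((4, 3), 1.0)        # row: call (AA/AB/BB/uninformative)
    for c_call in (AA, AB, BB):
        emit[c_call] = eps / 2.0
        emit[c_call, c_call] = 1.0 - eps
    for c in gmap.chromosomes:
        for mid in gmap.marker_ids[c]:
            if mid not in col:
                raise ValueError(f"map marker {mid!r} absent from genotypes")
        g_cm, g_bp, g_id, g_marker = _grid_for_chrom(
            gmap.cm[c], gmap.bp[c], gmap.marker_ids[c], cfg.step)
        P = len(g_cm)
        # emissions: (n, P, 3)
        E = np.ones((n, P, 3))
        for t in range(P):
            if g_marker[t]:
                calls = g.calls[:, col[g_id[t]]].astype(int)
                E[:, t, :] = emit[np.where(calls == MISSING, 3, calls)]
        r_steps = haldane_r(np.diff(np.asarray(g_cm)))
        trans = [f2_transition(float(r)) for r in np.atleast_1d(r_steps)]
        # forward, scaled
        alpha = np.empty((P, n, 3))
        a = F2_PRIOR[None, :] * E[:, 0, :]
        a /= a.sum(1, keepdims=True)
        alpha[0] = a
        for t in range(1, P):
            a = (a @ trans[t - 1]) * E[:, t, :]
            a /= a.sum(1, keepdims=True)
            alpha[t] = a
        # backward, scaled
        post = np.empty((n, P, 3))
        b = np.ones((n, 3))
        post[:, P - 1, :] = alpha[P - 1]
        for t in range(P - 2, -1, -1):
            b = (E[:, t + 1, :] * b) @ trans[t].T
            b /= b.sum(1, keepdims=True)
            p = alpha[t] * b
            post[:, t, :] = p / p.sum(1, keepdims=True)
        prob_blocks.append(post)
        rows["chromosome"] += [c] * P
        rows["cm"] += g_cm
        rows["position_bp"] += g_bp
        rows["marker_id"] += g_id
        rows["is_marker"] += g_marker
    probs = np.concatenate(prob_blocks, axis=1) if prob_blocks \
        else np.zeros((n, 0, 3))
    return GenoProbTable(list(g.plants), pd.DataFrame(rows), probs, eps)


@dataclass
class Interval:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_lod: float


@dataclass
class ScanResult:
    positions: pd.DataFrame
    lod: np.ndarray
    penetrance: np.ndarray          # (n_positions, 3)
    null_loglik: float
    n_iter: np.ndarray | None = None
    threshold: float | None = None
    intervals: list[Interval] = field(default_factory=list)

    def max_lod(self) -> float:
        return float(self.lod.max()) if len(self.lod) else 0.0


def _null_loglik(y: np.ndarray) -> float:
    mu = y.mean()
    if mu in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * math.log(mu) + n0 * math.log(1 - mu))


def _em_scan(w: np.ndarray, y: np.ndarray, cfg: ScanConfig):
    """Vectorised-over-positions EM for the Bernoulli mixture.

    Returns (loglik per position, penetrance (P, 3), iterations used).
    """
    n, P, _ = w.shape
    yf = y.astype(float)[:, None, None]
    wy = (w * yf).sum(0)
    pi = np.clip(wy / np.maximum(w.sum(0), 1e-300), 1e-3, 1 - 1e-3)
    loglik = np.full(P, -np.inf)
    active = np.ones(P, dtype=bool)
    iters = np.zeros(P, dtype=np.int64)
    for _ in range(cfg.em_max_iter):
        bern = yf * pi[None] + (1 - yf) * (1 - pi[None])   # (n, P, 3)
        z = w * bern
        denom = z.sum(2)                                    # (n, P)
        new_ll = np.log(np.maximum(denom, 1e-300)).sum(0)
        z = z / np.maximum(denom, 1e-300)[:, :, None]
        zsum = z.sum(0)
        pi = np.clip((z * yf).sum(0) / np.maximum(zsum, 1e-300),
                     1e-12, 1 - 1e-12)
        improved = new_ll - loglik
        loglik = new_ll
        iters[active] += 1
        active = improved > cfg.em_tolerance
        if not active.any():
            break
    # final log-likelihood at the last parameter values
    bern = yf * pi[None] + (1 - yf) * (1 - pi[None])
    loglik = np.log(np.maximum((w * bern).sum(2), 1e-300)).sum(0)
    return loglik, pi, iters


def scan_binary_em(gp: GenoProbTable, phenotypes: PhenotypeTable,
                   cfg: ScanConfig | None = None) -> ScanResult:
    """LOD profile of the single-locus binary model over the grid."""
    cfg = cfg or ScanConfig()
    y = phenotypes.as_binary(gp.plants)
    if gp.probs.shape[1] == 0:
        return ScanResult(gp.positions, np.zeros(0), np.zeros((0, 3)),
                          _null_loglik(y))
    l1, pi, iters = _em_scan(gp.probs, y, cfg)
    l0 = _null_loglik(y)
    lod = (l1 - l0) / math.log(10.0)
    if lod.min() < -1e-6:
        raise RuntimeError(f"EM log-likelihood fell below the null "
                           f"(min LOD {lod.min():.3g})")
    lod = np.maximum(lod, 0.0)
    return ScanResult(gp.positions.copy(), lod, pi, l0, iters)


@dataclass
class PermutationResult:
    threshold: float
    maxima: np.ndarray
    alpha: float


def permutation_threshold(gp: GenoProbTable, phenotypes: PhenotypeTable,
                          cfg: ScanConfig | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> PermutationResult:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype labels are shuffled across plants (genotype probabilities
    fixed), the scan re-run in full, and the maximum LOD recorded per
    replicate.  The threshold is the order statistic ceil((1 - alpha) * n)
    of the sorted maxima — no interpolation, for cross-platform
    reproducibility.
    """
    cfg = cfg or ScanConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.n_permutations < 1.0 / cfg.alpha:
        import warnings
        warnings.warn(f"{cfg.n_permutations} permutations is unstable for "
                      f"alpha={cfg.alpha}", stacklevel=2)
    y = phenotypes.as_binary(gp.plants)
    maxima = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        yb = rng.permutation(y)
        l1, _, _ = _em_scan(gp.probs, yb, cfg)
        lod = (l1 - _null_loglik(yb)) / math.log(10.0)
        maxima[b] = max(float(lod.max()), 0.0)
    k = math.ceil((1.0 - cfg.alpha) * cfg.n_permutations)
    threshold = float(np.sort(maxima)[k - 1])
    return PermutationResult(threshold, maxima, cfg.alpha)


def call_intervals(result: ScanResult, threshold: float) -> list[Interval]:
    """Intervals from first to last significant observed marker.

    Pseudomarkers never define endpoints; the peak is the leftmost marker
    with maximal LOD.  Chromosomes without a significant marker yield
    nothing.
    """
    pos = result.positions
    intervals = []
    for c in pos["chromosome"].unique():
        sel = (pos["chromosome"] == c).to_numpy() \
            & pos["is_marker"].to_numpy() \
            & (result.lod >= threshold)
        if not sel.any():
            continue
        bp = pos["position_bp"].to_numpy()[sel]
        lods = result.lod[sel]
        peak = int(np.argmax(lods))     # argmax is leftmost on ties
        intervals.append(Interval(str(c), int(bp.min()), int(bp.max()),
                                  int(bp[peak]), float(lods[peak])))
    return intervals


def genome_scan(d: Dataset, cfg: ScanConfig | None = None,
                gmap: GeneticMap | None = None,
                rng: np.random.Generator | None = None) -> ScanResult:
    """Convenience end-to-end scan: map -> genoprob -> EM scan ->
    permutation threshold -> intervals."""
    cfg = cfg or ScanConfig()
    gmap = gmap or build_genetic_map(d.genotypes.markers)
    gp = calc_genoprob(d, gmap, cfg)
    result = scan_binary_em(gp, d.phenotypes, cfg)
    perm = permutation_threshold(gp, d.phenotypes, cfg, rng)
    result.threshold = perm.threshold
    result.intervals = call_intervals(result, perm.threshold)
    return result
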