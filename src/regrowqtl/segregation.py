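"""Complementary-dominant-epistasis segregation models.

A trait controlled by ``k`` dominant, complementary loci is expressed only
when every locus carries at least one dominant allele; in an F2 intercross
the expected expressing fraction is (3/4)^k, giving the classical ratios
3:1 (k=1), 9:7 (k=2) and 27:37 (k=3).

All model fractions are computed in exact rational arithmetic and converted
to floats only at the boundary, so that expected counts fed to chi-square
statistics carry no 0.333... drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from scipy import stats

from .genotypes import NR, R


@dataclass(frozen=True)
class SegModel:
    """k dominant complementary loci and the implied F2 expressing fraction."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def expected_R_fraction(self) -> Fraction:
        return Fraction(3, 4) ** self.k

    @property
    def label(self) -> str:
        """Ratio string such as '9:7'; defined for k up to 10."""
        if self.k > 10:
            raise ValueError("ratio labels defined for k <= 10")
        num = 3 ** self.k
        return f"{num}:{4 ** self.k - num}"


@dataclass(frozen=True)
class GofResult:
    """Pearson goodness-of-fit of observed R/NR counts to a SegModel."""

    model: SegModel
    chi2: float
    df: int
    p: float
    observed: tuple[int, int]
    expected: tuple[float, float]


def expected_regrowth_fraction(k: int) -> Fraction:
    """Expected F2 expressing fraction (3/4)^k for k complementary loci."""
    return SegModel(k).expected_R_fraction


def backcross_expected_fraction(direction: str, k: int) -> Fraction:
    """Expected expressing fraction in a backcross of the F1.

    Backcrossing to the donor (Zd) parent fixes at least one dominant allele
    at every locus, so every plant expresses; backcrossing to the recurrent
    maize parent requires the F1 to transmit the dominant allele at each of
    the k loci independently, giving (1/2)^k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if direction == "to_Zd":
        return Fraction(1)
    if direction == "to_maize":
        return Fraction(1, 2) ** k
    raise ValueError(f"direction must be 'to_Zd' or 'to_maize', "
                     f"got {direction!r}")


def gof_test(n_R: int, n_NR: int, model: SegModel) -> GofResult:
    """Pearson chi-square goodness of fit over the two phenotype classes.

    df = 1, no continuity correction; p from the chi-square survival
    function.
    """
    n = n_R + n_NR
    if n < 1:
        raise ValueError("at least one observation required")
    f = model.expected_R_fraction
    e_R, e_NR = n * f, n * (1 - f)
    chi2 = float((n_R - e_R) ** 2 / e_R + (n_NR - e_NR) ** 2 / e_NR)
    p = float(stats.chi2.sf(chi2, df=1))
    return GofResult(model, chi2, 1, p, (n_R, n_NR),
                     (float(e_R), float(e_NR)))


def best_fit_model(n_R: int, n_NR: int,
                   candidates: Sequence[SegModel]) -> tuple[SegModel, list[GofResult]]:
    """Pick the candidate with the largest p-value; ties go to smaller k."""
    if not candidates:
        raise ValueError("need at least one candidate model")
    results = [gof_test(n_R, n_NR, m) for m in candidates]
    best = max(results, key=lambda r: (r.p, -r.model.k))
    return best.model, results


@dataclass(frozen=True)
class ConditionalGenotypeDist:
    """Genotype distribution at a fully linked marker given phenotype class."""

    phenotype_class: str
    probs: tuple[Fraction, Fraction, Fraction]  # (pAA, pAB, pBB)

    def as_floats(self) -> tuple[float, float, float]:
        return tuple(float(p) for p in self.probs)  # type: ignore[return-value]


def conditional_genotype_probs(phenotype_class: str,
                               model: SegModel) -> ConditionalGenotypeDist:
    """Genotype distribution at a marker perfectly linked to one causal locus.

    For the two-locus (9:7) model: a regrowable plant must carry a dominant
    allele at the linked locus, and within the 1 AA : 2 AB : 1 BB marker
    segregation that leaves AA:AB = 1:2 and no BB, i.e. (1/3, 2/3, 0).
    Non-regrowth arises either from BB at the linked locus (probability 1/4)
    or from a dominant linked genotype combined with the 1/4 recessive class
    at the unlinked complementary locus; normalising by the 7/16 non-express
    fraction gives (1/7, 2/7, 4/7).
    """
    if model.k != 2:
        raise ValueError("conditional genotype distributions are derived "
                         f"for the two-locus model only (got k={model.k})")
    one = Fraction(1)
    # joint of linked-locus genotype (1:2:1) with expression at the unlinked
    # locus (3/4 dominant)
    dom_other = Fraction(3, 4)
    marker = {
        "AA": Fraction(1, 4), "AB": Fraction(1, 2), "BB": Fraction(1, 4)}
    p_R = {g: marker[g] * (dom_other if g != "BB" else 0) for g in marker}
    p_NR = {g: marker[g] - p_R[g] for g in marker}
    if phenotype_class == R:
        tot = sum(p_R.values())
        probs = (p_R["AA"] / tot, p_R["AB"] / tot, p_R["BB"] / tot)
    elif phenotype_class == NR:
        tot = sum(p_NR.values())
        probs = (p_NR["AA"] / tot, p_NR["AB"] / tot, p_NR["BB"] / tot)
    else:
        raise ValueError(f"phenotype_class must be R or NR, "
                         f"got {phenotype_class!r}")
    assert sum(probs) == one
    return ConditionalGenotypeDist(phenotype_class, probs)


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.chi2.isf(alpha, df))
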