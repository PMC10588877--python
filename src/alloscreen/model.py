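"""Closed-form biallelic maternal-fetal incompatibility model.

The model: a single autosomal biallelic locus with minor-allele frequency
``q`` (major-allele frequency ``P = 1 - q``) in Hardy-Weinberg equilibrium.
A mother homozygous for the minor allele can be immunized against the
contrasting (major) allele product; a fetus is at risk whenever it inherits
the major allele from the father, and manifests disease with probability
``penetrance``.

Under this model the population-level recurrence rate for an immunized
mother with a random father equals ``penetrance * P``: each pregnancy draws
one paternal allele from the population, and the fetus is at risk iff that
allele is the major one.  A 95% recurrence rate therefore maps to a minor
allele at frequency 0.05, and a 30% minor allele predicts only ~70%
recurrence.  A second mating scheme conditions on the *same* father having
already fathered one affected child, which shifts his genotype distribution
toward homozygous-major and raises the next-pregnancy risk to
``penetrance * (P + q/2)``.

The module also carries the classic library-screening formula
``N = ln(1 - P_detect) / ln(1 - f)`` for the number of clones to screen to
hit a species of abundance ``f`` with probability ``P_detect``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy.optimize import brentq


@dataclass(frozen=True)
class BiallelicModelParams:
    """Parameters of the biallelic alloantigen model.

    Parameters
    ----------
    minor_af:
        Frequency ``q`` of the putative maternal (minor) allele, in (0, 1).
    penetrance:
        Probability that an at-risk fetus is affected, in [0, 1].
    """

    minor_af: float
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_af < 1.0:
            raise ValueError(f"minor_af must be in (0,1), got {self.minor_af}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0,1], got {self.penetrance}")


@dataclass(frozen=True)
class LibraryScreenParams:
    """Detection probability and target abundance for a clone library screen."""

    detect_prob: float
    target_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_prob < 1.0:
            raise ValueError(
                f"detect_prob must be in (0,1), got {self.detect_prob}"
            )
        if not 0.0 < self.target_frequency <= 1.0:
            raise ValueError(
                f"target_frequency must be in (0,1], got {self.target_frequency}"
            )


class Mating(str, Enum):
    """Sampling scheme for the father in the recurrence calculation."""

    RANDOM_FATHER = "random_father"
    SAME_FATHER_GIVEN_INDEX = "same_father_given_index"


def incompatibility_probability(p: float) -> float:
    """Probability of the incompatible mother-fetus constellation.

    For a maternal allele at frequency ``p``, the probability that a random
    mother is homozygous for it *and* a random fetus carries the contrasting
    allele is ``p^2 * (1 - p)``.  Zero at both endpoints, with a global
    maximum of 4/27 at ``p = 2/3``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {p}")
    return p * p * (1.0 - p)


def expected_recurrence_rate(
    params: BiallelicModelParams,
    mating: Mating | str = Mating.RANDOM_FATHER,
) -> float:
    """Recurrence risk for the next pregnancy of an immunized mother.

    ``random_father``: the paternal allele is a fresh draw from the
    population, so the risk is ``penetrance * (1 - q)`` -- the population
    level mapping between recurrence rate and minor-allele frequency.

    ``same_father_given_index``: the father is the same man, with his
    genotype distribution updated by the fact that he has already fathered
    one affected child.  Enumerating his genotypes at Hardy-Weinberg
    proportions (hom-major ``P^2``, het ``2Pq``, hom-minor ``q^2``) with
    per-pregnancy risk (1, 1/2, 0) gives a next-pregnancy risk of
    ``penetrance * (P + q/2)``, always >= the random-father value.
    """
    mating = Mating(mating)
    q = params.minor_af
    big_p = 1.0 - q
    if mating is Mating.RANDOM_FATHER:
        return params.penetrance * big_p
    # posterior over father genotype given one affected child is
    # proportional to (P^2 * 1, 2Pq * 1/2); averaging the per-genotype risk
    # over it yields (P^2 + P q / 2) / P = P + q/2
    return params.penetrance * (big_p + q / 2.0)


def invert_recurrence(
    recurrence: float,
    penetrance: float = 1.0,
    mating: Mating | str = Mating.RANDOM_FATHER,
) -> float:
    """Minor-allele frequency implied by an observed recurrence rate.

    Solves ``expected_recurrence_rate(q) = recurrence`` for ``q`` by root
    bracketing on (0, 1).
    """
    if penetrance <= 0.0:
        raise ValueError("cannot invert recurrence with zero penetrance")
    if not 0.0 < recurrence < penetrance:
        raise ValueError(
            f"recurrence {recurrence} not attainable with penetrance {penetrance}"
        )

    def f(q: float) -> float:
        return (
            expected_recurrence_rate(
                BiallelicModelParams(minor_af=q, penetrance=penetrance), mating
            )
            - recurrence
        )

    eps = 1e-12
    return float(brentq(f, eps, 1.0 - eps, xtol=1e-12))


def clones_to_screen(params: LibraryScreenParams) -> int:
    """Number of library clones to screen for a given detection probability.

    ``N = ceil( ln(1 - P) / ln(1 - f) )`` where ``P`` is the target
    detection probability and ``f`` the abundance of the desired clone.
    With ``f = 1`` any single clone is the target, so N = 1.
    """
    big_p, f = params.detect_prob, params.target_frequency
    if f == 1.0:
        return 1
    return math.ceil(math.log1p(-big_p) / math.log1p(-f))
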