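"""Monte-Carlo power of the couple incompatibility screen.

Power here means: the probability that the planted causal variant survives
``alloantigen_couple_filter`` in a simulated affected-family cohort.  The
planted variant is retained only if *every* father is homozygous-major, so
power falls as the minor-allele frequency rises -- the quantitative version
of the argument that only a mother homozygous for a *rare* allele is
compatible with a rare disease that recurs in nearly every pregnancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BiallelicModelParams
from .screen import ScreenConfig, alloantigen_couple_filter
from .simulate import PlantedVariantSpec, SimulationSpec, simulate_cohort


@dataclass(frozen=True)
class PowerEstimate:
    """Fraction of simulated cohorts in which the planted variant survives."""

    power: float
    n_replicates: int
    mc_se: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must be in [0,1]")
        if self.mc_se < 0:
            raise ValueError("mc_se must be >= 0")


def screen_power(
    model: BiallelicModelParams,
    n_families: int,
    screen: ScreenConfig | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
    force_father_hom_major: bool = False,
    n_background_variants: int = 0,
) -> PowerEstimate:
    """Estimate planted-variant retention probability by simulation.

    Each replicate simulates a cohort of ``n_families`` couples, each with
    one genotyped affected child, ascertained through an affected index
    pregnancy; the planted causal locus sits at ``model.minor_af``.  The
    replicate scores a success when the couple filter retains the planted
    variant.  Deterministic given ``seed``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    screen = screen or ScreenConfig()
    planted = PlantedVariantSpec(
        minor_af=model.minor_af,
        force_father_hom_major=force_father_hom_major,
        penetrance=model.penetrance,
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) >> 1
    hits = 0
    for r in range(n_replicates):
        spec = SimulationSpec(
            n_families=n_families,
            n_missing_fathers=0,
            n_background_variants=n_background_variants,
            planted=planted,
            child_per_family=1,
            missing_rate=0.0,
            seed=int(child_seeds[r]),
        )
        cohort = simulate_cohort(spec)
        planted_key = cohort.variants[-1].key
        result = alloantigen_couple_filter(cohort, screen)
        if planted_key in result.candidate_keys():
            hits += 1
    power = hits / n_replicates
    mc_se = float(np.sqrt(power * (1.0 - power) / n_replicates))
    return PowerEstimate(power=power, n_replicates=n_replicates, mc_se=mc_se)


def analytic_couple_power(
    minor_af: float, n_families: int, n_conditioning_events: int = 2
) -> float:
    """Closed-form retention probability matching ``screen_power``'s design.

    With fathers at Hardy-Weinberg proportions conditioned on
    ``n_conditioning_events`` affected pregnancies each (index case plus
    one genotyped affected child by default), the planted variant survives
    iff every father is homozygous-major.  Enumerating father genotypes
    gives the per-family probability
    ``P^2 / (P^2 + 2 P q (1/2)^k)`` with ``P = 1 - q``, raised to the
    number of families.
    """
    q = minor_af
    big_p = 1.0 - q
    w_aa = big_p * big_p
    w_het = 2.0 * big_p * q * 0.5**n_conditioning_events
    per_family = w_aa / (w_aa + w_het)
    return per_family**n_families
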