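"""In-memory containers for family cohorts of biallelic variants.

A :class:`Cohort` holds the three things every screen needs: the sample
roster, the variant table with per-sample genotypes, and the pedigree
structure (mother / father / children per family, with affected status).

Genotypes are stored as alternate-allele dosages (0, 1, 2) with ``-1`` for
a missing call.  Screens never reason in REF/ALT terms directly: each
variant re-orients itself into minor/major-allele space from its population
allele-frequency annotation (see :meth:`VariantRecord.minor_dosages`), so a
REF/ALT swap with a correspondingly re-expressed AF leaves every screen
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Consequence vocabulary understood by the screens.
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "missense",
    "frameshift",
    "splice_loss",
    "inframe_indel",
    "synonymous",
    "other",
)

#: Classes treated as loss-of-function by the cohort homozygous screen.
LOF_CLASSES: frozenset[str] = frozenset({"frameshift", "splice_loss"})


@dataclass(frozen=True)
class Genotype:
    """A single diploid call: alternate-allele dosage, or missing.

    ``dosage`` is the number of alternate alleles carried (0, 1 or 2);
    ``None`` encodes a missing call (``./.`` in VCF).
    """

    dosage: int | None

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1, 2 or None, got {self.dosage!r}")

    @property
    def is_missing(self) -> bool:
        return self.dosage is None


@dataclass
class Family:
    """One affected family: the unit of the incompatibility filter.

    The mother is always present (she is the ascertained individual); the
    father and children may be absent from the cohort.
    """

    family_id: str
    mother_id: str
    father_id: str | None = None
    child_ids: list[str] = field(default_factory=list)
    child_affected: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mother_id:
            raise ValueError(f"family {self.family_id}: mother_id is required")
        if len(self.child_affected) != len(self.child_ids):
            raise ValueError(
                f"family {self.family_id}: child_affected must match child_ids"
            )

    @property
    def has_father(self) -> bool:
        return self.father_id is not None


@dataclass
class VariantRecord:
    """One biallelic site with genotypes for every cohort sample.

    ``alt_af`` is the population frequency of the ALT allele (``None`` when
    unannotated).  The *minor* allele is whichever of REF/ALT has the lower
    population frequency; a tie at exactly 0.5 breaks to ALT-as-minor.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray
    consequence_class: str = "other"
    gene: str | None = None
    aa_change: str | None = None
    alt_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence class {self.consequence_class!r}"
            )
        if self.alt_af is not None and not 0.0 <= self.alt_af <= 1.0:
            raise ValueError(f"alt_af must be in [0,1], got {self.alt_af}")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"{self.chrom}:{self.pos}: invalid dosage values")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def minor_is_alt(self) -> bool:
        """Whether ALT is the minor allele (ties at 0.5 and unknown AF -> ALT)."""
        return self.alt_af is None or self.alt_af <= 0.5

    @property
    def pop_minor_af(self) -> float | None:
        """Population minor-allele frequency in [0, 0.5], or None."""
        if self.alt_af is None:
            return None
        return min(self.alt_af, 1.0 - self.alt_af)

    def minor_dosages(self) -> np.ndarray:
        """Per-sample dosage of the *minor* allele (missing stays -1)."""
        d = self.dosages.copy()
        if not self.minor_is_alt:
            called = d != MISSING
            d[called] = 2 - d[called]
        return d

    def swap_ref_alt(self) -> None:
        """Re-encode the site with REF and ALT exchanged (in place).

        The AF annotation is re-expressed so the site describes the same
        population fact; screens must be invariant under this.
        """
        self.ref, self.alt = self.alt, self.ref
        if self.alt_af is not None:
            self.alt_af = 1.0 - self.alt_af
        called = self.dosages != MISSING
        self.dosages[called] = 2 - self.dosages[called]


@dataclass
class Cohort:
    """Samples, variants and pedigree structure for one study cohort."""

    samples: list[str]
    variants: list[VariantRecord]
    families: list[Family]
    sex: dict[str, int] = field(default_factory=dict)  # 1=male, 2=female, 0=unknown
    affected: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels in cohort")
        self.sample_index: dict[str, int] = {s: i for i, s in enumerate(self.samples)}
        for v in self.variants:
            if len(v.dosages) != len(self.samples):
                raise ValueError(
                    f"{v.chrom}:{v.pos}: {len(v.dosages)} dosages for "
                    f"{len(self.samples)} samples"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def mother_ids(self) -> list[str]:
        return [f.mother_id for f in self.families]

    def father_ids(self) -> list[str]:
        return [f.father_id for f in self.families if f.father_id is not None]

    def child_ids(self) -> list[str]:
        return [c for f in self.families for c in f.child_ids]

    def genotype_matrix(self) -> np.ndarray:
        """Variants x samples matrix of ALT dosages (-1 missing)."""
        if not self.variants:
            return np.empty((0, len(self.samples)), dtype=np.int8)
        return np.stack([v.dosages for v in self.variants])
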