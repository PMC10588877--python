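"""Synthetic affected-family cohorts under the biallelic alloantigen model.

The generator emulates the study design of an affected-family sequencing
cohort: each family is ascertained through a mother who has had at least
one affected pregnancy (the index case, which is not itself genotyped).
Mothers and fathers are drawn at Hardy-Weinberg proportions for background
variants; children receive one allele from each parent uniformly at random.

An optional *planted* causal locus realises the alloantigen hypothesis:
every mother is homozygous for the minor allele there.  Fathers at the
planted locus are either forced homozygous-major, or drawn from the
Hardy-Weinberg distribution *conditioned on the family's ascertainment* --
a father who has produced affected children is enriched for the
homozygous-major genotype, since only a paternally transmitted major allele
puts the fetus at risk.  Each affected pregnancy used for conditioning
multiplies a genotype's prior weight by its transmission probability of the
major allele (1 for hom-major, 1/2 for het, 0 for hom-minor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    CONSEQUENCE_CLASSES,
    MISSING,
    Cohort,
    Family,
    Genotype,
    VariantRecord,
)
from .model import BiallelicModelParams

_BASES = np.array(list("ACGT"))
_AMINO = list("ARNDCQEGHILKMFPSTWYV")

# rough coding-variant spectrum used for background consequence labels
_CSQ_WEIGHTS = {
    "missense": 0.40,
    "synonymous": 0.30,
    "other": 0.12,
    "inframe_indel": 0.06,
    "frameshift": 0.06,
    "splice_loss": 0.06,
}

_VARIANTS_PER_GENE = 4


@dataclass(frozen=True)
class PlantedVariantSpec:
    """Description of the planted causal alloantigen locus.

    ``ascertain_index_case`` conditions each father's genotype on one
    affected (non-genotyped) index pregnancy; ``children_affected``
    additionally makes every genotyped child an affected subsequent
    pregnancy, which conditions the father once more per child and forces
    the child to carry the paternal major allele (hence heterozygous, since
    the mother contributes the minor allele).
    """

    minor_af: float = 0.05
    consequence_class: str = "missense"
    gene: str = "ALLO1"
    force_father_hom_major: bool = False
    ascertain_index_case: bool = True
    children_affected: bool = True
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_af <= 0.5:
            raise ValueError(
                "planted minor_af must be in (0, 0.5]: the mothers are forced "
                f"homozygous for the *minor* allele (got {self.minor_af})"
            )
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0,1], got {self.penetrance}")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated cohort.

    Defaults emulate a genome-sequencing cohort of 26 affected-family
    mothers of whom 22 have the father available, with no genotyped
    children unless overridden per family.
    """

    n_families: int = 26
    n_missing_fathers: int = 4
    n_background_variants: int = 5000
    background_af_range: tuple[float, float] = (0.01, 0.99)
    planted: PlantedVariantSpec | None = None
    child_per_family: int = 0
    child_overrides: dict[int, int] = field(default_factory=dict)
    missing_rate: float = 0.02
    shuffle_ref_alt: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.background_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"background_af_range must lie in (0,1), got {lo},{hi}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 <= self.n_missing_fathers <= self.n_families:
            raise ValueError("n_missing_fathers must be in [0, n_families]")
        if self.child_per_family < 0:
            raise ValueError("child_per_family must be >= 0")


def _pedigree_skeleton(spec: SimulationSpec, rng: np.random.Generator):
    families: list[Family] = []
    samples: list[str] = []
    sex: dict[str, int] = {}
    for i in range(spec.n_families):
        fid = f"FAM{i + 1:03d}"
        mother = f"{fid}_M"
        samples.append(mother)
        sex[mother] = 2
        father: str | None = None
        if i >= spec.n_missing_fathers:  # first few families are mother-only
            father = f"{fid}_F"
            samples.append(father)
            sex[father] = 1
        n_children = spec.child_overrides.get(i, spec.child_per_family)
        children = []
        for j in range(n_children):
            cid = f"{fid}_C{j + 1}"
            samples.append(cid)
            sex[cid] = int(rng.integers(1, 3))
            children.append(cid)
        families.append(
            Family(
                family_id=fid,
                mother_id=mother,
                father_id=father,
                child_ids=children,
                child_affected=[True] * n_children,  # provisional, see planted locus
            )
        )
    return families, samples, sex


def _background_variants(spec: SimulationSpec, n_samples: int, rng: np.random.Generator):
    n = spec.n_background_variants
    lo, hi = spec.background_af_range
    afs = rng.uniform(lo, hi, size=n)
    classes = rng.choice(
        list(_CSQ_WEIGHTS), size=n, p=np.array(list(_CSQ_WEIGHTS.values()))
    )
    refs = rng.choice(_BASES, size=n)
    meta = []
    for i in range(n):
        ref = str(refs[i])
        csq = str(classes[i])
        if csq == "frameshift":
            alt = ref + str(rng.choice(_BASES))
        elif csq == "inframe_indel":
            alt = ref + "".join(rng.choice(_BASES, size=3))
        else:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        aa = None
        if csq in ("missense", "inframe_indel"):
            a1, a2 = rng.choice(_AMINO, size=2)
            aa = f"p.{a1}{int(rng.integers(1, 800))}{a2}"
        meta.append(
            dict(
                chrom="1",
                pos=1000 * (i + 1),
                ref=ref,
                alt=alt,
                consequence_class=csq,
                gene=f"G{i // _VARIANTS_PER_GENE + 1:05d}",
                aa_change=aa,
                alt_af=round(float(afs[i]), 6),
            )
        )
    return meta


def _conditioned_father_dosage(
    q: float, n_events: int, rng: np.random.Generator
) -> int:
    """Draw a father's minor-allele dosage at the planted locus.

    Hardy-Weinberg prior reweighted by the probability of transmitting the
    major allele in each of ``n_events`` affected pregnancies.
    """
    big_p = 1.0 - q
    w = np.array(
        [
            big_p * big_p,  # dosage 0: hom-major, transmits major surely
            2.0 * big_p * q * 0.5**n_events,
            q * q * (1.0 if n_events == 0 else 0.0),
        ]
    )
    return int(rng.choice(3, p=w / w.sum()))


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Simulate genotypes, pedigree and affected status for one cohort.

    Background variants are independent; parents are Hardy-Weinberg draws
    at each variant's allele frequency and children inherit one uniformly
    chosen allele per parent.  The planted locus (if any) follows the
    alloantigen pattern described in the module docstring.  In simulated
    VCFs the minor allele of the planted locus is encoded as ALT; the
    ``shuffle_ref_alt`` flag re-encodes a random half of all variants with
    REF and ALT swapped (AF re-expressed) so that consumers can be checked
    for orientation invariance.
    """
    rng = np.random.default_rng(spec.seed)
    families, samples, sex = _pedigree_skeleton(spec, rng)
    idx = {s: i for i, s in enumerate(samples)}
    n_s = len(samples)

    meta = _background_variants(spec, n_s, rng)
    n_bg = len(meta)

    # parental genotypes: two independent allele draws per sample
    dos = np.zeros((n_bg, n_s), dtype=np.int8)
    afs = np.array([m["alt_af"] for m in meta]) if n_bg else np.empty(0)
    parent_cols = [idx[s] for f in families for s in (f.mother_id, f.father_id) if s]
    for c in parent_cols:
        dos[:, c] = rng.binomial(2, afs)
    # children: one allele from each parent, uniform over the parent's two
    for fam in families:
        for cid in fam.child_ids:
            mcol = idx[fam.mother_id]
            mat = rng.random(n_bg) < dos[:, mcol] / 2.0
            if fam.father_id is not None:
                pat = rng.random(n_bg) < dos[:, idx[fam.father_id]] / 2.0
            else:  # untyped father: population draw
                pat = rng.random(n_bg) < afs
            dos[:, idx[cid]] = mat.astype(np.int8) + pat.astype(np.int8)

    variants = [VariantRecord(dosages=dos[i], **meta[i]) for i in range(n_bg)]

    if spec.planted is not None:
        variants.append(_plant_variant(spec, families, idx, n_s, n_bg, rng))

    # missing calls, never at the planted locus's mothers
    if spec.missing_rate > 0:
        mother_cols = {idx[f.mother_id] for f in families}
        for vi, v in enumerate(variants):
            mask = rng.random(n_s) < spec.missing_rate
            if spec.planted is not None and vi == len(variants) - 1:
                mask[list(mother_cols)] = False
            v.dosages[mask] = MISSING

    if spec.shuffle_ref_alt:
        for v in variants:
            if rng.random() < 0.5:
                v.swap_ref_alt()

    affected = {s: False for s in samples}
    for fam in families:
        for cid, aff in zip(fam.child_ids, fam.child_affected):
            affected[cid] = bool(aff)
    return Cohort(
        samples=samples, variants=variants, families=families, sex=sex,
        affected=affected,
    )


def _plant_variant(spec, families, idx, n_s, n_bg, rng) -> VariantRecord:
    p = spec.planted
    q = p.minor_af
    dos = np.zeros(n_s, dtype=np.int8)
    for fam in families:
        dos[idx[fam.mother_id]] = 2  # mother homozygous minor, by hypothesis
        n_children = len(fam.child_ids)
        n_events = (1 if p.ascertain_index_case else 0) + (
            n_children if p.children_affected else 0
        )
        if fam.father_id is not None:
            fd = 0 if p.force_father_hom_major else _conditioned_father_dosage(
                q, n_events, rng
            )
            dos[idx[fam.father_id]] = fd
        else:
            fd = None
        new_aff = []
        for cid in fam.child_ids:
            if p.children_affected:
                pat_minor, aff = 0, True  # affected => paternal major transmitted
            else:
                pat_af = q if fd is None else fd / 2.0
                pat_minor = int(rng.random() < pat_af)
                aff = pat_minor == 0 and rng.random() < p.penetrance
            dos[idx[cid]] = 1 + pat_minor  # maternal allele is always minor
            new_aff.append(aff)
        fam.child_affected = new_aff
    return VariantRecord(
        chrom="1",
        pos=1000 * (n_bg + 1) + 500,
        ref="G",
        alt="T",
        dosages=dos,
        consequence_class=p.consequence_class,
        gene=p.gene,
        aa_change="p.A100V" if p.consequence_class == "missense" else None,
        alt_af=round(q, 6),
    )


def simulate_pregnancies(
    model: BiallelicModelParams,
    father_genotype: Genotype | None,
    n: int,
    seed: int,
) -> int:
    """Count affected pregnancies of an immunized (hom-minor) mother.

    Each pregnancy draws one paternal allele; the fetus is at risk iff that
    allele is the major one, and affected with probability ``penetrance``.
    ``father_genotype.dosage`` is the father's *minor*-allele count.  With
    ``father_genotype=None`` each pregnancy draws a fresh father from
    Hardy-Weinberg proportions at ``model.minor_af`` -- the population-level
    recurrence experiment, whose expectation is
    ``expected_recurrence_rate(model, "random_father")``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if father_genotype is None:
        # fresh HWE father per pregnancy: transmitted allele is a population draw
        paternal_minor = rng.random(n) < model.minor_af
    elif father_genotype.is_missing:
        raise ValueError("father genotype is missing")
    else:
        paternal_minor = rng.random(n) < father_genotype.dosage / 2.0
    at_risk = ~paternal_minor
    affected = at_risk & (rng.random(n) < model.penetrance)
    return int(affected.sum())


def swap_ref_alt(cohort: Cohort, variant_indices) -> Cohort:
    """Return a copy of ``cohort`` with REF/ALT swapped at the given variants."""
    new_variants = []
    swap = set(int(i) for i in variant_indices)
    for i, v in enumerate(cohort.variants):
        nv = replace(v, dosages=v.dosages.copy())
        if i in swap:
            nv.swap_ref_alt()
        new_variants.append(nv)
    return Cohort(
        samples=list(cohort.samples),
        variants=new_variants,
        families=cohort.families,
        sex=dict(cohort.sex),
        affected=dict(cohort.affected),
    )
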