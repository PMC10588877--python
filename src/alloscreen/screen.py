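"""Family-based candidate-alloantigen screens over a cohort VCF.

All screens reason in minor/major-allele space: each variant is oriented
by its population allele-frequency annotation, never by REF/ALT order.
The screens are deterministic predicates, not hypothesis tests; no
multiple-testing correction applies anywhere.

Filters
-------
``alloantigen_couple_filter``
    The incompatibility pattern across affected families: mother
    homozygous-minor, father homozygous-major, genotyped children
    heterozygous.
``cohort_homozygous_screen``
    Rare (MAF below a cut-off) protein-altering variants at which at least
    one case mother is homozygous for the minor allele.
``gene_recurrence``
    Genes where the same coordinate or the same amino-acid change is
    carried homozygous by several distinct women.
``trio_denovo_recessive``
    Per-family child-centred screens: de novo, rare homozygous recessive,
    and compound heterozygous.
``sex_stratified_genotype_counts`` / ``candidate_exclusion``
    The genotype-tally argument that rules a candidate out whenever any
    father is homozygous for the putative maternal minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd
from scipy.stats import fisher_exact

from .cohort import LOF_CLASSES, MISSING, Cohort, Family, VariantRecord

_DEFAULT_CONSEQUENCES = frozenset(
    {"missense", "frameshift", "splice_loss", "inframe_indel"}
)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate screens.

    ``maf_max_hom_screen`` bounds the population minor-AF in the cohort
    homozygous screen (default 10%); ``maf_max_recessive`` bounds it in the
    recessive/compound-het trio screens (default 2%).  ``lof_only_mode``
    restricts the homozygous screen to loss-of-function classes.
    """

    maf_max_hom_screen: float = 0.10
    maf_max_recessive: float = 0.02
    allowed_consequences: frozenset[str] = _DEFAULT_CONSEQUENCES
    min_women_recurrence: int = 3
    require_child_het: bool = True
    lof_only_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_max_hom_screen", "maf_max_recessive"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.min_women_recurrence < 2:
            raise ValueError("min_women_recurrence must be >= 2")
        object.__setattr__(
            self, "allowed_consequences", frozenset(self.allowed_consequences)
        )


@dataclass
class Candidate:
    """One surviving variant with its supporting evidence."""

    variant: VariantRecord
    families: list[str]
    filter_name: str
    details: dict = field(default_factory=dict)


@dataclass
class ScreenResult:
    """Candidates plus the per-stage survivor counts of the filter cascade."""

    candidates: list[Candidate]
    stage_counts: dict[str, int]
    filter_name: str

    def candidate_keys(self) -> set[tuple]:
        return {c.variant.key for c in self.candidates}

    def to_frame(self) -> pd.DataFrame:
        """One row per candidate x supporting family/sample."""
        rows = []
        for c in self.candidates:
            for fam in c.families or ["."]:
                rows.append(
                    dict(
                        chrom=c.variant.chrom,
                        pos=c.variant.pos,
                        ref=c.variant.ref,
                        alt=c.variant.alt,
                        gene=c.variant.gene,
                        aa_change=c.variant.aa_change,
                        consequence=c.variant.consequence_class,
                        pop_minor_af=c.variant.pop_minor_af,
                        filter=c.filter_name,
                        support=fam,
                        pattern=c.details.get("pattern", {}).get(fam, ""),
                    )
                )
        cols = [
            "chrom", "pos", "ref", "alt", "gene", "aa_change", "consequence",
            "pop_minor_af", "filter", "support", "pattern",
        ]
        return pd.DataFrame(rows, columns=cols)


def alloantigen_couple_filter(cohort: Cohort, config: ScreenConfig) -> ScreenResult:
    """Screen for the maternal-fetal incompatibility pattern across couples.

    A variant is a candidate iff in *every* family where both parents have
    non-missing calls the mother is homozygous for the minor allele and the
    father homozygous for the contrasting (major) allele, and -- when
    ``require_child_het`` -- every genotyped, non-missing child is
    heterozygous.  Families with a missing parental call at the variant
    neither support nor veto; at least one supporting family is required.
    The supporting-family count is reported so callers can demand support
    from all families.
    """
    duos = [
        f for f in cohort.families
        if f.father_id is not None and f.mother_id in cohort.sample_index
        and f.father_id in cohort.sample_index
    ]
    if not duos:
        raise ValueError("no family with both parents genotyped in the cohort")
    idx = cohort.sample_index
    n_csq = 0
    candidates: list[Candidate] = []
    for v in cohort.variants:
        if v.consequence_class not in config.allowed_consequences:
            continue
        n_csq += 1
        md = v.minor_dosages()
        support: list[str] = []
        pattern: dict[str, str] = {}
        vetoed = False
        n_noninformative = 0
        for fam in duos:
            m, fa = md[idx[fam.mother_id]], md[idx[fam.father_id]]
            if m == MISSING or fa == MISSING:
                n_noninformative += 1
                continue
            ok = m == 2 and fa == 0
            kid_doses = [
                md[idx[c]] for c in fam.child_ids if c in idx
            ]
            kid_doses = [k for k in kid_doses if k != MISSING]
            if ok and config.require_child_het:
                ok = all(k == 1 for k in kid_doses)
            if ok:
                support.append(fam.family_id)
                pattern[fam.family_id] = _pattern_str(m, fa, kid_doses)
            else:
                vetoed = True
                break
        if not vetoed and support:
            candidates.append(
                Candidate(
                    variant=v,
                    families=support,
                    filter_name="couple_incompatibility",
                    details=dict(
                        pattern=pattern,
                        n_supporting=len(support),
                        n_noninformative=n_noninformative,
                        all_families_support=(
                            len(support) == len(duos)
                        ),
                    ),
                )
            )
    counts = {
        "input": cohort.n_variants,
        "consequence_class": n_csq,
        "couple_pattern": len(candidates),
    }
    return ScreenResult(candidates, counts, "couple_incompatibility")


def _pattern_str(m: int, fa: int, kids: list[int]) -> str:
    s = f"mother=hom_minor,father=hom_major"
    if kids:
        s += ",children=" + "/".join("het" if k == 1 else str(k) for k in kids)
    return s


def cohort_homozygous_screen(cohort: Cohort, config: ScreenConfig) -> ScreenResult:
    """Rare homozygous protein-altering variants in the case mothers.

    Keeps variants with population minor-AF strictly below
    ``maf_max_hom_screen`` whose consequence is missense or
    loss-of-function (frameshift / splice loss; LoF only when
    ``lof_only_mode``), at which at least one case mother is homozygous for
    the minor allele.  Variants without an AF annotation are dropped at the
    AF stage.
    """
    mothers = cohort.mother_ids()
    if not mothers:
        raise ValueError("cohort has no mothers")
    classes = LOF_CLASSES if config.lof_only_mode else ({"missense"} | LOF_CLASSES)
    idx = cohort.sample_index
    n_af = n_csq = 0
    candidates: list[Candidate] = []
    for v in cohort.variants:
        if v.pop_minor_af is None or v.pop_minor_af >= config.maf_max_hom_screen:
            continue
        n_af += 1
        if v.consequence_class not in classes:
            continue
        n_csq += 1
        md = v.minor_dosages()
        hom_women = [m for m in mothers if m in idx and md[idx[m]] == 2]
        if hom_women:
            candidates.append(
                Candidate(
                    variant=v,
                    families=hom_women,
                    filter_name="cohort_homozygous",
                    details=dict(hom_women=hom_women),
                )
            )
    counts = {
        "input": cohort.n_variants,
        "maf_below_cutoff": n_af,
        "consequence_class": n_csq,
        "hom_minor_mother": len(candidates),
    }
    return ScreenResult(candidates, counts, "cohort_homozygous")


def gene_recurrence(result: ScreenResult, config: ScreenConfig) -> pd.DataFrame:
    """Aggregate screen candidates to genes recurrent across women.

    A gene is flagged when the identical coordinate *or* the identical
    amino-acid change is carried (homozygous-minor) by at least
    ``min_women_recurrence`` distinct women.  Returns one row per gene with
    the maximum per-site and per-amino-acid woman counts.
    """
    coord_women: dict[tuple, set[str]] = {}
    aa_women: dict[tuple, set[str]] = {}
    gene_candidates: dict[str, int] = {}
    for c in result.candidates:
        gene = c.variant.gene
        if gene is None:
            continue
        women = set(c.details.get("hom_women", c.families))
        gene_candidates[gene] = gene_candidates.get(gene, 0) + 1
        ck = (gene, c.variant.chrom, c.variant.pos)
        coord_women.setdefault(ck, set()).update(women)
        if c.variant.aa_change is not None:
            ak = (gene, c.variant.aa_change)
            aa_women.setdefault(ak, set()).update(women)
    rows = []
    for gene in sorted(gene_candidates):
        max_coord = max(
            (len(w) for k, w in coord_women.items() if k[0] == gene), default=0
        )
        max_aa = max(
            (len(w) for k, w in aa_women.items() if k[0] == gene), default=0
        )
        rows.append(
            dict(
                gene=gene,
                n_candidates=gene_candidates[gene],
                max_women_same_coordinate=max_coord,
                max_women_same_aa=max_aa,
                flagged=max(max_coord, max_aa) >= config.min_women_recurrence,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "n_candidates", "max_women_same_coordinate",
            "max_women_same_aa", "flagged",
        ],
    ).astype(
        {
            "n_candidates": int,
            "max_women_same_coordinate": int,
            "max_women_same_aa": int,
            "flagged": bool,
        }
    )


def _alleles_of(dosage: int) -> set[int]:
    """Allele indices (0=REF-side, 1=ALT-side of the oriented dosage) present."""
    return {0: {0}, 1: {0, 1}, 2: {1}}[dosage]


def trio_denovo_recessive(
    cohort: Cohort,
    family: Family,
    config: ScreenConfig,
    child_id: str | None = None,
) -> ScreenResult:
    """Child-centred de novo, recessive and compound-het screens.

    ``de_novo``: the child carries an allele absent from the mother's call
    (and from the father's, when he is genotyped and called).
    ``recessive_hom``: child homozygous-minor with population minor-AF
    strictly below ``maf_max_recessive``.
    ``compound_het``: at least two distinct rare heterozygous variants in
    the same gene; when both parents are genotyped, at least one variant
    must be attributable to each parent (unphased approximation -- a
    variant carried by both parents may count for either side); with an
    ungenotyped parent the rule degrades to ">= 2 rare hets in one gene"
    and candidates carry ``phase_known=False``.

    All three screens are restricted to ``allowed_consequences``.
    """
    genotyped_children = [c for c in family.child_ids if c in cohort.sample_index]
    if not genotyped_children:
        raise ValueError(f"family {family.family_id} has no genotyped child")
    child = child_id if child_id is not None else genotyped_children[0]
    if child not in cohort.sample_index:
        raise ValueError(f"child {child!r} is not genotyped")
    idx = cohort.sample_index
    ci = idx[child]
    mi = idx.get(family.mother_id)
    fi = idx.get(family.father_id) if family.father_id is not None else None

    candidates: list[Candidate] = []
    rare_hets: dict[str, list[tuple[VariantRecord, str]]] = {}
    n_denovo = n_rec = 0
    for v in cohort.variants:
        if v.consequence_class not in config.allowed_consequences:
            continue
        d = v.dosages
        cd = int(d[ci])
        if cd == MISSING:
            continue
        child_alleles = _alleles_of(cd)
        m_d = int(d[mi]) if mi is not None else MISSING
        f_d = int(d[fi]) if fi is not None else MISSING

        # de novo: an allele of the child absent from the called parents,
        # mother's call required (she defines "absent from mother")
        if m_d != MISSING:
            novel = child_alleles - _alleles_of(m_d)
            if f_d != MISSING:
                novel -= _alleles_of(f_d)
            if novel:
                n_denovo += 1
                candidates.append(
                    Candidate(v, [family.family_id], "de_novo",
                              dict(child=child, novel_alleles=sorted(novel))),
                )

        maf = v.pop_minor_af
        if maf is None or maf >= config.maf_max_recessive:
            continue
        md_child = cd if v.minor_is_alt else 2 - cd
        if md_child == 2:
            n_rec += 1
            candidates.append(
                Candidate(v, [family.family_id], "recessive_hom",
                          dict(child=child)),
            )
        elif md_child == 1 and v.gene is not None:
            origin = _parental_origin(v, m_d, f_d)
            rare_hets.setdefault(v.gene, []).append((v, origin))

    n_ch_genes = 0
    both_parents = mi is not None and fi is not None
    for gene, entries in sorted(rare_hets.items()):
        if len(entries) < 2:
            continue
        qualified, phase_known = _compound_het_call(entries, both_parents)
        if not qualified:
            continue
        n_ch_genes += 1
        for v, origin in entries:
            candidates.append(
                Candidate(
                    v, [family.family_id], "compound_het",
                    dict(child=child, gene=gene, origin=origin,
                         phase_known=phase_known,
                         partners=[p.key for p, _ in entries if p is not v]),
                )
            )
    counts = {
        "input": cohort.n_variants,
        "de_novo": n_denovo,
        "recessive_hom": n_rec,
        "compound_het_genes": n_ch_genes,
    }
    return ScreenResult(candidates, counts, "trio")


def _parental_origin(v: VariantRecord, m_d: int, f_d: int) -> str:
    """Whose chromosome a child's het minor allele can have come from."""
    if m_d == MISSING or f_d == MISSING:
        return "unknown"
    mm = m_d if v.minor_is_alt else 2 - m_d
    fm = f_d if v.minor_is_alt else 2 - f_d
    if mm >= 1 and fm == 0:
        return "maternal"
    if fm >= 1 and mm == 0:
        return "paternal"
    if mm >= 1 and fm >= 1:
        return "ambiguous"
    return "neither"  # untransmitted by either called parent


def _compound_het_call(entries, both_parents: bool) -> tuple[bool, bool]:
    """Decide whether a gene's rare hets form a compound heterozygote."""
    if not both_parents:
        return True, False
    origins = [o for _, o in entries]
    # one variant attributable to each parent, on distinct variants
    maternal_ok = [o in ("maternal", "ambiguous") for o in origins]
    paternal_ok = [o in ("paternal", "ambiguous") for o in origins]
    qualified = any(
        maternal_ok[i] and paternal_ok[j]
        for i, j in permutations(range(len(origins)), 2)
    )
    phase_known = any(
        origins[i] == "maternal" and origins[j] == "paternal"
        for i, j in permutations(range(len(origins)), 2)
    )
    return qualified, phase_known


@dataclass(frozen=True)
class SexCounts:
    hom_minor: int = 0
    het: int = 0
    hom_major: int = 0
    missing: int = 0

    @property
    def n_called(self) -> int:
        return self.hom_minor + self.het + self.hom_major

    @property
    def total(self) -> int:
        return self.n_called + self.missing

    def minor_af(self) -> float | None:
        if self.n_called == 0:
            return None
        return (2 * self.hom_minor + self.het) / (2 * self.n_called)


@dataclass(frozen=True)
class GenotypeCountsBySex:
    """Minor-allele genotype tallies for adult men, adult women, children."""

    men: SexCounts
    women: SexCounts
    children: SexCounts


@dataclass(frozen=True)
class ExclusionDecision:
    decision: str  # "EXCLUDED" or "RETAINED"
    reason: str
    minor_af_men: float | None
    minor_af_women: float | None
    fisher_p: float

    @property
    def excluded(self) -> bool:
        return self.decision == "EXCLUDED"


def sex_stratified_genotype_counts(
    cohort: Cohort, variant: VariantRecord
) -> GenotypeCountsBySex:
    """Tally minor-allele genotypes separately for men, women and children.

    Adults are the pedigree parents (fathers are men, mothers are women);
    children are tallied separately regardless of sex.
    """
    idx = cohort.sample_index
    md = variant.minor_dosages()
    child_set = set(cohort.child_ids())
    men = [s for s in cohort.father_ids() if s in idx]
    women = [s for s in cohort.mother_ids() if s in idx]
    kids = [s for s in child_set if s in idx]

    def tally(sample_ids) -> SexCounts:
        c = {2: 0, 1: 0, 0: 0, MISSING: 0}
        for s in sample_ids:
            c[int(md[idx[s]])] += 1
        return SexCounts(
            hom_minor=c[2], het=c[1], hom_major=c[0], missing=c[MISSING]
        )

    return GenotypeCountsBySex(men=tally(men), women=tally(women),
                               children=tally(kids))


def candidate_exclusion(counts: GenotypeCountsBySex) -> ExclusionDecision:
    """Rule a candidate in or out from the sex-stratified genotype tallies.

    A father homozygous for the putative maternal minor allele cannot
    transmit the contrasting major allele to any child, so a single
    hom-minor man among the affected families contradicts the variant being
    causal: the decision is EXCLUDED whenever ``men.hom_minor >= 1``.  The
    per-sex minor-allele frequencies and a two-sided Fisher exact p-value
    on hom-minor versus rest are reported as descriptive support only; the
    decision never depends on them.
    """
    if counts.men.total + counts.women.total == 0:
        raise ValueError("no adults counted at this variant")
    table = [
        [counts.men.hom_minor, counts.men.n_called - counts.men.hom_minor],
        [counts.women.hom_minor, counts.women.n_called - counts.women.hom_minor],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    if counts.men.hom_minor >= 1:
        return ExclusionDecision(
            decision="EXCLUDED",
            reason=(
                f"{counts.men.hom_minor} father(s) homozygous for the putative "
                "maternal minor allele cannot transmit the contrasting major "
                "allele, contradicting causality"
            ),
            minor_af_men=counts.men.minor_af(),
            minor_af_women=counts.women.minor_af(),
            fisher_p=float(p),
        )
    return ExclusionDecision(
        decision="RETAINED",
        reason="no father is homozygous for the putative maternal minor allele",
        minor_af_men=counts.men.minor_af(),
        minor_af_women=counts.women.minor_af(),
        fisher_p=float(p),
    )
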