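"""Brute-force re-statements of every screen predicate.

These evaluate each filter rule directly, variant by variant and family by
family, in plain Python, independently of the implementation under test.
They are deliberately naive: no shared helpers from the package's screen
module beyond the raw data containers.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def minor_dosage(variant, sample_pos):
    """Dosage of the rarer allele: re-derives orientation from the AF."""
    d = int(variant.dosages[sample_pos])
    if d == -1:
        return None
    if variant.alt_af is not None and variant.alt_af > 0.5:
        return 2 - d
    return d


def couple_filter_oracle(cohort, config):
    """Set of variant keys passing the incompatibility pattern."""
    idx = cohort.sample_index
    duos = [
        f for f in cohort.families
        if f.father_id is not None and f.mother_id in idx and f.father_id in idx
    ]
    keys = set()
    for v in cohort.variants:
        if v.consequence_class not in config.allowed_consequences:
            continue
        n_support, vetoed = 0, False
        for fam in duos:
            m = minor_dosage(v, idx[fam.mother_id])
            fa = minor_dosage(v, idx[fam.father_id])
            if m is None or fa is None:
                continue
            ok = m == 2 and fa == 0
            if ok and config.require_child_het:
                for c in fam.child_ids:
                    if c in idx:
                        k = minor_dosage(v, idx[c])
                        if k is not None and k != 1:
                            ok = False
            if ok:
                n_support += 1
            else:
                vetoed = True
        if not vetoed and n_support >= 1:
            keys.add(v.key)
    return keys


def cohort_hom_oracle(cohort, config):
    """Set of variant keys with a rare hom-minor case mother."""
    idx = cohort.sample_index
    classes = (
        {"frameshift", "splice_loss"}
        if config.lof_only_mode
        else {"missense", "frameshift", "splice_loss"}
    )
    keys = set()
    for v in cohort.variants:
        if v.alt_af is None:
            continue
        maf = min(v.alt_af, 1 - v.alt_af)
        if maf >= config.maf_max_hom_screen:
            continue
        if v.consequence_class not in classes:
            continue
        for fam in cohort.families:
            if fam.mother_id in idx and minor_dosage(v, idx[fam.mother_id]) == 2:
                keys.add(v.key)
                break
    return keys


def gene_recurrence_oracle(cohort, config):
    """Set of genes where one site or one aa-change is hom in enough women."""
    idx = cohort.sample_index
    hom_keys = cohort_hom_oracle(cohort, config)
    site_women: dict[tuple, set] = {}
    aa_women: dict[tuple, set] = {}
    for v in cohort.variants:
        if v.key not in hom_keys or v.gene is None:
            continue
        women = {
            f.mother_id for f in cohort.families
            if f.mother_id in idx and minor_dosage(v, idx[f.mother_id]) == 2
        }
        site_women.setdefault((v.gene, v.chrom, v.pos), set()).update(women)
        if v.aa_change is not None:
            aa_women.setdefault((v.gene, v.aa_change), set()).update(women)
    flagged = set()
    for (gene, *_), women in list(site_women.items()) + list(aa_women.items()):
        if len(women) >= config.min_women_recurrence:
            flagged.add(gene)
    return flagged


def _alleles(d):
    return {0: {"ref"}, 1: {"ref", "alt"}, 2: {"alt"}}[d]


def trio_oracle(cohort, family, config):
    """(de_novo, recessive_hom, compound_het) variant-key sets for the child."""
    idx = cohort.sample_index
    child = next(c for c in family.child_ids if c in idx)
    mi = idx.get(family.mother_id)
    fi = idx.get(family.father_id) if family.father_id else None

    de_novo, recessive, rare_hets = set(), set(), {}
    for v in cohort.variants:
        if v.consequence_class not in config.allowed_consequences:
            continue
        cd = int(v.dosages[idx[child]])
        if cd == -1:
            continue
        md = int(v.dosages[mi]) if mi is not None else -1
        fd = int(v.dosages[fi]) if fi is not None else -1
        if md != -1:
            novel = _alleles(cd) - _alleles(md)
            if fd != -1:
                novel -= _alleles(fd)
            if novel:
                de_novo.add(v.key)
        if v.alt_af is None:
            continue
        maf = min(v.alt_af, 1 - v.alt_af)
        if maf >= config.maf_max_recessive:
            continue
        cm = minor_dosage(v, idx[child])
        if cm == 2:
            recessive.add(v.key)
        elif cm == 1 and v.gene is not None:
            mm = minor_dosage(v, mi) if mi is not None else None
            fm = minor_dosage(v, fi) if fi is not None else None
            rare_hets.setdefault(v.gene, []).append((v.key, mm, fm))

    compound = set()
    both = mi is not None and fi is not None
    for gene, entries in rare_hets.items():
        if len(entries) < 2:
            continue
        if not both:
            compound.update(k for k, _, _ in entries)
            continue
        def can_maternal(mm, fm):
            return mm is not None and fm is not None and mm >= 1
        def can_paternal(mm, fm):
            return mm is not None and fm is not None and fm >= 1
        ok = any(
            can_maternal(*a[1:]) and can_paternal(*b[1:])
            for a, b in combinations(entries, 2)
        ) or any(
            can_maternal(*b[1:]) and can_paternal(*a[1:])
            for a, b in combinations(entries, 2)
        )
        if ok:
            compound.update(k for k, _, _ in entries)
    return de_novo, recessive, compound


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    return sum(p for x in range(col1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))
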