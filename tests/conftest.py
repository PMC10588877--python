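"""Shared fixtures: hand-built toy cohorts and the genotype-tally example."""

from __future__ import annotations

import numpy as np
import pytest

from alloscreen import Cohort, Family, VariantRecord


def build_cohort(samples, families, variant_specs, sex=None, affected=None):
    """Construct a cohort from explicit per-sample dosage lists.

    ``variant_specs`` is a list of dicts with at least ``dosages`` (ALT
    dosages in sample order, -1 for missing); chrom/pos/ref/alt and
    annotations get sensible defaults.
    """
    variants = []
    for i, vs in enumerate(variant_specs):
        vs = dict(vs)
        dosages = np.array(vs.pop("dosages"), dtype=np.int8)
        vs.setdefault("chrom", "1")
        vs.setdefault("pos", 100 * (i + 1))
        vs.setdefault("ref", "A")
        vs.setdefault("alt", "C")
        vs.setdefault("consequence_class", "missense")
        variants.append(VariantRecord(dosages=dosages, **vs))
    return Cohort(
        samples=list(samples),
        variants=variants,
        families=families,
        sex=sex or {},
        affected=affected or {},
    )


def trio_family(fid="FAM1"):
    return Family(
        family_id=fid,
        mother_id=f"{fid}_M",
        father_id=f"{fid}_F",
        child_ids=[f"{fid}_C1"],
        child_affected=[True],
    )


@pytest.fixture
def tally_cohort():
    """Cohort realising the worked genotype-tally example for one variant.

    22 couples and 4 mother-only families; among the men 3 are
    homozygous-minor and 8 heterozygous, among the 26 women 4 are
    homozygous-minor and 6 heterozygous; two families contribute one
    heterozygous child each.  The variant's minor allele is ALT at
    population frequency 0.29.
    """
    samples, families, sex = [], [], {}
    men_dos = [2] * 3 + [1] * 8 + [0] * 11
    women_dos = [2] * 4 + [1] * 6 + [0] * 16
    dosage = {}
    for i in range(26):
        fid = f"F{i + 1:02d}"
        mother = f"{fid}_M"
        samples.append(mother)
        sex[mother] = 2
        dosage[mother] = women_dos[i]
        father = None
        if i < 22:
            father = f"{fid}_F"
            samples.append(father)
            sex[father] = 1
            dosage[father] = men_dos[i]
        children = []
        if i < 2:
            cid = f"{fid}_C1"
            samples.append(cid)
            sex[cid] = 1
            dosage[cid] = 1
            children.append(cid)
        families.append(
            Family(
                family_id=fid,
                mother_id=mother,
                father_id=father,
                child_ids=children,
                child_affected=[True] * len(children),
            )
        )
    cohort = build_cohort(
        samples,
        families,
        [dict(dosages=[dosage[s] for s in samples], alt_af=0.29,
              gene="CANDIDATE1", aa_change="p.A503V")],
        sex=sex,
    )
    return cohort
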