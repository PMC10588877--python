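"""Reading and writing cohorts as VCF v4.2 + 6-column pedigree files.

The on-disk dialect: a multi-sample VCF with per-sample ``GT`` calls and
INFO keys ``AF`` (population ALT-allele frequency), ``CSQ_CLASS``
(consequence class) and optional ``GENE`` / ``AA_CHANGE``; alongside it a
tab-separated pedigree with columns FamilyID, SampleID, FatherID, MotherID,
Sex, AffectedStatus (0 = missing, sex 1 = male / 2 = female, affected
status 2 = affected).  Population AFs may instead come from a sidecar TSV
with columns chrom, pos, ref, alt, af.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohort import MISSING, Cohort, Family, VariantRecord

_PED_COLUMNS = ["family_id", "sample_id", "father_id", "mother_id", "sex", "affected"]


def _build_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chroms = sorted({v.chrom for v in cohort.variants}, key=str)
    for c in chroms or ["1"]:
        header.contigs.add(c, length=536_870_911)
    header.info.add("AF", "A", "Float", "Population alternate-allele frequency")
    header.info.add("CSQ_CLASS", "1", "String", "Predicted consequence class")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("AA_CHANGE", "1", "String", "Amino acid change")
    header.formats.add("GT", "1", "String", "Genotype")
    for s in cohort.samples:
        header.add_sample(s)
    return header


_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_cohort(cohort: Cohort, vcf_path, ped_path) -> None:
    """Write a cohort as an uncompressed VCF v4.2 plus pedigree file.

    Round-trips losslessly through :func:`read_cohort` at the genotype
    level; AF annotations are stored at 6-decimal precision.
    """
    if not cohort.samples:
        raise ValueError("cohort has no samples")
    header = _build_header(cohort)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for v in cohort.variants:
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if v.alt_af is not None:
                rec.info["AF"] = (v.alt_af,)
            rec.info["CSQ_CLASS"] = v.consequence_class
            if v.gene is not None:
                rec.info["GENE"] = v.gene
            if v.aa_change is not None:
                rec.info["AA_CHANGE"] = v.aa_change
            for s, d in zip(cohort.samples, v.dosages):
                rec.samples[s]["GT"] = _GT[int(d)]
            vf.write(rec)

    rows = []
    in_family: set[str] = set()
    for fam in cohort.families:
        father = fam.father_id or "0"
        rows.append([fam.family_id, fam.mother_id, "0", "0", 2, 1])
        in_family.add(fam.mother_id)
        if fam.father_id is not None:
            rows.append([fam.family_id, fam.father_id, "0", "0", 1, 1])
            in_family.add(fam.father_id)
        for cid, aff in zip(fam.child_ids, fam.child_affected):
            rows.append(
                [fam.family_id, cid, father, fam.mother_id,
                 cohort.sex.get(cid, 0), 2 if aff else 1]
            )
            in_family.add(cid)
    for s in cohort.samples:  # unrelated samples, if any
        if s not in in_family:
            rows.append([s, s, "0", "0", cohort.sex.get(s, 0),
                         2 if cohort.affected.get(s) else 1])
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(
        ped_path, sep="\t", header=False, index=False
    )


def read_pedigree(ped_path) -> tuple[list[Family], dict[str, int], dict[str, bool]]:
    """Parse the 6-column pedigree into families plus sex/affected maps."""
    ped = pd.read_csv(
        ped_path, sep="\t", header=None, names=_PED_COLUMNS,
        dtype=str, comment="#",
    )
    if ped.empty:
        raise ValueError(f"pedigree file {ped_path} is empty")
    ped["sex"] = ped["sex"].astype(int)
    ped["affected"] = ped["affected"].astype(int)
    sex = dict(zip(ped["sample_id"], ped["sex"]))
    affected = {s: a == 2 for s, a in zip(ped["sample_id"], ped["affected"])}

    families: list[Family] = []
    for fid, grp in ped.groupby("family_id", sort=False):
        children = grp[(grp["father_id"] != "0") | (grp["mother_id"] != "0")]
        founders = grp[(grp["father_id"] == "0") & (grp["mother_id"] == "0")]
        mothers = set(children["mother_id"]) - {"0"}
        fathers = set(children["father_id"]) - {"0"}
        mothers |= set(founders[founders["sex"] == 2]["sample_id"])
        fathers |= set(founders[founders["sex"] == 1]["sample_id"])
        if len(mothers) != 1:
            raise ValueError(
                f"family {fid}: expected exactly one mother, found {sorted(mothers)}"
            )
        if len(fathers) > 1:
            raise ValueError(
                f"family {fid}: expected at most one father, found {sorted(fathers)}"
            )
        child_ids = list(children["sample_id"])
        families.append(
            Family(
                family_id=str(fid),
                mother_id=next(iter(mothers)),
                father_id=next(iter(fathers)) if fathers else None,
                child_ids=child_ids,
                child_affected=[affected[c] for c in child_ids],
            )
        )
    return families, sex, affected


def _read_af_sidecar(path) -> dict[tuple[str, int, str, str], float]:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required.issubset(tab.columns):
        raise ValueError(f"AF sidecar must have columns {sorted(required)}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(r.af)
        for r in tab.itertuples()
    }


def read_cohort(vcf_path, ped_path, af_sidecar=None) -> Cohort:
    """Load a cohort from VCF + pedigree, splitting multiallelic records.

    Each ALT of a multiallelic record becomes its own biallelic
    :class:`VariantRecord`, with per-sample dosages recomputed for that ALT.
    The population AF comes from the sidecar table when provided, else from
    the INFO ``AF`` field; the minor allele is then whichever of REF/ALT is
    rarer (ties to ALT).
    """
    for p in (vcf_path, ped_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    families, sex, affected = read_pedigree(ped_path)
    sidecar = _read_af_sidecar(af_sidecar) if af_sidecar is not None else {}

    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        sample_set = set(samples)
        for fam in families:
            for s in [fam.mother_id, fam.father_id, *fam.child_ids]:
                if s is not None and s not in sample_set:
                    raise ValueError(
                        f"pedigree sample {s!r} (family {fam.family_id}) "
                        f"is absent from the VCF sample header"
                    )
        variants: list[VariantRecord] = []
        rec_no = 0
        try:
            for rec in vf:
                rec_no += 1
                variants.extend(_split_record(rec, samples, sidecar))
        except (ValueError, OSError) as exc:
            raise ValueError(
                f"malformed VCF record at data line {rec_no + 1} "
                f"of {vcf_path}: {exc}"
            ) from exc
    return Cohort(
        samples=samples, variants=variants, families=families,
        sex=sex, affected=affected,
    )


def _info_get(rec, key, default=None):
    # pysam raises on keys absent from the header rather than returning
    # the default, so guard the lookup
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _split_record(rec, samples, sidecar) -> list[VariantRecord]:
    out = []
    alts = rec.alts or ()
    af_info = _info_get(rec, "AF")
    if af_info is not None and not isinstance(af_info, tuple):
        af_info = (af_info,)
    csq = _info_get(rec, "CSQ_CLASS", "other")
    if isinstance(csq, tuple):
        csq = csq[0]
    gene = _info_get(rec, "GENE")
    aa = _info_get(rec, "AA_CHANGE")
    gts = [rec.samples[s].get("GT") or (None,) for s in samples]
    for j, alt in enumerate(alts):
        allele_idx = j + 1
        dosages = np.full(len(samples), MISSING, dtype=np.int8)
        for k, gt in enumerate(gts):
            if any(a is None for a in gt):
                continue
            dosages[k] = sum(1 for a in gt if a == allele_idx)
        af = sidecar.get((rec.chrom, rec.pos, rec.ref, str(alt)))
        if af is None and af_info is not None and j < len(af_info):
            af = af_info[j]
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=str(alt),
                dosages=dosages,
                consequence_class=str(csq),
                gene=str(gene) if gene is not None else None,
                aa_change=str(aa) if aa is not None else None,
                alt_af=round(float(af), 6) if af is not None else None,
            )
        )
    return out


def write_af_sidecar(cohort: Cohort, path) -> None:
    """Write the cohort's AF annotations as a sidecar TSV."""
    rows = [
        dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, af=v.alt_af)
        for v in cohort.variants
        if v.alt_af is not None
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


__all__ = [
    "read_cohort",
    "read_pedigree",
    "write_cohort",
    "write_af_sidecar",
]
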