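"""Readers and writers for the pipeline's external formats.

All tabular formats are plain CSV/TSV; the delimiter is auto-detected from
the file extension (``.csv`` → comma, anything else → tab) and can be
overridden.  SNP input is standard VCF read through cyvcf2, GT-only and
biallelic-only.  Writers and readers round-trip exactly on valid data.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .model import (
    Allele,
    Family,
    GenotypeTable,
    LocusRegistry,
    PhasedHaplotype,
    RegistryError,
    SNP,
    allele_sort_key,
)

_NONE_TOKENS = {"", "-", "–", "—", "na", "nan", "none", "."}


def _delim(path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_allele(token) -> Optional[Allele]:
    """Numeric tokens become int (bp); anything else is kept as a string
    symbol.  Missing-value tokens become None."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip()
    if s.lower() in _NONE_TOKENS:
        return None
    try:
        f = float(s)
    except ValueError:
        return s
    if f != int(f):
        raise ValueError(f"unparsable allele token {token!r} (fractional bp)")
    return int(f)


def _parse_allele_list(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    s = str(cell).strip()
    if s.lower() in _NONE_TOKENS:
        return frozenset()
    out = set()
    for tok in s.split("/"):
        a = _parse_allele(tok)
        if a is None:
            raise ValueError(f"unparsable allele token in {cell!r}")
        out.add(a)
    return frozenset(out)


def read_locus_registry(path, delimiter: Optional[str] = None) -> LocusRegistry:
    """Read a locus table: columns locus, L-specific alleles, R-specific
    alleles; alleles "/"-separated; "–" or empty means none.  File order
    is preserved as registry order."""
    df = pd.read_csv(path, sep=_delim(path, delimiter), dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 3:
        raise RegistryError(f"{path}: expected 3 columns (locus, L, R)")
    loci, l_spec, r_spec = [], {}, {}
    for _, row in df.iterrows():
        locus = str(row.iloc[0]).strip()
        if locus in l_spec:
            raise RegistryError(f"{path}: duplicate locus name {locus}")
        loci.append(locus)
        l_spec[locus] = _parse_allele_list(row.iloc[1])
        r_spec[locus] = _parse_allele_list(row.iloc[2])
    return LocusRegistry(loci=tuple(loci), l_specific=l_spec, r_specific=r_spec)


def write_locus_registry(registry: LocusRegistry, path,
                         delimiter: Optional[str] = None) -> None:
    rows = []
    for locus in registry.loci:
        rows.append({
            "locus": locus,
            "lessonae_specific": "/".join(
                str(a) for a in sorted(registry.l_specific[locus], key=allele_sort_key)) or "-",
            "ridibundus_specific": "/".join(
                str(a) for a in sorted(registry.r_specific[locus], key=allele_sort_key)) or "-",
        })
    pd.DataFrame(rows).to_csv(path, sep=_delim(path, delimiter), index=False)


def read_genotypes(path, registry: LocusRegistry,
                   delimiter: Optional[str] = None,
                   permissive: bool = False,
                   marker_mode: str = "microsatellite") -> GenotypeTable:
    """Read a long-format genotype table: individual, locus, allele1,
    allele2 (blank/NA = missing; allele2 repeats allele1 for homozygotes).

    Alleles absent from the registry's diagnostic union are kept and simply
    class as non-diagnostic.  More than two distinct alleles at one
    (individual, locus) is an error — a possible triploid — unless
    ``permissive`` is set, in which case the call is stored aside for the
    ploidy check.
    """
    df = pd.read_csv(path, sep=_delim(path, delimiter), dtype=str,
                     keep_default_na=False)
    table = GenotypeTable(marker_mode=marker_mode)
    seen: dict[tuple[str, str], set] = {}
    for _, row in df.iterrows():
        ind = str(row.iloc[0]).strip()
        locus = str(row.iloc[1]).strip()
        if locus not in registry:
            raise ValueError(f"{path}: locus {locus} absent from registry")
        alleles = [_parse_allele(row.iloc[c]) for c in range(2, df.shape[1])]
        key = (ind, locus)
        acc = seen.setdefault(key, set())
        acc.update(a for a in alleles if a is not None)
        if len(acc) > 2:
            if not permissive:
                raise ValueError(
                    f"{path}: {ind} @ {locus} has {len(acc)} distinct alleles "
                    "in diploid mode (possible triploidy)")
            table.calls.pop(key, None)
            table.permissive_calls[key] = tuple(sorted(acc, key=allele_sort_key))
            continue
        obs = [a for a in alleles if a is not None]
        prev = table.call(ind, locus)
        prev_obs = [a for a in prev if a is not None]
        table.set_call(ind, locus, prev_obs + [a for a in obs if a not in prev_obs]
                       if prev_obs else obs)
    return table


def write_genotypes(table: GenotypeTable, path,
                    delimiter: Optional[str] = None) -> None:
    rows = []
    for (ind, locus) in sorted(table.calls):
        a1, a2 = table.calls[(ind, locus)]
        rows.append({"individual": ind, "locus": locus,
                     "allele1": "" if a1 is None else a1,
                     "allele2": "" if a2 is None else a2})
    pd.DataFrame(rows).to_csv(path, sep=_delim(path, delimiter), index=False)


def read_pedigree(path, delimiter: Optional[str] = None) -> list[Family]:
    """Read a cross map: cross_id, mother_id, father_id, offspring_id, sex.

    One Family per cross_id (rows grouped); the same father may appear in
    several crosses.  A row with an empty offspring_id declares a cross
    with no (genotyped) offspring.  An offspring id may belong to only one
    family.
    """
    df = pd.read_csv(path, sep=_delim(path, delimiter), dtype=str,
                     keep_default_na=False)
    crosses: dict[str, dict] = {}
    seen_offspring: dict[str, str] = {}
    for _, row in df.iterrows():
        cid = str(row.iloc[0]).strip()
        mother = str(row.iloc[1]).strip()
        father = str(row.iloc[2]).strip()
        if not mother or not father:
            raise ValueError(f"{path}: cross {cid}: missing parent id")
        entry = crosses.setdefault(cid, {"mother": mother, "father": father,
                                         "offspring": []})
        if entry["mother"] != mother or entry["father"] != father:
            raise ValueError(f"{path}: cross {cid}: inconsistent parent ids")
        off = str(row.iloc[3]).strip() if df.shape[1] > 3 else ""
        if not off:
            continue
        sex = str(row.iloc[4]).strip().lower() if df.shape[1] > 4 else ""
        sex = sex if sex in ("male", "female") else "undetermined"
        if off in seen_offspring and seen_offspring[off] != cid:
            raise ValueError(
                f"{path}: offspring {off} listed in two families "
                f"({seen_offspring[off]} and {cid})")
        seen_offspring[off] = cid
        entry["offspring"].append((off, sex))
    return [Family(cross_id=cid, mother_id=e["mother"], father_id=e["father"],
                   offspring=tuple(e["offspring"]))
            for cid, e in sorted(crosses.items())]


def write_pedigree(families: Sequence[Family], path,
                   delimiter: Optional[str] = None) -> None:
    rows = []
    for fam in sorted(families, key=lambda f: f.cross_id):
        if not fam.offspring:
            rows.append({"cross_id": fam.cross_id, "mother_id": fam.mother_id,
                         "father_id": fam.father_id, "offspring_id": "", "sex": ""})
        for off, sex in fam.offspring:
            rows.append({"cross_id": fam.cross_id, "mother_id": fam.mother_id,
                         "father_id": fam.father_id, "offspring_id": off,
                         "sex": sex})
    pd.DataFrame(rows).to_csv(path, sep=_delim(path, delimiter), index=False)


class VcfResult(NamedTuple):
    table: GenotypeTable
    registry: LocusRegistry
    n_skipped: int


def read_snp_vcf(path, sample_ids: Optional[Sequence[str]] = None,
                 on_multiallelic: str = "error") -> VcfResult:
    """Read a biallelic VCF (GT only) into a snp-mode GenotypeTable.

    Loci are named "CHROM:POS"; alleles are the REF/ALT base symbols;
    "./." becomes a missing call.  Sites with more than one ALT are
    rejected (``on_multiallelic="error"``) or dropped and counted
    (``"skip"``).  The returned registry lists the sites in file order
    with empty diagnostic sets — species-specificity of SNP alleles is
    supplied downstream, not by the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in vcf.samples]
        if missing:
            raise ValueError(f"{path}: sample(s) {missing} absent from VCF header")
        vcf.set_samples(list(sample_ids))
    samples = vcf.samples
    table = GenotypeTable(marker_mode=SNP)
    loci: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                n_skipped += 1
                continue
            raise ValueError(
                f"{path}: multiallelic site {var.CHROM}:{var.POS} "
                "(use on_multiallelic='skip' to drop)")
        locus = f"{var.CHROM}:{var.POS}"
        loci.append(locus)
        symbols = [var.REF, var.ALT[0]]
        for sample, gt in zip(samples, var.genotypes):
            alleles = [symbols[i] for i in gt[:2] if i >= 0]
            table.set_call(sample, locus, alleles)
    registry = LocusRegistry(loci=tuple(loci),
                             l_specific={l: frozenset() for l in loci},
                             r_specific={l: frozenset() for l in loci})
    return VcfResult(table, registry, n_skipped)


def write_phased(haplotypes: Sequence[PhasedHaplotype], path,
                 registry: LocusRegistry,
                 delimiter: Optional[str] = None) -> None:
    """Write phased haplotypes as a long table (individual, origin, locus,
    allele, status), sorted by (individual, origin, registry locus order)."""
    if not haplotypes:
        raise ValueError("no haplotypes to write")
    rows = []
    for hap in sorted(haplotypes, key=lambda h: (h.individual_id, h.origin)):
        for locus in registry.loci:
            if locus not in hap.status:
                continue
            st = hap.status[locus]
            a = hap.alleles.get(locus)
            rows.append({"individual": hap.individual_id, "origin": hap.origin,
                         "locus": locus, "allele": "" if a is None else a,
                         "status": st})
    pd.DataFrame(rows).to_csv(path, sep=_delim(path, delimiter), index=False)


def read_phased(path, delimiter: Optional[str] = None) -> list[PhasedHaplotype]:
    df = pd.read_csv(path, sep=_delim(path, delimiter), dtype=str,
                     keep_default_na=False)
    haps: dict[tuple[str, str], PhasedHaplotype] = {}
    for _, row in df.iterrows():
        key = (row["individual"], row["origin"])
        hap = haps.setdefault(key, PhasedHaplotype(
            individual_id=row["individual"], origin=row["origin"]))
        locus, status = row["locus"], row["status"]
        hap.status[locus] = status
        if status == "phased":
            a = _parse_allele(row["allele"])
            if a is not None:
                hap.alleles[locus] = a
    return list(haps.values())
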