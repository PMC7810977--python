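"""Family-wise phasing of diploid genotypes into haploid genomes.

In an R[L] × RR cross every offspring receives one recombinant egg
haplotype from its RR mother and one clonal sperm haplotype from its
hybrid father.  Because the paternal gamete is a whole haploid genome of
known species ([L] or [R]), each offspring genotype can be split locus by
locus: the maternal allele must occur in the mother, the paternal allele
in the father, the maternal allele cannot be lessonae-specific (the
mother is RR) and the paternal allele's specificity must match the gamete
class.  When both assignments of a heterozygote survive these checks, the
allele present in the father but absent from the mother is the paternal
one; if neither or both are father-exclusive the locus stays ambiguous.
A locus with no surviving assignment is a conflict — recorded, never
fatal, because the interesting biology (genome leakage) lives in the
conflicts.

Before phasing, loci are filtered (both parents typed, ≥75% of the
family's offspring typed by default) and screened for null-allele
artifacts: an offspring apparently homozygous for an allele one parent
lacks while the other carries it is the signature of a null allele in the
first parent, and such loci are dropped family-wide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .model import Allele, Family, GenotypeTable, LocusRegistry, PhasedHaplotype, SNP
from .taxon import TaxonCall, assign_taxon


@dataclass(frozen=True)
class PhaseParams:
    offspring_presence: float = 0.75   # min fraction of offspring fully typed
    min_support: int = 2               # diagnostic loci needed per taxon call
    max_missing: float = 0.65          # MLG missing-data ceiling (downstream)


@dataclass(frozen=True)
class CrossType:
    """Cross class and the offspring classes each paternal gamete yields."""
    label: str                      # RL_father_x_RR_mother | RR_father_x_RR_mother
    father_taxon: str
    mother_taxon: str

    @property
    def hybrid_father(self) -> bool:
        return self.father_taxon == "RL"


@dataclass(frozen=True)
class Conflict:
    offspring_id: str
    locus: Optional[str]
    kind: str          # leak_candidate | unattributable_allele | paternal_deviation
                       # | taxon_fallback | taxon_unknown
    description: str
    allele: Optional[Allele] = None
    expected_genome: Optional[str] = None  # "[L]" or "[R]"


@dataclass
class PhasedFamily:
    family: Family
    cross_type: CrossType
    retained_loci: list[str]
    dropped_loci: dict[str, str]
    offspring_haplotypes: dict[str, tuple[PhasedHaplotype, PhasedHaplotype]]
    gamete_class: dict[str, Optional[str]]   # offspring -> "[L]" | "[R]" | None
    offspring_taxon: dict[str, TaxonCall]
    father_L_haplotype: Optional[PhasedHaplotype]
    father_R_haplotype: Optional[PhasedHaplotype]
    conflicts: list[Conflict] = field(default_factory=list)


def infer_cross_type(family: Family, table: GenotypeTable,
                     registry: LocusRegistry, min_support: int = 2) -> CrossType:
    mother = assign_taxon(family.mother_id, table, registry, min_support)
    father = assign_taxon(family.father_id, table, registry, min_support)
    if mother.taxon != "RR":
        raise ValueError(
            f"cross {family.cross_id}: mother {family.mother_id} called "
            f"{mother.taxon}, expected RR")
    if father.taxon == "RL":
        label = "RL_father_x_RR_mother"
    elif father.taxon == "RR":
        label = "RR_father_x_RR_mother"
    else:
        raise ValueError(
            f"cross {family.cross_id}: father {family.father_id} called "
            f"{father.taxon}; only RL or RR fathers are supported")
    return CrossType(label=label, father_taxon=father.taxon, mother_taxon="RR")


def _family_loci(family: Family, table: GenotypeTable,
                 registry: LocusRegistry) -> list[str]:
    members = [family.mother_id, family.father_id, *family.offspring_ids]
    return [l for l in registry.loci
            if any((m, l) in table.calls or (m, l) in table.permissive_calls
                   for m in members)]


def filter_family_loci(family: Family, table: GenotypeTable,
                       registry: LocusRegistry,
                       offspring_presence: float = 0.75
                       ) -> tuple[list[str], dict[str, str]]:
    """Retain a locus iff both parents are fully typed, at least
    ``offspring_presence`` of the offspring are fully typed, and (snp
    mode) the site is biallelic within the family.  Returns the retained
    list in registry order and a locus → reason map for the rest."""
    retained: list[str] = []
    dropped: dict[str, str] = {}
    offspring = family.offspring_ids
    for locus in _family_loci(family, table, registry):
        if not (table.has_full_call(family.mother_id, locus)
                and table.has_full_call(family.father_id, locus)):
            dropped[locus] = "parent_missing"
            continue
        if offspring:
            n_ok = sum(table.has_full_call(o, locus) for o in offspring)
            if n_ok < offspring_presence * len(offspring):
                dropped[locus] = "offspring_presence"
                continue
        if table.marker_mode == SNP:
            alleles = set()
            for m in (family.mother_id, family.father_id, *offspring):
                alleles.update(table.observed(m, locus))
            if len(alleles) > 2:
                dropped[locus] = "multiallelic"
                continue
        retained.append(locus)
    return retained, dropped


def screen_null_alleles(family: Family, table: GenotypeTable,
                        registry: LocusRegistry,
                        loci: Optional[list[str]] = None) -> list[str]:
    """Flag loci bearing the null-allele signature: an offspring apparently
    homozygous for an allele that one parent does not carry while the
    other parent does (the silent parent must have transmitted a null)."""
    loci = loci if loci is not None else list(registry.loci)
    flagged: list[str] = []
    for locus in loci:
        mother = set(table.observed(family.mother_id, locus))
        father = set(table.observed(family.father_id, locus))
        if not mother or not father:
            continue
        for off in family.offspring_ids:
            gt = table.genotype(off, locus)
            if gt is None or gt[0] != gt[1]:
                continue
            a = gt[0]
            if (a in mother) != (a in father):  # in exactly one parent
                flagged.append(locus)
                break
    return flagged


def _candidate_assignments(off_gt, mother_gt, father_gt, locus,
                           registry: LocusRegistry,
                           gamete: Optional[str],
                           mother_is_rr: bool,
                           relax_class: bool = False) -> list[tuple]:
    """Enumerate (maternal, paternal) assignments of the offspring's allele
    pair that survive the transmission and species constraints."""
    a, b = off_gt
    cands = [(a, b)] if a == b else [(a, b), (b, a)]
    valid = []
    for m, p in cands:
        if m not in mother_gt or p not in father_gt:
            continue
        if mother_is_rr and registry.classify(locus, m) == "L":
            continue
        if not relax_class and gamete is not None:
            p_class = registry.classify(locus, p)
            if gamete == "[L]" and p_class == "R":
                continue
            if gamete == "[R]" and p_class == "L":
                continue
        valid.append((m, p))
    if len(valid) > 1:
        exclusive = [mp for mp in valid if mp[1] not in mother_gt]
        if len(exclusive) == 1:
            valid = exclusive
    return valid


def phase_offspring(offspring_id: str, family: Family, table: GenotypeTable,
                    registry: LocusRegistry, cross_type: CrossType,
                    gamete: Optional[str],
                    loci: Optional[list[str]] = None
                    ) -> tuple[PhasedHaplotype, PhasedHaplotype, list[Conflict]]:
    """Split one offspring's genotype into (maternal, paternal) haplotypes.

    ``gamete`` is the paternal gamete class: "[L]"/"[R]" for a hybrid
    father, None for the Mendelian control cross (no species constraint
    on the paternal allele).
    """
    if offspring_id not in family.offspring_ids:
        raise KeyError(f"{offspring_id} not an offspring of cross {family.cross_id}")
    loci = loci if loci is not None else list(registry.loci)
    pat_origin = "paternal_L" if gamete == "[L]" else "paternal_R"
    maternal = PhasedHaplotype(individual_id=offspring_id, origin="maternal_R")
    paternal = PhasedHaplotype(individual_id=offspring_id, origin=pat_origin)
    conflicts: list[Conflict] = []
    for locus in loci:
        off_gt = table.genotype(offspring_id, locus)
        m_gt = table.genotype(family.mother_id, locus)
        f_gt = table.genotype(family.father_id, locus)
        if off_gt is None or m_gt is None or f_gt is None:
            maternal.status[locus] = paternal.status[locus] = "missing"
            continue
        valid = _candidate_assignments(off_gt, m_gt, f_gt, locus, registry,
                                       gamete,
                                       mother_is_rr=cross_type.mother_taxon == "RR")
        if len(valid) == 1:
            m, p = valid[0]
            maternal.status[locus] = paternal.status[locus] = "phased"
            maternal.alleles[locus] = m
            paternal.alleles[locus] = p
        elif len(valid) > 1:
            maternal.status[locus] = paternal.status[locus] = "ambiguous"
        else:
            maternal.status[locus] = paternal.status[locus] = "conflict"
            conflicts.append(_diagnose_conflict(
                offspring_id, locus, off_gt, m_gt, f_gt, registry, gamete,
                cross_type.mother_taxon == "RR"))
    return maternal, paternal, conflicts


def _diagnose_conflict(offspring_id, locus, off_gt, m_gt, f_gt,
                       registry: LocusRegistry, gamete: Optional[str],
                       mother_is_rr: bool = True) -> Conflict:
    # Would the locus phase if the gamete-species constraint were relaxed?
    relaxed = _candidate_assignments(off_gt, m_gt, f_gt, locus, registry,
                                     gamete, mother_is_rr=mother_is_rr,
                                     relax_class=True)
    if gamete is not None and relaxed:
        other = "R" if gamete == "[L]" else "L"
        allele = relaxed[0][1]
        return Conflict(
            offspring_id=offspring_id, locus=locus, kind="leak_candidate",
            description=(f"paternal {other} allele in {gamete} gamete context"),
            allele=allele, expected_genome=gamete)
    orphan = [a for a in off_gt if a not in m_gt and a not in f_gt]
    if orphan:
        return Conflict(
            offspring_id=offspring_id, locus=locus, kind="unattributable_allele",
            description=(f"allele {orphan[0]} absent from both parents "
                         "(mutation or genotyping error candidate)"),
            allele=orphan[0], expected_genome=gamete)
    return Conflict(offspring_id=offspring_id, locus=locus,
                    kind="unattributable_allele",
                    description="no transmission-consistent assignment",
                    expected_genome=gamete)


def _gamete_class_for(call: TaxonCall, cross_type: CrossType,
                      min_support: int) -> tuple[Optional[str], Optional[Conflict]]:
    """Map an offspring taxon call to its paternal gamete class.

    Unknown calls with sub-threshold minority evidence fall back to the
    majority context (flagged), so single-locus leakage does not silence
    an entire offspring.
    """
    if not cross_type.hybrid_father:
        return None, None
    if call.taxon == "RL":
        return "[L]", None
    if call.taxon == "RR":
        return "[R]", None
    n_l, n_r = call.n_l_diagnostic_loci, call.n_r_diagnostic_loci
    if n_r >= min_support and 0 < n_l < min_support:
        return "[R]", Conflict(
            offspring_id=call.individual_id, locus=None, kind="taxon_fallback",
            description=(f"taxon unknown (n_L={n_l}, n_R={n_r}); phased in "
                         "[R] gamete context, minority L evidence flagged"))
    if n_l >= min_support and 0 < n_r < min_support:
        return "[L]", Conflict(
            offspring_id=call.individual_id, locus=None, kind="taxon_fallback",
            description=(f"taxon unknown (n_L={n_l}, n_R={n_r}); phased in "
                         "[L] gamete context, minority R evidence flagged"))
    return None, Conflict(
        offspring_id=call.individual_id, locus=None, kind="taxon_unknown",
        description=f"taxon unknown (n_L={n_l}, n_R={n_r}); offspring not phased")


def _consensus(values: Counter) -> Optional[Allele]:
    """Strict-majority consensus; None when tied or empty."""
    if not values:
        return None
    ranked = values.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def phase_family(family: Family, table: GenotypeTable, registry: LocusRegistry,
                 params: PhaseParams = PhaseParams()) -> PhasedFamily:
    """Run the full per-family pipeline: locus filtering, null screening,
    per-offspring phasing, and inference of the father's transmitted
    haploid genome(s) as the per-class consensus across offspring.

    Within one gamete class a clonal father's haplotype must be identical
    across offspring; any phased paternal allele deviating from the class
    consensus becomes a recorded conflict (leakage / mutation candidate),
    not an error.
    """
    cross_type = infer_cross_type(family, table, registry, params.min_support)
    retained, dropped = filter_family_loci(
        family, table, registry, params.offspring_presence)
    for locus in screen_null_alleles(family, table, registry, retained):
        retained.remove(locus)
        dropped[locus] = "null_allele"
    if not retained:
        raise ValueError(f"cross {family.cross_id}: no retained loci")

    conflicts: list[Conflict] = []
    haplotypes: dict[str, tuple[PhasedHaplotype, PhasedHaplotype]] = {}
    gamete_class: dict[str, Optional[str]] = {}
    taxa: dict[str, TaxonCall] = {}
    for off in sorted(family.offspring_ids):
        call = assign_taxon(off, table, registry, params.min_support)
        taxa[off] = call
        gamete, note = _gamete_class_for(call, cross_type, params.min_support)
        if note is not None:
            conflicts.append(note)
        gamete_class[off] = gamete
        if cross_type.hybrid_father and gamete is None:
            continue
        maternal, paternal, off_conf = phase_offspring(
            off, family, table, registry, cross_type, gamete, retained)
        haplotypes[off] = (maternal, paternal)
        conflicts.extend(off_conf)

    father_L = _father_consensus(family, haplotypes, gamete_class, "[L]",
                                 "paternal_L", retained, conflicts)
    father_R = _father_consensus(family, haplotypes, gamete_class, "[R]",
                                 "paternal_R", retained, conflicts)
    if not cross_type.hybrid_father:
        father_L = None
    if father_R is not None and cross_type.hybrid_father:
        _fill_father_r_from_complement(father_R, father_L, family, table, retained)
    elif father_R is None and cross_type.hybrid_father and father_L is not None:
        father_R = PhasedHaplotype(individual_id=family.father_id,
                                   origin="paternal_R")
        _fill_father_r_from_complement(father_R, father_L, family, table, retained)

    return PhasedFamily(
        family=family, cross_type=cross_type, retained_loci=retained,
        dropped_loci=dropped, offspring_haplotypes=haplotypes,
        gamete_class=gamete_class, offspring_taxon=taxa,
        father_L_haplotype=father_L, father_R_haplotype=father_R,
        conflicts=conflicts)


def _father_consensus(family, haplotypes, gamete_class, gclass, origin,
                      loci, conflicts) -> Optional[PhasedHaplotype]:
    members = [o for o, g in gamete_class.items() if g == gclass and o in haplotypes]
    if not members:
        return None
    consensus = PhasedHaplotype(individual_id=family.father_id, origin=origin)
    for locus in loci:
        votes = Counter(haplotypes[o][1].alleles[locus] for o in members
                        if haplotypes[o][1].status.get(locus) == "phased")
        if not votes:
            consensus.status[locus] = "missing"
            continue
        top = _consensus(votes)
        if top is None:
            consensus.status[locus] = "ambiguous"
            continue
        consensus.status[locus] = "phased"
        consensus.alleles[locus] = top
        for o in sorted(members):
            hap = haplotypes[o][1]
            if hap.status.get(locus) == "phased" and hap.alleles[locus] != top:
                conflicts.append(Conflict(
                    offspring_id=o, locus=locus, kind="paternal_deviation",
                    description=(f"paternal allele {hap.alleles[locus]} deviates "
                                 f"from the {gclass} class consensus {top}"),
                    allele=hap.alleles[locus], expected_genome=gclass))
    return consensus


def _fill_father_r_from_complement(father_R, father_L, family, table, loci):
    """At loci where the father's [L] allele is known and his genotype is
    heterozygous, the other allele is his R haplotype — a direct
    generalization of the species-specificity rule."""
    if father_L is None:
        return
    for locus in loci:
        if father_R.status.get(locus) == "phased":
            continue
        if father_L.status.get(locus) != "phased":
            father_R.status.setdefault(locus, "missing")
            continue
        f_gt = table.genotype(family.father_id, locus)
        if f_gt is None:
            father_R.status.setdefault(locus, "missing")
            continue
        l_allele = father_L.alleles[locus]
        rest = [a for a in f_gt if a != l_allele]
        if len(rest) == 1 or (len(rest) == 2 and rest[0] == rest[1]):
            father_R.status[locus] = "phased"
            father_R.alleles[locus] = rest[0]
        elif not rest:  # father homozygous for the clonal allele
            father_R.status[locus] = "phased"
            father_R.alleles[locus] = l_allele
        else:
            father_R.status.setdefault(locus, "ambiguous")
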