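"""Taxon assignment from species-diagnostic alleles.

A diploid water frog showing lessonae-specific alleles at enough loci and
ridibundus-specific alleles at enough loci is a hybrid (RL); only
R-specific (plus non-diagnostic) alleles indicate P. ridibundus (RR);
only L-specific indicates P. lessonae (LL).  ``min_support`` loci of
diagnostic evidence are required for any positive call, which guards
against a single leaked allele mimicking a hybrid.  Shared
(non-diagnostic) alleles never contribute evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import GenotypeTable, LocusRegistry


@dataclass(frozen=True)
class TaxonCall:
    individual_id: str
    taxon: str  # RR | RL | LL | unknown
    n_l_diagnostic_loci: int
    n_r_diagnostic_loci: int
    ploidy_flag: str  # diploid_consistent | possible_polyploid | insufficient


def diagnostic_support(individual: str, table: GenotypeTable,
                       registry: LocusRegistry) -> tuple[int, int]:
    """Number of loci with ≥1 observed L-specific allele, and with ≥1
    observed R-specific allele.  Half-calls still carry evidence."""
    n_l = n_r = 0
    for locus in registry.loci:
        classes = {registry.classify(locus, a)
                   for a in table.observed(individual, locus)}
        n_l += "L" in classes
        n_r += "R" in classes
    return n_l, n_r


def assess_ploidy(individual: str, table: GenotypeTable) -> str:
    """Allele-count ploidy screen: >2 alleles anywhere (permissive storage)
    suggests polyploidy; fewer than 3 typed loci is insufficient evidence.
    Peak-intensity dosage is outside the data model."""
    typed = [l for l in table.loci if not table.is_missing(individual, l)]
    if any((individual, l) in table.permissive_calls for l in typed):
        return "possible_polyploid"
    if len(typed) < 3:
        return "insufficient"
    return "diploid_consistent"


def assign_taxon(individual: str, table: GenotypeTable,
                 registry: LocusRegistry, min_support: int = 2) -> TaxonCall:
    """Deterministic taxon call from diagnostic-allele presence.

    RL requires ≥ min_support loci of L evidence AND ≥ min_support of R
    evidence; RR requires zero L evidence and ≥ min_support R loci; LL is
    symmetric.  Sub-threshold minority evidence (e.g. one L-specific locus
    on an otherwise pure-R background) yields "unknown" rather than a
    forced call — the phasing engine inspects such cases separately as
    leakage candidates.
    """
    if individual not in table.individuals:
        raise KeyError(f"individual {individual} absent from genotype table")
    n_l, n_r = diagnostic_support(individual, table, registry)
    if n_l >= min_support and n_r >= min_support:
        taxon = "RL"
    elif n_r >= min_support and n_l == 0:
        taxon = "RR"
    elif n_l >= min_support and n_r == 0:
        taxon = "LL"
    else:
        taxon = "unknown"
    return TaxonCall(individual_id=individual, taxon=taxon,
                     n_l_diagnostic_loci=n_l, n_r_diagnostic_loci=n_r,
                     ploidy_flag=assess_ploidy(individual, table))


def count_diagnostic_alleles(table: "GenotypeTable | None",
                             registry: LocusRegistry,
                             mode: str = "observed") -> tuple[int, int, int]:
    """Count distinct (locus, allele) pairs by specificity class.

    mode="registry": count the alleles listed in the registry (all of
    which are diagnostic by construction).  mode="observed": count the
    distinct alleles actually observed in the table; the total includes
    non-diagnostic alleles.
    """
    if mode == "registry":
        n_l = sum(len(registry.l_specific[l]) for l in registry.loci)
        n_r = sum(len(registry.r_specific[l]) for l in registry.loci)
        return (n_l + n_r, n_l, n_r)
    if table is None:
        raise ValueError("observation mode needs a genotype table")
    seen: set[tuple[str, object]] = set()
    for (ind, locus) in list(table.calls) + list(table.permissive_calls):
        for a in table.observed(ind, locus):
            seen.add((locus, a))
    n_l = sum(1 for locus, a in seen if registry.classify(locus, a) == "L")
    n_r = sum(1 for locus, a in seen if registry.classify(locus, a) == "R")
    return (len(seen), n_l, n_r)
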