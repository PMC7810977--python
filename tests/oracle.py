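"""Independent brute-force oracles used by the test suite.

The phasing oracle enumerates every (mother haplotype slot × father
haplotype slot) gamete combination directly — a different route from the
engine, which enumerates orderings of the offspring's allele pair — and
applies the same declared constraint semantics.
"""

from collections import Counter

from hemiphase.model import allele_sort_key


def brute_force_locus_phase(off_gt, mother_gt, father_gt, locus, registry,
                            gamete, mother_is_rr=True):
    """Return (status, assignment) where assignment is the unique
    (maternal, paternal) pair, or None.

    Enumerates the ≤4 slot combinations; keeps those that reproduce the
    offspring's genotype multiset and satisfy: maternal allele not
    lessonae-specific when the mother is RR; paternal allele's species
    class compatible with the gamete class.  If several survive and
    exactly one paternal allele is absent from the mother, that one wins.
    """
    target = Counter(off_gt)
    valid = set()
    for m in mother_gt:
        for p in father_gt:
            if Counter((m, p)) != target:
                continue
            if mother_is_rr and registry.classify(locus, m) == "L":
                continue
            p_class = registry.classify(locus, p)
            if gamete == "[L]" and p_class == "R":
                continue
            if gamete == "[R]" and p_class == "L":
                continue
            valid.add((m, p))
    if len(valid) > 1:
        exclusive = {mp for mp in valid if mp[1] not in mother_gt}
        if len(exclusive) == 1:
            valid = exclusive
    if len(valid) == 1:
        return "phased", next(iter(valid))
    if valid:
        return "ambiguous", None
    return "conflict", None


def brute_force_retained(family, table, threshold):
    """Row-scan reimplementation of the locus filter (microsatellite mode)."""
    retained = []
    members = [family.mother_id, family.father_id, *family.offspring_ids]
    loci = sorted({l for (i, l) in table.calls if i in members})
    for locus in loci:
        if not (table.has_full_call(family.mother_id, locus)
                and table.has_full_call(family.father_id, locus)):
            continue
        n_off = len(family.offspring_ids)
        if n_off:
            ok = sum(table.has_full_call(o, locus) for o in family.offspring_ids)
            if ok < threshold * n_off:
                continue
        retained.append(locus)
    return retained


def compatible(h1, h2):
    """Two haploid profiles agree at every mutually defined locus."""
    shared = set(h1.alleles) & set(h2.alleles)
    return all(h1.alleles[l] == h2.alleles[l] for l in shared)


def random_registry(rng, n_loci, alleles_per_locus=4):
    """Random registry over integer alleles with random (possibly empty,
    always disjoint) diagnostic sets per locus."""
    from hemiphase.model import LocusRegistry

    loci = [f"rl{i}" for i in range(n_loci)]
    l_spec, r_spec = {}, {}
    pools = {}
    for locus in loci:
        alleles = list(100 + 2 * rng.integers(0, 50, size=alleles_per_locus))
        alleles = sorted(set(int(a) for a in alleles))
        classes = rng.integers(0, 3, size=len(alleles))  # 0=nondiag,1=L,2=R
        l_spec[locus] = frozenset(a for a, c in zip(alleles, classes) if c == 1)
        r_spec[locus] = frozenset(a for a, c in zip(alleles, classes) if c == 2)
        pools[locus] = alleles
    return LocusRegistry(loci=tuple(loci), l_specific=l_spec,
                         r_specific=r_spec), pools
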