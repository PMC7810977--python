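"""Walk through the phasing of a single family, locus by locus.

Takes cross 25-2013 from the packaged dataset (an R[L] x RR cross with 20
sons) and shows how one son's diploid genotype splits into a maternal R
haplotype and the father's clonal [L] haplotype.
"""

from hemiphase import PhaseParams, datasets, phase_family

fix = datasets.table2_dataset()
fam = next(f for f in fix.families if f.cross_id == "25-2013")
pf = phase_family(fam, fix.table, fix.registry, PhaseParams())

print(f"cross {fam.cross_id}: mother {fam.mother_id}, father {fam.father_id}, "
      f"{len(fam.offspring)} offspring ({pf.cross_type.label})")
print(f"retained loci: {len(pf.retained_loci)}; dropped: {pf.dropped_loci}")

son = sorted(pf.offspring_haplotypes)[0]
mat, pat = pf.offspring_haplotypes[son]
print(f"\n{son} (paternal gamete {pf.gamete_class[son]}):")
print(f"{'locus':<12}{'offspring':<12}{'maternal':<10}{'paternal':<10}status")
for locus in pf.retained_loci:
    gt = fix.table.genotype(son, locus)
    status = mat.status[locus]
    m = mat.alleles.get(locus, "-")
    p = pat.alleles.get(locus, "-")
    print(f"{locus:<12}{f'{gt[0]}/{gt[1]}':<12}{m!s:<10}{p!s:<10}{status}")

print(f"\nfather's inferred [L] haplotype: {pf.father_L_haplotype.alleles}")

# At each phased locus the maternal and paternal alleles reassemble the
# son's observed genotype; the paternal column is constant across all 20
# sons - the clonal [L] sperm haplotype.
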