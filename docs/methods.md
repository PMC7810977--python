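# Methods

## Biological model

The pipeline models first-generation backcross (B1) families from an R-E
population system: hybrid *P. esculentus* males (RL) crossed with sexual
*P. ridibundus* females (RR), plus an RR × RR control cross.  Assumptions:

- Mothers are sexual: each egg is a recombinant haploid R genome drawn
  from the mother's two R haplotypes.
- Hybrid fathers are hemiclonal: each sperm carries one whole, unrecombined
  parental genome — the clonal [L] haplotype (shared within a hemiclone
  lineage) or the clonal [R] haplotype captured from the host species one
  generation earlier.  A father may produce [L] sperm, [R] sperm, or both
  (amphispermy).
- Sex determination is XX-XY with the male-determining factor on the L
  genome: [L]-sperm offspring are RL males, [R]-sperm offspring are RR
  females.  Phenotypic sex can still be undetermined (undeveloped gonads),
  so gamete-class evidence is always taken from offspring *taxon*, never
  sex; sex concordance is reported as a separate column.
- Rare genome leakage may place a single allele from the father's other
  genome inside an otherwise clonal gamete.

## Taxon assignment

An allele is diagnostic if the locus registry lists it as specific to one
species at that locus; shared alleles carry no evidence.  A call requires
`min_support` (default 2) loci of evidence per species: RL needs ≥ 2 L-loci
and ≥ 2 R-loci; RR needs ≥ 2 R-loci and *zero* L evidence; LL is symmetric.
Anything else is `unknown`.  The threshold of 2 exists precisely so that a
single leaked allele cannot flip a call; the flip side is that an offspring
with exactly one minority-species locus is formally `unknown`.  During
family phasing such offspring are assigned the majority gamete context
(e.g. [R] for one L-locus on an R background) with a recorded
`taxon_fallback` note, so the minority locus surfaces as a leakage
candidate instead of silencing the whole individual.

Ploidy is screened from allele counts only (> 2 alleles at a locus in
permissive parsing ⇒ possible polyploid; < 3 typed loci ⇒ insufficient);
peak-intensity dosage is outside the data model.

## Phasing engine

Per family, in order:

1. **Locus filter.** A locus is retained iff both parents have full
   diploid calls and ≥ `offspring_presence` (default 0.75) of the
   offspring do; SNP-mode sites must be biallelic within the family.
   Raising the threshold can only shrink the retained set.  The 0.95
   presence value used by some upstream SNP-calling workflows is available
   as a parameter but is not the default, since 0.75 is the filter that
   defines the phased dataset.  The filter is applied per family; a
   union-across-families mode was considered and rejected as it lets a
   badly-typed family poison loci for well-typed ones.
2. **Null-allele screen.** An offspring apparently homozygous for an
   allele that exactly one parent carries is the signature of a null
   (non-amplifying) allele in the other parent; such loci are dropped
   family-wide (`null_allele`).  This is deliberately conservative: a
   single masking event discards the locus rather than risking wrong
   haplotypes.
3. **Per-offspring, per-locus enumeration.** For offspring genotype
   {a, b}, the candidate assignments (maternal, paternal) are (a, b) and
   (b, a) (one candidate if homozygous).  An assignment survives iff the
   maternal allele occurs in the mother's genotype, the paternal allele in
   the father's, the maternal allele is not L-specific (the mother is RR),
   and the paternal allele's species class matches the gamete class ([L]
   sperm cannot carry an R-specific allele and vice versa).  If two
   assignments survive and exactly one paternal candidate is absent from
   the mother, father-exclusivity decides — the generalization of the
   species-specificity rule to non-diagnostic alleles.  Exactly one
   survivor ⇒ `phased`; several ⇒ `ambiguous`; none ⇒ `conflict`.
   Half-calls (one observed allele) are treated as missing for phasing.
   No imputation is performed anywhere: Mendelian imputation is exactly
   what non-Mendelian data must not be subjected to.
4. **Conflicts are data, not errors.** A conflict that would phase once
   the gamete-species constraint is relaxed is a `leak_candidate` (the
   interesting case); an offspring allele present in neither parent is an
   `unattributable_allele` (mutation or genotyping-error candidate).
   Mutation vs. leakage is not auto-resolved; both explanations stay on
   the record.
5. **Father haplotype consensus.** Within one gamete class the clonal
   haplotype must be constant, so the father's [L] ([R]) haplotype is the
   strict-majority consensus of phased paternal alleles across RL (RR)
   offspring; any phased deviation becomes a `paternal_deviation`
   conflict.  Where the [L] allele is known and the father is
   heterozygous, his [R] allele is filled in as the complement.
   Ties yield `ambiguous`, never an arbitrary pick.

The control RR × RR family runs the same enumeration without the
species-class constraint (plain Mendelian trio logic); loci where the
parents share genotypes come out `ambiguous`, as they must.

Iteration order is fixed everywhere (families by cross id, loci by
registry order, offspring by id), so outputs are reproducible
byte-for-byte.

## Clonality analytics

**MLG clustering.**  A haplotype's raw MLG is its allele string in
registry locus order with a fixed missing token that sorts after all
alleles.  Haplotypes with > `max_missing` (default 0.65) missing fraction
are removed.  The rest, sorted by (missing fraction, id), join the first
cluster whose representative they are compatible with (equal at every
mutually defined locus) or found a new one; representatives absorb member
alleles on join, keeping members pairwise compatible.  Compatibility is
not transitive, so a haplotype compatible with several clusters is
assigned to the first and flagged — a deterministic greedy rule chosen
over any probabilistic model, mirroring "filtering out variation caused by
missing data".  Both raw-string counts and merged cluster counts are
reported, because raw MLG counts inflate purely through missingness.

**Gamete profiles.**  Per father, the union over his crosses of the
gamete classes evidenced by offspring taxa; amphispermic ⇔ both classes
present.

**Leakage detection.**  `leak_candidate` conflicts plus
`paternal_deviation` conflicts whose deviant allele occurs in the
father's other genome.  With clean genotypes this detects [L]-gamete
leaks exactly (a leaked R allele makes both offspring alleles R-class, so
no valid assignment can exist); an [R]-gamete offspring hit by two or
more independent leaks at L-diagnostic loci would satisfy the RL taxon
rule and be mis-contexted, a confound inherent to taxon-based gamete
classing and noted as a limitation.

**Two-point linkage.**  For one parent's gametes, r̂ per locus pair is
the phase-minimizing backcross count min(n₁₁+n₂₂, n₁₂+n₂₁)/n over doubly
typed gametes, restricted to the two most frequent alleles per locus
(ties broken by allele order).  Only loci heterozygous in the parent are
informative, so the parent's genotypes can be supplied; otherwise
heterozygosity is inferred from the gametes.  Degenerate cases: a single
two-locus class gives r̂ = 0; classes differing at one locus only count
the minority class as recombinant; pairs with < 2 usable gametes are
undefined (NaN).  With two complementary gametes the minimizing pairing
gives r̂ = 0 — the phase-ambiguity floor.  This is deliberately not a
likelihood map: the claim under test is complete linkage vs.
recombination, nothing finer.

## Simulator

`simulate_system` draws, from one seed: hemiclone [L] founder haplotypes
(pairwise distinct when the pool allows), per-father [R] haplotypes and
gamete profiles, maternal R haplotype pairs, a cross layout
(`n_fathers` × 2–3 of `n_mothers`, optional control male crossed with all
females), and per cross the offspring: clonal paternal gamete (verbatim
copy, then per-locus leak substitutions from the father's other genome at
`leak_rate` — a substitution model chosen as the smallest mechanism
consistent with single-allele leakage observations; whole-arm exchange is
deliberately not modeled), recombinant maternal gamete (linkage groups
with per-interval recombination fractions; default independent
assortment), sex from the gamete class (control sperm carry an unobserved
Y marker to 50 % of offspring).  Null alleles are drawn per (parent,
locus, haplotype) and rendered as apparent homozygotes downstream;
missingness is applied last.  Per-family substreams are derived by CRC32
hashing of the cross id, so results do not depend on iteration order and
replicates under one seed are byte-identical.

`study_like_config` mirrors the emulated experiment: the packaged
15-locus registry, 16 fathers, 9 mothers, 2–3 females per male, control
included, profile probabilities 9:1:2/12 ([L]-only : [R]-only :
amphispermic — the observed tally among the 12 fathers with surviving
progeny), p([R] sperm | amphispermic) = 0.5, one hemiclone, 2–25
offspring per cross (uniform; centers total progeny near the ~520
juveniles of the emulated design).  Where the registry lists no
diagnostic allele for one species at a locus, that genome receives
shared non-diagnostic filler alleles so the locus amplifies in both
species and stays phaseable through father-exclusivity; true
non-amplification is available through `null_allele_rate` or explicit
NULL pool entries.  Microsatellite pool frequencies are uniform — allele
lists, not frequencies, are what such registries provide.

What the simulator does *not* emulate: genotyping error and allele
dropout beyond nulls, stutter/size-calling noise, triploids,
multi-generation dynamics, linkage between the sex determiner and typed
loci, and real allele-frequency spectra.  Green tests therefore show the
*inference logic* is correct under the stated model, not that real
datasets are free of artifacts the model excludes.

## Packaged fixtures

The registry fixture is the published 15-locus diagnostic table (71
alleles: 8 lessonae-specific, 63 ridibundus-specific).  The cross-table
fixture reconstructs the published 17 crosses (12 hybrid fathers, 278
offspring: 67 RR ♀ + 207 RL ♂ + 4 of undetermined sex) with deterministic
taxon-consistent genotypes, including the single leakage case (son JUV19
of cross 60-2013, father's R-specific Re1Caga10 allele inside an [L]
gamete).  Parental allele picks and mother-to-cross assignment are
arbitrary-but-deterministic: the source table reports progeny counts and
allele pools, not per-individual genotypes, so the fixture reproduces
structure and tallies, not real allele calls.  One typographically
ambiguous row (cross 59-2013) follows the accompanying text: three RR
progeny, two female and one of undetermined sex.

## Problem sizes and tolerances

The test suite and acceptance script use: 1,000 random families (≤ 6
offspring, ≤ 10 loci) for oracle equivalence; the full study-shaped
simulation (~40 hybrid crosses, ~700–900 offspring) for noiseless
recovery; ~2,000 meioses at leak rate 0.01 for leakage precision/recall;
n = 500 gametes for the linkage contrast, with stochastic checks at 3
standard errors (or central 99 % binomial bands); exact equality
everywhere determinism or zero-noise recovery is claimed.
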