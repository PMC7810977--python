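"""Downstream analytics on phased haplotypes.

Multilocus genotypes (MLGs), gamete-profile classification of each hybrid
father ([L]-only, [R]-only, or amphispermic), genome-leakage event
extraction, a two-point recombination-fraction contrast (clonal sperm
show complete linkage, r̂ = 0; recombinant eggs do not), and per-cross
progeny summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    Allele,
    Family,
    LocusRegistry,
    MISSING_TOKEN,
    PhasedHaplotype,
    allele_sort_key,
)
from .phasing import PhasedFamily
from .taxon import TaxonCall


# ---------------------------------------------------------------------------
# MLG clustering

def mlg_key(haplotype: PhasedHaplotype, registry: LocusRegistry) -> str:
    """Canonical raw MLG string: alleles in registry locus order joined by
    "|", with a fixed missing token that sorts after any allele."""
    parts = []
    for locus in registry.loci:
        if haplotype.status.get(locus) == "phased":
            parts.append(str(haplotype.alleles[locus]))
        else:
            parts.append(MISSING_TOKEN)
    return "|".join(parts)


@dataclass
class MLGCluster:
    cluster_id: int
    members: list[PhasedHaplotype]
    representative: dict[str, Allele]
    n_distinct_raw: int = 0
    ambiguous_members: list[str] = field(default_factory=list)


def _compatible(hap: PhasedHaplotype, rep: dict[str, Allele]) -> bool:
    return all(rep.get(l) is None or rep[l] == a
               for l, a in hap.alleles.items() if hap.status.get(l) == "phased")


def cluster_mlgs(haplotypes: Sequence[PhasedHaplotype],
                 registry: LocusRegistry,
                 max_missing: float = 0.65) -> list[MLGCluster]:
    """Greedy missing-data-tolerant MLG clustering.

    Haplotypes with more than ``max_missing`` missing fraction are removed
    first (the paper-derived 65% rule).  The rest are sorted by (missing
    fraction ascending, individual id, origin) and each joins the first
    cluster whose representative it is compatible with — equal at every
    mutually defined locus — otherwise it founds a new cluster.
    Representatives absorb member alleles as they join, so all members of
    a cluster are pairwise compatible.  Compatibility is not transitive:
    a haplotype compatible with several representatives is assigned to
    the first and flagged in ``ambiguous_members``.
    """
    loci = registry.loci
    kept = [h for h in haplotypes if h.missing_fraction(loci) <= max_missing]
    if not kept:
        raise ValueError("all haplotypes exceed the missing-data ceiling")
    kept.sort(key=lambda h: (h.missing_fraction(loci), h.individual_id, h.origin))
    clusters: list[MLGCluster] = []
    for hap in kept:
        homes = [c for c in clusters if _compatible(hap, c.representative)]
        if homes:
            home = homes[0]
            home.members.append(hap)
            for l, a in hap.alleles.items():
                if hap.status.get(l) == "phased":
                    home.representative.setdefault(l, a)
            if len(homes) > 1:
                home.ambiguous_members.append(hap.individual_id)
        else:
            clusters.append(MLGCluster(
                cluster_id=len(clusters), members=[hap],
                representative={l: a for l, a in hap.alleles.items()
                                if hap.status.get(l) == "phased"}))
    for c in clusters:
        c.n_distinct_raw = len({mlg_key(h, registry) for h in c.members})
    return clusters


# ---------------------------------------------------------------------------
# Gamete profiles

@dataclass(frozen=True)
class GameteProfile:
    father_id: str
    classes: frozenset  # subset of {"[L]", "[R]"}
    counts: Mapping[str, int]

    @property
    def amphispermic(self) -> bool:
        return len(self.classes) == 2


def classify_gamete_profile(father_id: str,
                            phased_families: Sequence[PhasedFamily]
                            ) -> GameteProfile:
    """Union of paternal gamete classes over all of one father's crosses.

    An RL offspring is evidence of [L] sperm, an RR offspring of a hybrid
    father is evidence of [R] sperm; a father producing both is
    amphispermic.
    """
    counts: Counter = Counter()
    for pf in phased_families:
        if pf.family.father_id != father_id:
            continue
        for off, gclass in pf.gamete_class.items():
            if gclass is not None and off in pf.offspring_haplotypes:
                counts[gclass] += 1
    if not counts:
        raise ValueError(f"father {father_id}: no phased offspring")
    return GameteProfile(father_id=father_id,
                         classes=frozenset(counts),
                         counts=dict(counts))


# ---------------------------------------------------------------------------
# Leakage

@dataclass(frozen=True)
class LeakageEvent:
    offspring_id: str
    locus: str
    expected_genome: str       # "[L]" or "[R]"
    observed_allele: Allele
    observed_class: str        # L_specific | R_specific | non_diagnostic


def _class_label(registry: LocusRegistry, locus: str, allele) -> str:
    c = registry.classify(locus, allele)
    return {"L": "L_specific", "R": "R_specific"}.get(c, "non_diagnostic")


def detect_leakage(phased_family: PhasedFamily,
                   registry: LocusRegistry) -> list[LeakageEvent]:
    """Extract genome-leakage events from a phased family's conflicts.

    Two signatures count: (a) a locus that only phases when the paternal
    allele's species class contradicts the gamete class (e.g. an
    R-specific allele inside an otherwise clonal [L] sperm); (b) a phased
    paternal allele deviating from the clonal class consensus while being
    present in the father's genotype — i.e. explainable as transmission
    of the father's other genome's allele.
    """
    events: list[LeakageEvent] = []
    for conflict in phased_family.conflicts:
        if conflict.locus is None or conflict.expected_genome is None:
            continue
        if conflict.kind == "leak_candidate":
            events.append(LeakageEvent(
                offspring_id=conflict.offspring_id, locus=conflict.locus,
                expected_genome=conflict.expected_genome,
                observed_allele=conflict.allele,
                observed_class=_class_label(registry, conflict.locus,
                                            conflict.allele)))
        elif conflict.kind == "paternal_deviation":
            other = (phased_family.father_R_haplotype
                     if conflict.expected_genome == "[L]"
                     else phased_family.father_L_haplotype)
            explainable = (other is not None
                           and other.alleles.get(conflict.locus) == conflict.allele)
            if explainable:
                events.append(LeakageEvent(
                    offspring_id=conflict.offspring_id, locus=conflict.locus,
                    expected_genome=conflict.expected_genome,
                    observed_allele=conflict.allele,
                    observed_class=_class_label(registry, conflict.locus,
                                                conflict.allele)))
    return events


# ---------------------------------------------------------------------------
# Two-point linkage

Gamete = Union[PhasedHaplotype, Mapping[str, Allele]]


def _gamete_allele(g: Gamete, locus: str):
    if isinstance(g, PhasedHaplotype):
        return g.alleles.get(locus) if g.status.get(locus) == "phased" else None
    return g.get(locus)


def two_point_rf(gametes: Sequence[Gamete],
                 loci: Sequence[str],
                 parent_genotypes: Optional[Mapping[str, tuple]] = None,
                 min_gametes: int = 2) -> pd.DataFrame:
    """Pairwise two-point recombination fractions among one parent's
    transmitted gametes.

    For each locus pair the two-locus gamete classes are counted and the
    phase pairing minimizing recombinants is chosen, so r̂ ∈ [0, 0.5]
    (backcross-style counting; with only two gametes complementary at two
    loci the minimizing pairing gives r̂ = 0).  A locus at which the
    parent is homozygous is uninformative and its column is NaN; when
    ``parent_genotypes`` is not given, heterozygosity is inferred from
    the gametes themselves, except that a single observed allele with a
    known-het parent still yields r̂ = 0 (the clonal case).  Pairs with
    fewer than ``min_gametes`` doubly-typed gametes are NaN.
    """
    loci = list(loci)
    n = len(loci)
    rf = pd.DataFrame(np.full((n, n), np.nan), index=loci, columns=loci)

    def informative(locus):
        if parent_genotypes is not None:
            gt = parent_genotypes.get(locus)
            return gt is not None and len(set(gt)) == 2
        return len({a for g in gametes
                    if (a := _gamete_allele(g, locus)) is not None}) >= 2

    info = {l: informative(l) for l in loci}
    for i, li in enumerate(loci):
        if info[li]:
            rf.loc[li, li] = 0.0
        for lj in loci[i + 1:]:
            if not (info[li] and info[lj]):
                continue
            pairs = [(a, b) for g in gametes
                     if (a := _gamete_allele(g, li)) is not None
                     and (b := _gamete_allele(g, lj)) is not None]
            if len(pairs) < min_gametes:
                continue
            counts = Counter(pairs)
            a_alleles = _top_two(Counter(a for a, _ in pairs))
            b_alleles = _top_two(Counter(b for _, b in pairs))
            used = [(a, b) for (a, b) in pairs
                    if a in a_alleles and b in b_alleles]
            if len(used) < min_gametes:
                continue
            counts = Counter(used)
            if len(a_alleles) == 1 and len(b_alleles) == 1:
                r = 0.0  # a single two-locus class: no recombinants visible
            elif len(a_alleles) == 1 or len(b_alleles) == 1:
                # classes differ at one locus only; the minority class is
                # recombinant under the minimizing phase pairing
                r = min(counts.values()) / len(used) if len(counts) > 1 else 0.0
            else:
                a1, a2 = a_alleles
                b1, b2 = b_alleles
                phase1 = counts[(a1, b1)] + counts[(a2, b2)]
                phase2 = counts[(a1, b2)] + counts[(a2, b1)]
                r = min(phase1, phase2) / len(used)
            rf.loc[li, lj] = rf.loc[lj, li] = r
    return rf


def _top_two(counter: Counter) -> list:
    ranked = sorted(counter.items(),
                    key=lambda kv: (-kv[1], allele_sort_key(kv[0])))
    return [a for a, _ in ranked[:2]]


# ---------------------------------------------------------------------------
# Summaries

def summarize_families(families: Sequence[Family],
                       taxa: Mapping[str, Union[str, TaxonCall]],
                       gamete_profiles: Optional[Mapping[str, GameteProfile]] = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Per-cross progeny table (taxon × sex cells) plus study-wide tallies.

    Aggregates report the totals the crossing design is read by: RR
    daughters returned to the sexual host population, sexed offspring
    (known taxon, determined sex), and offspring of undetermined sex.
    The cell sum always equals the number of offspring with a known
    taxon.
    """
    def taxon_of(off):
        t = taxa.get(off)
        return t.taxon if isinstance(t, TaxonCall) else t

    rows = []
    for fam in sorted(families, key=lambda f: f.cross_id):
        cells = Counter()
        for off, sex in fam.offspring:
            t = taxon_of(off)
            if t in ("RR", "RL"):
                cells[(t, sex)] += 1
        row = {"cross_id": fam.cross_id, "father_id": fam.father_id,
               "mother_id": fam.mother_id}
        for t in ("RR", "RL"):
            for sex in ("male", "female", "undetermined"):
                row[f"{t}_{sex}"] = cells[(t, sex)]
        if gamete_profiles and fam.father_id in gamete_profiles:
            prof = gamete_profiles[fam.father_id]
            row["father_gametes"] = ",".join(sorted(prof.classes))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {"n_crosses": 0, "rr_daughters": 0, "sexed_offspring": 0,
                    "undetermined_sex": 0, "known_taxon": 0,
                    "sex_concordant": 0, "sex_discordant": 0}
    cell_cols = [c for c in df.columns if c.startswith(("RR_", "RL_"))]
    concordant = int(df["RR_female"].sum() + df["RL_male"].sum())
    discordant = int(df["RR_male"].sum() + df["RL_female"].sum())
    agg = {
        "n_crosses": int(len(df)),
        "rr_daughters": int(df["RR_female"].sum()),
        "sexed_offspring": int(df[[c for c in cell_cols
                                   if not c.endswith("undetermined")]].sum().sum()),
        "undetermined_sex": int(df["RR_undetermined"].sum()
                                + df["RL_undetermined"].sum()),
        "known_taxon": int(df[cell_cols].sum().sum()),
        # XX-XY with Y on the [L] genome predicts RL ⇒ male, RR ⇒ female
        "sex_concordant": concordant,
        "sex_discordant": discordant,
    }
    return df, agg
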