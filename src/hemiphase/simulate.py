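"""Synthetic hybridogenetic cross generator with known ground truth.

Emulates the study design this package analyzes: hybrid (RL) males, each
carrying one clonal lessonae haplotype ([L], shared within a hemiclone
and bearing the male-determining factor) and one ridibundus haplotype
([R]) captured from the host species a generation ago, are crossed with
sexual RR females.  Each father transmits whole, non-recombined haploid
genomes: [L] sperm yield RL sons, [R] sperm yield RR daughters, and an
amphispermic father produces both.  Mothers transmit recombinant R
gametes.  Optional imperfections: rare genome leakage (a single-locus
substitution from the father's other genome inside an otherwise clonal
gamete), null alleles (a silent parental allele creating apparent
homozygotes downstream), and missing data.  Everything is driven by one
seed; per-family substreams are derived by stable hashing of the cross
id so outputs do not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .model import Allele, Family, GenotypeTable, LocusRegistry

#: sentinel for a non-amplifying (null) allele inside a true haplotype
NULL = "<null>"

LinkageGroups = list[tuple[list[str], list[float]]]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated crossing experiment.

    Defaults mirror the emulated design: 16 hybrid fathers each crossed
    with 2–3 of 9 RR females, an optional RR control male crossed with
    every female, and father gamete profiles drawn 9:1:2
    ([L]-only : [R]-only : amphispermic), the tally observed among the 12
    fathers with surviving progeny.
    """

    pools: Mapping[str, Mapping[str, Sequence[Allele]]]  # locus -> {"L": [...], "R": [...]}
    registry: Optional[LocusRegistry] = None
    n_fathers: int = 16
    n_mothers: int = 9
    females_per_father: tuple[int, int] = (2, 3)
    offspring_per_cross: tuple[int, int] = (2, 25)
    profile_probs: Mapping[str, float] = field(
        default_factory=lambda: {"L": 9 / 12, "R": 1 / 12, "LR": 2 / 12})
    p_r_sperm: float = 0.5
    n_hemiclones: int = 1
    linkage_groups: Optional[LinkageGroups] = None  # None = independent assortment
    leak_rate: float = 0.0
    null_allele_rate: float = 0.0
    missing_rate: float = 0.0
    include_control: bool = False
    seed: int = 0

    def __post_init__(self):
        total = sum(self.profile_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.profile_probs.values()):
            raise ValueError("profile probabilities must be in [0,1] and sum to 1")
        for rate in (self.leak_rate, self.null_allele_rate, self.missing_rate,
                     self.p_r_sperm):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        if self.linkage_groups:
            for _, rfs in self.linkage_groups:
                if any(not 0.0 <= r <= 0.5 for r in rfs):
                    raise ValueError("recombination fractions must lie in [0, 0.5]")

    @property
    def loci(self) -> tuple[str, ...]:
        if self.registry is not None:
            return self.registry.loci
        return tuple(self.pools)

    def derived_registry(self) -> LocusRegistry:
        if self.registry is not None:
            return self.registry
        loci = tuple(self.pools)
        l_spec, r_spec = {}, {}
        for locus in loci:
            lp = set(self.pools[locus]["L"]) - {NULL}
            rp = set(self.pools[locus]["R"]) - {NULL}
            l_spec[locus] = frozenset(lp - rp)
            r_spec[locus] = frozenset(rp - lp)
        return LocusRegistry(loci=loci, l_specific=l_spec, r_specific=r_spec)


@dataclass(frozen=True)
class LeakTruth:
    offspring_id: str
    locus: str
    genome: str            # gamete class carrying the leak, "[L]" or "[R]"
    original_allele: Allele
    substituted_allele: Allele


@dataclass(frozen=True)
class NullTruth:
    individual_id: str
    locus: str
    haplotype: str         # which of the parent's haplotypes is silent
    allele: Allele         # the masked allele value


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset: true haplotypes, gamete class
    and sex per offspring, injected leak and null events, hemiclone ids."""

    haplotypes: dict[str, dict[str, dict[str, Allele]]]
    gamete_class: dict[str, str]        # offspring -> "[L]" | "[R]" | "R"
    sex: dict[str, str]
    parents: dict[str, tuple[str, str]]  # offspring -> (mother, father)
    father_profile: dict[str, frozenset]
    hemiclone: dict[str, int]
    leak_events: list[LeakTruth] = field(default_factory=list)
    null_events: list[NullTruth] = field(default_factory=list)
    #: offspring -> {"maternal": {locus: parental slot}, "paternal": {...}};
    #: records which parental haplotype each inherited allele came from
    inheritance: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)

    def realized_classes(self, father_id: str) -> frozenset:
        return frozenset(g for off, g in self.gamete_class.items()
                         if self.parents[off][1] == father_id)


class SimResult(NamedTuple):
    table: GenotypeTable
    families: list[Family]
    registry: LocusRegistry
    truth: SimTruth


def _substream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _draw_haplotype(pools, genome: str, loci, rng) -> dict[str, Allele]:
    hap = {}
    for locus in loci:
        pool = list(pools[locus][genome])
        hap[locus] = pool[rng.integers(len(pool))]
    return hap


def draw_recombinant_gamete(hap_pair, groups: LinkageGroups, rng
                            ) -> tuple[dict[str, Allele], dict[str, int]]:
    """One recombinant gamete from a diploid pair of haplotypes.

    Within each linkage group the contributing haplotype switches between
    adjacent loci with the configured recombination fraction; groups
    assort independently.  Returns (alleles, source haplotype per locus).
    """
    alleles: dict[str, Allele] = {}
    source: dict[str, int] = {}
    for loci, rfs in groups:
        h = int(rng.integers(2))
        for k, locus in enumerate(loci):
            if k > 0 and rng.random() < rfs[k - 1]:
                h = 1 - h
            alleles[locus] = hap_pair[h][locus]
            source[locus] = h
    return alleles, source


def draw_recombinant_gametes(hap_pair, groups: LinkageGroups, n: int,
                             rng) -> list[dict[str, Allele]]:
    """Convenience: n independent recombinant gametes (alleles only)."""
    return [draw_recombinant_gamete(hap_pair, groups, rng)[0] for _ in range(n)]


def _independent_groups(loci) -> LinkageGroups:
    return [([l], []) for l in loci]


def simulate_system(config: SimConfig) -> SimResult:
    """Generate one full crossing experiment with ground truth.

    Offspring genotype = maternal gamete ∪ paternal gamete, before null
    masking and missingness; a clonal paternal gamete is a verbatim copy
    of the father's haplotype except at injected leak loci.  Fully
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    registry = config.derived_registry()
    loci = list(registry.loci)
    groups = config.linkage_groups or _independent_groups(loci)
    truth = SimTruth(haplotypes={}, gamete_class={}, sex={}, parents={},
                     father_profile={}, hemiclone={})

    # hemiclonal [L] founder haplotypes, pairwise distinct where possible
    clones: list[dict[str, Allele]] = []
    for _ in range(config.n_hemiclones):
        for _attempt in range(100):
            hap = _draw_haplotype(config.pools, "L", loci, rng)
            if hap not in clones:
                break
        clones.append(hap)

    profile_names = sorted(config.profile_probs)
    profile_p = np.array([config.profile_probs[k] for k in profile_names])

    fathers = [f"M{i + 1}" for i in range(config.n_fathers)]
    for i, fid in enumerate(fathers):
        clone_id = int(rng.integers(config.n_hemiclones))
        truth.hemiclone[fid] = clone_id
        truth.haplotypes[fid] = {
            "L": dict(clones[clone_id]),
            "R": _draw_haplotype(config.pools, "R", loci, rng),
        }
        prof = profile_names[int(rng.choice(len(profile_names), p=profile_p))]
        truth.father_profile[fid] = frozenset(
            {"L": {"[L]"}, "R": {"[R]"}, "LR": {"[L]", "[R]"}}[prof])

    mothers = [f"F{j + 1}" for j in range(config.n_mothers)]
    for mid in mothers:
        truth.haplotypes[mid] = {
            "R_a": _draw_haplotype(config.pools, "R", loci, rng),
            "R_b": _draw_haplotype(config.pools, "R", loci, rng),
        }
    control_id = None
    if config.include_control:
        control_id = "CTRL-M"
        truth.haplotypes[control_id] = {
            "R_a": _draw_haplotype(config.pools, "R", loci, rng),
            "R_b": _draw_haplotype(config.pools, "R", loci, rng),
        }

    # null alleles: drawn once per (parent, locus, haplotype slot)
    null_slots: set[tuple[str, str, str]] = set()
    if config.null_allele_rate > 0:
        for pid in [*fathers, *mothers, *([control_id] if control_id else [])]:
            for locus in loci:
                if rng.random() < config.null_allele_rate:
                    slot = list(truth.haplotypes[pid])[int(rng.integers(2))]
                    null_slots.add((pid, locus, slot))
                    truth.null_events.append(NullTruth(
                        individual_id=pid, locus=locus, haplotype=slot,
                        allele=truth.haplotypes[pid][slot][locus]))

    # cross layout
    crosses: list[tuple[str, str, str]] = []  # (cross_id, mother, father)
    lo, hi = config.females_per_father
    for i, fid in enumerate(fathers):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(config.n_mothers, size=min(k, config.n_mothers),
                            replace=False)
        for j in sorted(int(c) for c in chosen):
            crosses.append((f"X{len(crosses) + 1:03d}", mothers[j], fid))
    if control_id:
        for mid in mothers:
            crosses.append((f"X{len(crosses) + 1:03d}", mid, control_id))

    families: list[Family] = []
    off_lo, off_hi = config.offspring_per_cross
    for cross_id, mid, fid in crosses:
        sub = _substream(config.seed, cross_id)
        n_off = int(sub.integers(off_lo, off_hi + 1))
        offspring: list[tuple[str, str]] = []
        hybrid = fid != control_id
        prof = truth.father_profile.get(fid, frozenset())
        for k in range(n_off):
            oid = f"{cross_id}_J{k + 1:03d}"
            if hybrid:
                if prof == frozenset({"[L]"}):
                    gclass = "[L]"
                elif prof == frozenset({"[R]"}):
                    gclass = "[R]"
                else:
                    gclass = "[R]" if sub.random() < config.p_r_sperm else "[L]"
                genome = "L" if gclass == "[L]" else "R"
                pat_alleles = dict(truth.haplotypes[fid][genome])
                pat_source = {l: genome for l in loci}
                other = "R" if genome == "L" else "L"
                for locus in loci:
                    if config.leak_rate > 0 and sub.random() < config.leak_rate:
                        repl = truth.haplotypes[fid][other][locus]
                        if repl != pat_alleles[locus]:
                            truth.leak_events.append(LeakTruth(
                                offspring_id=oid, locus=locus, genome=gclass,
                                original_allele=pat_alleles[locus],
                                substituted_allele=repl))
                            pat_alleles[locus] = repl
                            pat_source[locus] = other
                sex = "male" if gclass == "[L]" else "female"
            else:
                gclass = "R"
                pair = (truth.haplotypes[fid]["R_a"], truth.haplotypes[fid]["R_b"])
                pat_alleles, src = draw_recombinant_gamete(pair, groups, sub)
                pat_source = {l: ("R_a", "R_b")[src[l]] for l in loci}
                # unobserved Y marker segregates to half the control sperm
                sex = "male" if sub.random() < 0.5 else "female"
            mat_pair = (truth.haplotypes[mid]["R_a"], truth.haplotypes[mid]["R_b"])
            mat_alleles, msrc = draw_recombinant_gamete(mat_pair, groups, sub)
            mat_source = {l: ("R_a", "R_b")[msrc[l]] for l in loci}

            truth.haplotypes[oid] = {"maternal": mat_alleles,
                                     "paternal": pat_alleles}
            truth.gamete_class[oid] = gclass
            truth.sex[oid] = sex
            truth.parents[oid] = (mid, fid)
            offspring.append((oid, sex))
            truth.inheritance[oid] = {"maternal": mat_source,
                                      "paternal": pat_source}
        families.append(Family(cross_id=cross_id, mother_id=mid, father_id=fid,
                               offspring=tuple(offspring)))

    table = _render_observed(config, truth, families, loci, null_slots)
    return SimResult(table=table, families=families, registry=registry,
                     truth=truth)


def _render_observed(config, truth, families, loci, null_slots) -> GenotypeTable:
    table = GenotypeTable(marker_mode="microsatellite")
    miss_rng = _substream(config.seed, "missingness")
    parent_ids = sorted({f.mother_id for f in families}
                        | {f.father_id for f in families})
    for pid in parent_ids:
        haps = truth.haplotypes[pid]
        for locus in loci:
            visible = [haps[s][locus] for s in sorted(haps)
                       if (pid, locus, s) not in null_slots
                       and haps[s][locus] != NULL]
            _set_observed(table, pid, locus, visible)
    for fam in sorted(families, key=lambda f: f.cross_id):
        for oid in fam.offspring_ids:
            haps = truth.haplotypes[oid]
            sources = truth.inheritance[oid]
            mid, fid = truth.parents[oid]
            for locus in loci:
                visible = []
                if ((mid, locus, sources["maternal"][locus]) not in null_slots
                        and haps["maternal"][locus] != NULL):
                    visible.append(haps["maternal"][locus])
                if ((fid, locus, sources["paternal"][locus]) not in null_slots
                        and haps["paternal"][locus] != NULL):
                    visible.append(haps["paternal"][locus])
                _set_observed(table, oid, locus, visible)
    if config.missing_rate > 0:
        for ind in sorted(table.individuals):
            for locus in loci:
                if miss_rng.random() < config.missing_rate:
                    table.calls[(ind, locus)] = (None, None)
    return table


def _set_observed(table, ind, locus, visible):
    if not visible:
        table.calls[(ind, locus)] = (None, None)
    elif len(visible) == 1:
        # a silent (null) partner allele leaves an apparent homozygote
        table.set_call(ind, locus, [visible[0], visible[0]])
    else:
        table.set_call(ind, locus, visible)


def diagnostic_pools(n_loci: int = 10, n_alleles: int = 4,
                     l_base: int = 100, r_base: int = 200
                     ) -> dict[str, dict[str, list[int]]]:
    """Fully species-diagnostic microsatellite pools (disjoint allele
    ranges), convenient for simulations where every locus should be
    informative about genome of origin."""
    pools = {}
    for i in range(n_loci):
        locus = f"L{i + 1:02d}"
        pools[locus] = {
            "L": [l_base + 10 * i + 2 * j for j in range(n_alleles)],
            "R": [r_base + 10 * i + 2 * j for j in range(n_alleles)],
        }
    return pools


def study_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Configuration shaped like the emulated crossing experiment: the
    15-locus registry of the packaged locus table, 16 hybrid fathers ×
    2–3 of 9 RR females plus an RR control male, and profile
    probabilities matching the observed 9:1:2 profile tally.  Loci at
    which one species has no diagnostic allele are filled with shared,
    non-diagnostic alleles so both genomes amplify."""
    from .datasets import table1_pools, table1_registry

    defaults = dict(
        pools=table1_pools(),
        registry=table1_registry(),
        n_fathers=16,
        n_mothers=9,
        females_per_father=(2, 3),
        offspring_per_cross=(2, 25),
        profile_probs={"L": 9 / 12, "R": 1 / 12, "LR": 2 / 12},
        p_r_sperm=0.5,
        n_hemiclones=1,
        include_control=True,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
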