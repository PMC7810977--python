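"""Shared data model for the hemiclonal-cross pipeline.

Alleles are opaque tokens: microsatellite alleles are fragment lengths in
base pairs (``int``), SNP alleles are base symbols (``str``).  ``None``
marks a missing allele slot, so a half-called genotype is stored as
``(allele, None)`` and a fully missing call as ``(None, None)`` — an
apparent homozygote ``(a, a)`` is never silently equal to a missing call.

The registry records, per locus, which alleles are diagnostic for the
*P. lessonae* (L) genome and which for the *P. ridibundus* (R) genome;
everything else is non-diagnostic (shared or unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

Allele = Union[int, str]

#: token used for a missing allele in canonical MLG strings; "~" sorts
#: after digits and letters in ASCII so missing always sorts last.
MISSING_TOKEN = "~"

SEXES = ("male", "female", "undetermined")
MICROSAT = "microsatellite"
SNP = "snp"

ORIGINS = ("maternal_R", "paternal_L", "paternal_R")
STATUSES = ("phased", "ambiguous", "conflict", "missing")


def allele_sort_key(a: Optional[Allele]):
    """Stable sort key across int (bp) and str (base) alleles; None last."""
    if a is None:
        return (2, "")
    if isinstance(a, str):
        return (1, a)
    return (0, f"{a:012d}")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class LocusRegistry:
    """Ordered locus table with per-locus species-diagnostic allele sets.

    Invariants enforced at construction: locus names unique, at least one
    locus, and at every locus the L-specific and R-specific sets are
    disjoint (an allele cannot be diagnostic for both species at the same
    locus; the same bp value may of course be diagnostic for different
    species at *different* loci).
    """

    loci: tuple[str, ...]
    l_specific: Mapping[str, frozenset]
    r_specific: Mapping[str, frozenset]

    def __post_init__(self):
        if not self.loci:
            raise RegistryError("registry needs at least one locus")
        if len(set(self.loci)) != len(self.loci):
            dupes = sorted({l for l in self.loci if list(self.loci).count(l) > 1})
            raise RegistryError(f"duplicate locus name(s): {dupes}")
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(
            self, "l_specific",
            {l: frozenset(self.l_specific.get(l, frozenset())) for l in self.loci},
        )
        object.__setattr__(
            self, "r_specific",
            {l: frozenset(self.r_specific.get(l, frozenset())) for l in self.loci},
        )
        for locus in self.loci:
            both = self.l_specific[locus] & self.r_specific[locus]
            if both:
                raise RegistryError(
                    f"locus {locus}: allele(s) {sorted(both, key=allele_sort_key)} "
                    "listed as both lessonae- and ridibundus-specific"
                )

    def __contains__(self, locus: str) -> bool:
        return locus in self.l_specific

    def classify(self, locus: str, allele: Optional[Allele]) -> Optional[str]:
        """Return "L", "R", or None (non-diagnostic / missing / unknown)."""
        if allele is None:
            return None
        if allele in self.l_specific.get(locus, ()):
            return "L"
        if allele in self.r_specific.get(locus, ()):
            return "R"
        return None

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    @classmethod
    def from_spec(cls, spec: Mapping[str, tuple[Iterable, Iterable]],
                  order: Optional[Iterable[str]] = None) -> "LocusRegistry":
        loci = tuple(order) if order is not None else tuple(spec)
        return cls(
            loci=loci,
            l_specific={l: frozenset(spec[l][0]) for l in loci},
            r_specific={l: frozenset(spec[l][1]) for l in loci},
        )


Call = tuple[Optional[Allele], Optional[Allele]]


def _canon_call(alleles: Iterable[Optional[Allele]]) -> Call:
    obs = sorted((a for a in alleles if a is not None), key=allele_sort_key)
    if len(obs) > 2:
        raise ValueError(f">2 alleles in a diploid call: {obs}")
    while len(obs) < 2:
        obs.append(None)
    return (obs[0], obs[1])


@dataclass
class GenotypeTable:
    """Per-individual, per-locus unordered diploid allele observations.

    ``calls[(individual, locus)]`` holds a canonical ``(a1, a2)`` pair with
    ``None`` in empty slots.  Absent keys and ``(None, None)`` both mean
    missing.  ``permissive_calls`` holds >2-allele observations accepted
    only in permissive mode (possible polyploids); they are invisible to
    phasing and only consulted by the ploidy check.
    """

    marker_mode: str = MICROSAT
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)
    permissive_calls: dict[tuple[str, str], tuple] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        out = {i for i, _ in self.calls} | {i for i, _ in self.permissive_calls}
        return sorted(out)

    @property
    def loci(self) -> list[str]:
        return sorted({l for _, l in self.calls} | {l for _, l in self.permissive_calls})

    def set_call(self, individual: str, locus: str,
                 alleles: Iterable[Optional[Allele]], permissive: bool = False) -> None:
        obs = [a for a in alleles if a is not None]
        if len(set(obs)) > 2 or len(obs) > 2:
            if not permissive:
                raise ValueError(
                    f"{individual} @ {locus}: {len(obs)} alleles in diploid mode "
                    "(possible polyploidy; use permissive mode to keep)"
                )
            self.permissive_calls[(individual, locus)] = tuple(
                sorted(obs, key=allele_sort_key))
            return
        self.calls[(individual, locus)] = _canon_call(obs)

    def call(self, individual: str, locus: str) -> Call:
        return self.calls.get((individual, locus), (None, None))

    def observed(self, individual: str, locus: str) -> tuple[Allele, ...]:
        """All non-missing alleles recorded for this call (0–2, or more in
        permissive storage)."""
        if (individual, locus) in self.permissive_calls:
            return self.permissive_calls[(individual, locus)]
        return tuple(a for a in self.call(individual, locus) if a is not None)

    def has_full_call(self, individual: str, locus: str) -> bool:
        """Both allele slots observed — required for phasing; half-calls
        count as missing here but still carry evidence elsewhere."""
        c = self.call(individual, locus)
        return c[0] is not None and c[1] is not None

    def is_missing(self, individual: str, locus: str) -> bool:
        return len(self.observed(individual, locus)) == 0

    def genotype(self, individual: str, locus: str) -> Optional[tuple[Allele, Allele]]:
        """Full diploid genotype as a sorted pair, or None if not fully called."""
        c = self.call(individual, locus)
        if c[0] is None or c[1] is None:
            return None
        return c

    def loci_typed(self, individual: str) -> list[str]:
        return sorted({l for (i, l) in self.calls if i == individual
                       and not self.is_missing(individual, l)})


@dataclass(frozen=True)
class Family:
    """One experimental cross: a single mother, a single father, and their
    offspring with recorded phenotypic sex (may be "undetermined", e.g.
    juveniles without fully developed gonads)."""

    cross_id: str
    mother_id: str
    father_id: str
    offspring: tuple[tuple[str, str], ...]  # (offspring_id, sex)

    def __post_init__(self):
        if self.mother_id == self.father_id:
            raise ValueError(f"cross {self.cross_id}: mother == father")
        ids = [o for o, _ in self.offspring]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cross {self.cross_id}: duplicate offspring id")
        for _, sex in self.offspring:
            if sex not in SEXES:
                raise ValueError(f"cross {self.cross_id}: bad sex label {sex!r}")

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return tuple(o for o, _ in self.offspring)

    def sex_of(self, offspring_id: str) -> str:
        for o, s in self.offspring:
            if o == offspring_id:
                return s
        raise KeyError(offspring_id)


@dataclass
class PhasedHaplotype:
    """One haploid genome recovered from a diploid genotype.

    origin: maternal_R (recombinant egg from an RR mother), paternal_L
    (clonal [L] sperm) or paternal_R ([R] sperm — clonal from a hybrid
    father, Mendelian from the control).  ``alleles`` is defined only at
    loci with status "phased".
    """

    individual_id: str
    origin: str
    alleles: dict[str, Allele] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise ValueError(f"bad origin {self.origin!r}")
        for locus, st in self.status.items():
            if st != "phased" and locus in self.alleles:
                raise ValueError(f"{self.individual_id} @ {locus}: allele with status {st}")

    def missing_fraction(self, loci: Iterable[str]) -> float:
        loci = list(loci)
        if not loci:
            return 1.0
        n_ok = sum(1 for l in loci if self.status.get(l) == "phased")
        return 1.0 - n_ok / len(loci)
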