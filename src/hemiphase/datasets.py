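"""Packaged reference fixtures.

Two small datasets ship with the package: the 15-locus species-diagnostic
microsatellite registry (fragment lengths in bp, split into lessonae- and
ridibundus-specific alleles) and a deterministic reconstruction of the
published cross table — 17 crosses, 12 hybrid fathers, 278 offspring with
recorded taxon-consistent genotypes and phenotypic sex, including the
single observed genome-leakage case: one son of cross 60-2013 that
received its father's R-specific allele at locus Re1Caga10 inside an
otherwise clonal [L] sperm.

Genotypes are reconstructed, not measured: parental allele picks are
arbitrary-but-deterministic choices from the registry pools (the
publication reports allele pools, not per-individual genotypes), so the
fixture reproduces the table's structure — progeny counts, sexes, gamete
classes, the leakage case — rather than real allele calls.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import NamedTuple, Optional

from .io import read_locus_registry
from .model import Family, GenotypeTable, LocusRegistry

# Non-diagnostic filler alleles (bp) used where one species has no
# diagnostic allele at a locus, so that both genomes amplify.  None of
# these values appears in the registry, so they class as non-diagnostic.
_L_FILL = {  # carried by lessonae genomes at ridibundus-only loci
    "Re1Caga10": [101, 104], "Re2Caga3": [166, 170], "RICA1b6": [70, 74],
    "Res22": [78, 82], "Rrid059A": [123, 126], "Rrid082A": [157, 160],
    "Rrid169A": [181, 184],
}
_R_FILL = {  # carried by ridibundus genomes at lessonae-only loci
    "RICA2a34": [148, 150, 152, 154], "RICA5": [250, 252, 254, 256],
    "RICA18": [178, 180, 182, 186], "Res20": [112, 114, 116, 118],
}

# (cross_id, father, gamete classes, RR ♂/♀/undev, RL ♂/♀/undev)
TABLE2_ROWS = [
    ("25-2013", "M1", "[L]", 0, 0, 0, 20, 0, 0),
    ("32-2013", "M1", "[L]", 0, 0, 0, 3, 0, 0),
    ("65-2013", "M3", "[L]", 0, 0, 0, 1, 0, 0),
    ("49-2013", "M4", "[L],[R]", 0, 1, 0, 1, 0, 0),
    ("39-2013", "M4", "[R]", 0, 22, 0, 0, 0, 0),
    ("42-2013", "M5", "[L]", 0, 0, 0, 64, 0, 0),
    ("53-2013", "M8", "[L]", 0, 0, 0, 2, 0, 0),
    ("41-2013", "M9", "[L]", 0, 0, 0, 20, 0, 0),
    ("57-2013", "M10", "[L]", 0, 0, 0, 3, 0, 0),
    ("66-2013", "M10", "[L]", 0, 0, 0, 20, 0, 2),
    ("27-2013", "M11", "[L],[R]", 0, 14, 1, 11, 0, 0),
    ("30-2013", "M11", "[L],[R]", 0, 28, 0, 21, 0, 0),
    ("59-2013", "M12", "[R]", 0, 2, 1, 0, 0, 0),
    ("60-2013", "M13", "[L]", 0, 0, 0, 19, 0, 0),
    ("54-2013", "M14", "[L]", 0, 0, 0, 2, 0, 0),
    ("63-2013", "M14", "[L]", 0, 0, 0, 3, 0, 0),
    ("26-2013", "M16", "[L]", 0, 0, 0, 17, 0, 0),
]

LEAK_OFFSPRING = "60-2013_JUV19"
LEAK_LOCUS = "Re1Caga10"


@lru_cache(maxsize=1)
def table1_registry() -> LocusRegistry:
    """The packaged 15-locus diagnostic registry (read from the shipped
    CSV, so the reader itself is on the fixture path)."""
    path = resources.files("hemiphase").joinpath("data/table1_loci.csv")
    with resources.as_file(path) as p:
        return read_locus_registry(p)


def table1_pools() -> dict[str, dict[str, list[int]]]:
    """Per-genome allele pools for the simulator: diagnostic alleles where
    the registry has them, shared non-diagnostic fillers elsewhere."""
    reg = table1_registry()
    pools: dict[str, dict[str, list[int]]] = {}
    for locus in reg.loci:
        l = sorted(reg.l_specific[locus])
        r = sorted(reg.r_specific[locus])
        pools[locus] = {
            "L": l if l else list(_L_FILL[locus]),
            "R": r if r else list(_R_FILL[locus]),
        }
    return pools


class Table2Fixture(NamedTuple):
    table: GenotypeTable
    families: list[Family]
    registry: LocusRegistry
    expected_profiles: dict[str, frozenset]
    leak: Optional[tuple[str, str]]  # (offspring_id, locus)


def _father_haplotypes(registry, pools, idx: int):
    """Shared-hemiclone [L] haplotype and a per-father [R] haplotype."""
    hap_l, hap_r = {}, {}
    for locus in registry.loci:
        l_pool, r_pool = pools[locus]["L"], pools[locus]["R"]
        hap_l[locus] = l_pool[0]
        hap_r[locus] = r_pool[idx % len(r_pool)]
    return hap_l, hap_r


def _mother_haplotypes(registry, pools, idx: int):
    hap_a, hap_b = {}, {}
    for locus in registry.loci:
        r_pool = pools[locus]["R"]
        hap_a[locus] = r_pool[idx % len(r_pool)]
        hap_b[locus] = r_pool[(idx + 3) % len(r_pool)]
    return hap_a, hap_b


def table2_dataset(include_leak: bool = True) -> Table2Fixture:
    """Deterministic reconstruction of the published 17-cross table.

    Every offspring genotype is mother-gamete ∪ father-haplotype, with
    the father's clonal [L] or [R] genome transmitted whole; when
    ``include_leak`` is set, son JUV19 of cross 60-2013 receives the
    father's R-specific Re1Caga10 allele in place of his clonal [L]
    allele, mirroring the one observed leakage event.
    """
    registry = table1_registry()
    pools = table1_pools()
    table = GenotypeTable(marker_mode="microsatellite")
    families: list[Family] = []
    expected: dict[str, frozenset] = {}

    mothers = {}
    for j in range(9):
        mid = f"F{j + 1}"
        mothers[mid] = _mother_haplotypes(registry, pools, j + 1)
        for locus in registry.loci:
            table.set_call(mid, locus, [mothers[mid][0][locus],
                                        mothers[mid][1][locus]])
    fathers = {}
    for row in TABLE2_ROWS:
        fid = row[1]
        if fid in fathers:
            continue
        idx = int(fid[1:])
        fathers[fid] = _father_haplotypes(registry, pools, idx)
        for locus in registry.loci:
            table.set_call(fid, locus, [fathers[fid][0][locus],
                                        fathers[fid][1][locus]])
        expected[fid] = frozenset()

    for row_idx, (cid, fid, gametes, rr_m, rr_f, rr_u, rl_m, rl_f, rl_u) in \
            enumerate(TABLE2_ROWS):
        mid = f"F{row_idx % 9 + 1}"
        hap_l, hap_r = fathers[fid]
        mat_a, mat_b = mothers[mid]
        expected[fid] = expected[fid] | frozenset(gametes.split(","))
        offspring: list[tuple[str, str]] = []
        cells = [("RR", "male", rr_m), ("RR", "female", rr_f),
                 ("RR", "undetermined", rr_u), ("RL", "male", rl_m),
                 ("RL", "female", rl_f), ("RL", "undetermined", rl_u)]
        k = 0
        for taxon, sex, count in cells:
            for _ in range(count):
                k += 1
                oid = f"{cid}_JUV{k}"
                maternal = mat_a if k % 2 else mat_b
                paternal = hap_l if taxon == "RL" else hap_r
                for locus in registry.loci:
                    pat = paternal[locus]
                    if (include_leak and oid == LEAK_OFFSPRING
                            and locus == LEAK_LOCUS):
                        pat = hap_r[locus]  # the father's [R] allele leaks in
                    table.set_call(oid, locus, [maternal[locus], pat])
                offspring.append((oid, sex))
        families.append(Family(cross_id=cid, mother_id=mid, father_id=fid,
                               offspring=tuple(offspring)))
    families.sort(key=lambda f: f.cross_id)
    return Table2Fixture(
        table=table, families=families, registry=registry,
        expected_profiles=expected,
        leak=(LEAK_OFFSPRING, LEAK_LOCUS) if include_leak else None)
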