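import numpy as np
import pytest
from hypothesis import given, strategies as st

import hemiphase as hp
from hemiphase.model import Family, GenotypeTable, LocusRegistry
from hemiphase.phasing import (CrossType, PhaseParams, filter_family_loci,
                               phase_family, phase_offspring,
                               screen_null_alleles)
from hemiphase.simulate import SimConfig, diagnostic_pools, simulate_system

from .oracle import brute_force_locus_phase, brute_force_retained

HYBRID = CrossType(label="RL_father_x_RR_mother", father_taxon="RL",
                   mother_taxon="RR")


def _family_table(mother, father, offspring_calls, loci):
    """Build a one-family dataset; offspring_calls: {oid: {locus: pair}}."""
    t = GenotypeTable()
    for locus in loci:
        t.set_call("MOM", locus, mother[locus])
        t.set_call("DAD", locus, father[locus])
    for oid, calls in offspring_calls.items():
        for locus, pair in calls.items():
            t.set_call(oid, locus, pair)
    fam = Family(cross_id="C1", mother_id="MOM", father_id="DAD",
                 offspring=tuple((o, "undetermined") for o in offspring_calls))
    return fam, t


# ---------------------------------------------------------------------------
# locus filtering

def test_filter_presence_rule(registry):
    loci = ["Rrid013A", "Ga1a19"]
    mother = {"Rrid013A": [287, 293], "Ga1a19": [203, 207]}
    father = {"Rrid013A": [301, 287], "Ga1a19": [197, 203]}
    offspring = {}
    for i in range(10):
        calls = {"Rrid013A": [301, 287]}
        if i < 8:  # 8/10 typed at Ga1a19: exactly at the 0.75 threshold
            calls["Ga1a19"] = [197, 203]
        offspring[f"J{i}"] = calls
    fam, t = _family_table(mother, father, offspring, loci)
    retained, dropped = filter_family_loci(fam, t, registry, 0.75)
    assert retained == ["Rrid013A", "Ga1a19"]
    retained, dropped = filter_family_loci(fam, t, registry, 0.9)
    assert retained == ["Rrid013A"] and dropped == {"Ga1a19": "offspring_presence"}


def test_filter_parent_missing(registry):
    fam, t = _family_table({"Rrid013A": [287, 293]}, {"Rrid013A": []},
                           {"J1": {"Rrid013A": [287, 293]}}, ["Rrid013A"])
    retained, dropped = filter_family_loci(fam, t, registry)
    assert retained == [] and dropped == {"Rrid013A": "parent_missing"}


def test_filter_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    loci = [f"rl{i}" for i in range(20)]
    reg = LocusRegistry(loci=tuple(loci),
                        l_specific={l: frozenset() for l in loci},
                        r_specific={l: frozenset() for l in loci})
    t = GenotypeTable()
    members = ["MOM", "DAD"] + [f"J{i}" for i in range(6)]
    for ind in members:
        for locus in loci:
            if rng.random() < 0.5:  # heavy random missingness
                t.set_call(ind, locus, [])
            else:
                t.set_call(ind, locus, [100, 102])
    fam = Family(cross_id="C", mother_id="MOM", father_id="DAD",
                 offspring=tuple((f"J{i}", "undetermined") for i in range(6)))
    for threshold in (0.5, 0.75, 1.0):
        retained, _ = filter_family_loci(fam, t, reg, threshold)
        assert sorted(retained) == sorted(brute_force_retained(fam, t, threshold))


def test_filter_monotone_in_presence_threshold(registry, table2):
    fam = table2.families[0]
    prev = None
    for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
        retained, _ = filter_family_loci(fam, table2.table, registry, thr)
        if prev is not None:
            assert set(retained) <= set(prev)
        prev = retained


# ---------------------------------------------------------------------------
# null-allele screening

def test_null_signature_flagged(registry):
    loci = ["Res14"]
    fam, t = _family_table({"Res14": [140, 140]}, {"Res14": [150, 160]},
                           {"J1": {"Res14": [140, 140]}}, loci)
    # offspring homozygous for an allele the father lacks: null in father
    assert screen_null_alleles(fam, t, registry, loci) == ["Res14"]


def test_mendelian_consistent_not_flagged(registry):
    loci = ["Res14"]
    fam, t = _family_table({"Res14": [140, 140]}, {"Res14": [150, 160]},
                           {"J1": {"Res14": [140, 150]},
                            "J2": {"Res14": [140, 160]}}, loci)
    assert screen_null_alleles(fam, t, registry, loci) == []


def test_null_screen_against_simulation_truth():
    cfg = SimConfig(pools=diagnostic_pools(n_loci=10), n_fathers=4, n_mothers=4,
                    offspring_per_cross=(10, 15),
                    profile_probs={"L": 1.0, "R": 0.0, "LR": 0.0},
                    null_allele_rate=0.1, seed=17)
    res = simulate_system(cfg)
    truth = res.truth
    for fam in res.families:
        flagged = set(screen_null_alleles(fam, res.table, res.registry,
                                          list(res.registry.loci)))
        # loci where a masking event realized in this family must be caught
        for ev in truth.null_events:
            if ev.individual_id not in (fam.mother_id, fam.father_id):
                continue
            for oid in fam.offspring_ids:
                src = truth.inheritance[oid]
                side = ("maternal" if ev.individual_id == fam.mother_id
                        else "paternal")
                if src[side][ev.locus] != ev.haplotype:
                    continue  # offspring inherited the visible allele
                other_side = "paternal" if side == "maternal" else "maternal"
                visible = truth.haplotypes[oid][other_side][ev.locus]
                if visible not in res.table.observed(ev.individual_id, ev.locus):
                    assert ev.locus in flagged
    # and a clean simulation yields no flags at all
    clean = simulate_system(SimConfig(
        pools=diagnostic_pools(n_loci=10), n_fathers=4, n_mothers=4,
        offspring_per_cross=(10, 15),
        profile_probs={"L": 1.0, "R": 0.0, "LR": 0.0}, seed=17))
    for fam in clean.families:
        assert screen_null_alleles(fam, clean.table, clean.registry,
                                   list(clean.registry.loci)) == []


# ---------------------------------------------------------------------------
# per-offspring phasing

def test_phase_rl_son_diagnostic_split(registry):
    fam, t = _family_table({"Rrid013A": [287, 293]}, {"Rrid013A": [301, 287]},
                           {"J1": {"Rrid013A": [301, 287]}}, ["Rrid013A"])
    mat, pat, conf = phase_offspring("J1", fam, t, registry, HYBRID, "[L]",
                                     ["Rrid013A"])
    assert conf == []
    assert pat.alleles["Rrid013A"] == 301 and mat.alleles["Rrid013A"] == 287


def test_phase_rr_daughter_unique_assignment(registry):
    fam, t = _family_table({"Rrid013A": [293, 293]}, {"Rrid013A": [301, 287]},
                           {"J1": {"Rrid013A": [287, 293]}}, ["Rrid013A"])
    mat, pat, _ = phase_offspring("J1", fam, t, registry, HYBRID, "[R]",
                                  ["Rrid013A"])
    assert pat.alleles["Rrid013A"] == 287 and mat.alleles["Rrid013A"] == 293


def test_phase_offspring_not_in_family(registry):
    fam, t = _family_table({"Rrid013A": [293, 293]}, {"Rrid013A": [301, 287]},
                           {"J1": {"Rrid013A": [287, 293]}}, ["Rrid013A"])
    with pytest.raises(KeyError):
        phase_offspring("J9", fam, t, registry, HYBRID, "[R]", ["Rrid013A"])


@given(st.data())
def test_phase_matches_brute_force_oracle(data):
    """Engine status and assignments equal the slot-enumeration oracle on
    random small families over random registries."""
    seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    from .oracle import random_registry

    reg, pools = random_registry(rng, n_loci=int(rng.integers(1, 11)))
    gamete = [None, "[L]", "[R]"][int(rng.integers(3))]
    n_off = int(rng.integers(1, 7))
    loci = list(reg.loci)

    def draw_gt(locus):
        pool = pools[locus]
        return [pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]]

    mother = {l: draw_gt(l) for l in loci}
    father = {l: draw_gt(l) for l in loci}
    offspring = {}
    for i in range(n_off):
        calls = {}
        for l in loci:
            if rng.random() < 0.8:  # usually a true transmission
                calls[l] = [mother[l][rng.integers(2)], father[l][rng.integers(2)]]
            else:                   # sometimes arbitrary (conflict material)
                calls[l] = draw_gt(l)
        offspring[f"J{i}"] = calls
    fam, t = _family_table(mother, father, offspring, loci)
    for oid in offspring:
        mat, pat, _ = phase_offspring(oid, fam, t, reg, HYBRID, gamete, loci)
        for locus in loci:
            status, assignment = brute_force_locus_phase(
                t.genotype(oid, locus), t.genotype("MOM", locus),
                t.genotype("DAD", locus), locus, reg, gamete)
            assert mat.status[locus] == status
            if status == "phased":
                assert (mat.alleles[locus], pat.alleles[locus]) == assignment


def test_reassembly_invariant(table2, table2_phased):
    for pf in table2_phased:
        for oid, (mat, pat) in pf.offspring_haplotypes.items():
            for locus in pf.retained_loci:
                if mat.status.get(locus) == "phased":
                    got = tuple(sorted((mat.alleles[locus], pat.alleles[locus])))
                    assert got == table2.table.genotype(oid, locus)


# ---------------------------------------------------------------------------
# family-level phasing

def test_noiseless_family_is_fully_clonal():
    cfg = SimConfig(pools=diagnostic_pools(n_loci=10), n_fathers=1, n_mothers=1,
                    offspring_per_cross=(10, 10),
                    profile_probs={"L": 1.0, "R": 0.0, "LR": 0.0}, seed=5)
    res = simulate_system(cfg)
    pf = phase_family(res.families[0], res.table, res.registry, PhaseParams())
    fid = res.families[0].father_id
    true_l = res.truth.haplotypes[fid]["L"]
    pats = [pat for _, pat in pf.offspring_haplotypes.values()]
    assert len(pats) == 10
    for pat in pats:
        assert pat.alleles == {l: true_l[l] for l in pf.retained_loci}
    assert pf.father_L_haplotype.alleles == {l: true_l[l]
                                             for l in pf.retained_loci}
    assert pf.conflicts == []


def test_amphispermic_family_recovers_both_classes():
    cfg = SimConfig(pools=diagnostic_pools(n_loci=10), n_fathers=1, n_mothers=1,
                    offspring_per_cross=(10, 10),
                    profile_probs={"L": 0.0, "R": 0.0, "LR": 1.0},
                    p_r_sperm=0.4, seed=8)
    res = simulate_system(cfg)
    pf = phase_family(res.families[0], res.table, res.registry, PhaseParams())
    fid = res.families[0].father_id
    classes = set(pf.gamete_class.values())
    assert classes == {"[L]", "[R]"}
    for oid, g in pf.gamete_class.items():
        assert g == res.truth.gamete_class[oid]
    for origin, genome in (("father_L_haplotype", "L"), ("father_R_haplotype", "R")):
        hap = getattr(pf, origin)
        truth_hap = res.truth.haplotypes[fid][genome]
        for locus, a in hap.alleles.items():
            assert a == truth_hap[locus]


def test_leak_conflict_recorded(table2_phased):
    all_conf = [c for pf in table2_phased for c in pf.conflicts]
    assert len(all_conf) == 1
    c = all_conf[0]
    assert c.kind == "leak_candidate"
    assert (c.offspring_id, c.locus) == ("60-2013_JUV19", "Re1Caga10")
    assert "R allele in [L] gamete context" in c.description


def test_unknown_father_rejected(registry):
    fam, t = _family_table(
        {"Rrid013A": [287, 293], "Re1Caga10": [106, 110]},
        {"Rrid013A": [], "Re1Caga10": []},
        {"J1": {"Rrid013A": [287, 293], "Re1Caga10": [106, 110]}},
        ["Rrid013A", "Re1Caga10"])
    with pytest.raises(ValueError, match="father"):
        phase_family(fam, t, registry, PhaseParams())


def test_no_retained_loci_raises():
    cfg = SimConfig(pools=diagnostic_pools(n_loci=3), n_fathers=1, n_mothers=1,
                    offspring_per_cross=(4, 4),
                    profile_probs={"L": 1.0, "R": 0.0, "LR": 0.0}, seed=2)
    res = simulate_system(cfg)
    fam = res.families[0]
    for oid in fam.offspring_ids:  # blank every offspring call
        for locus in res.registry.loci:
            res.table.calls[(oid, locus)] = (None, None)
    with pytest.raises(ValueError, match="no retained loci"):
        phase_family(fam, res.table, res.registry, PhaseParams())
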