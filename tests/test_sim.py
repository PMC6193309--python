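"""Simulator: primitive operations, conservation invariants, replay."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleokaryo.families import FamilyTable
from paleokaryo.genome import Gene, Genome
from paleokaryo.sim import (
    BranchSpec,
    ScenarioConfig,
    apply_fission,
    apply_fusion,
    apply_gene_loss,
    apply_inversion,
    apply_n_rearrangements,
    apply_rearrangements,
    apply_translocation,
    apply_wgd,
    evolve_descendants,
    replay,
    simulate_pre1r,
    simulate_scenario,
)


def gene_multiset(g: Genome):
    return sorted(gene.gene_id for _, _, gene in g.genes())


def chrom_content(g: Genome):
    return {c: [(x.gene_id, x.strand) for x in genes] for c, genes in g.chromosomes.items()}


# ---------------------------------------------------------------------------
# pre-duplication genome
# ---------------------------------------------------------------------------


def test_pre1r_construction_counts():
    g, fam = simulate_pre1r(17, 100, seed=1)
    assert g.n_chromosomes == 17
    assert g.n_genes == 1700
    assert len(fam.family_ids()) == 1700
    assert all(len(fam.children(r.copy_id)) == 0 for r in fam.roots())


def test_pre1r_minimal():
    g, _ = simulate_pre1r(1, 1, seed=0)
    assert g.n_chromosomes == 1 and g.n_genes == 1


def test_pre1r_seed_determinism():
    a, _ = simulate_pre1r(5, (10, 20), seed=42)
    b, _ = simulate_pre1r(5, (10, 20), seed=42)
    assert a == b


def test_pre1r_rejects_bad_arguments():
    with pytest.raises(ValueError):
        simulate_pre1r(0, 10, seed=1)
    with pytest.raises(ValueError):
        simulate_pre1r(2, 0, seed=1)


# ---------------------------------------------------------------------------
# WGD, fusion, fission
# ---------------------------------------------------------------------------


def test_wgd_doubles_everything():
    g, fam = simulate_pre1r(17, 60, seed=3)
    g2, fam2 = apply_wgd(g, fam, "1R")
    assert g2.n_chromosomes == 34
    assert g2.n_genes == 2 * g.n_genes
    # every family now has exactly two leaf copies, duplicated at 1R
    for root in fam2.roots():
        kids = fam2.children(root.copy_id)
        assert len(kids) == 2
        assert all(fam2.copies[k].epoch == "1R" for k in kids)


def test_wgd_small_and_repeated():
    g = Genome("t", "pre1R", {"c": [Gene("x", "x"), Gene("y", "y"), Gene("z", "z")]})
    fam = FamilyTable()
    for gid in "xyz":
        fam.add_root(gid)
    g2, fam2 = apply_wgd(g, fam, "1R")
    assert g2.n_chromosomes == 2 and g2.n_genes == 6
    g4, _ = apply_wgd(g2, fam2, "2R")
    assert g4.n_chromosomes == 4 and g4.n_genes == 12
    # 17 chromosomes twice -> 68
    big, bfam = simulate_pre1r(17, 10, seed=0)
    once, bfam = apply_wgd(big, bfam, "1R")
    twice, _ = apply_wgd(once, bfam, "2R")
    assert twice.n_chromosomes == 68


def test_wgd_rejects_empty():
    with pytest.raises(ValueError):
        apply_wgd(Genome("e", "x", {}), FamilyTable(), "1R")


def test_fusion_preserves_order_and_counts():
    g, _ = simulate_pre1r(3, 10, seed=1)
    fused = apply_fusion(g, "C01", "C02")
    assert fused.n_chromosomes == 2
    assert fused.n_genes == g.n_genes
    merged = fused.chromosomes["C01+C02"]
    assert [x.gene_id for x in merged] == [
        x.gene_id for x in g.chromosomes["C01"] + g.chromosomes["C02"]
    ]


def test_fusion_seven_times_34_to_27():
    g, fam = simulate_pre1r(17, 10, seed=2)
    g, fam = apply_wgd(g, fam, "1R")
    chroms = sorted(g.chromosomes)
    for i in range(7):
        g = apply_fusion(g, chroms[2 * i], chroms[2 * i + 1])
    assert g.n_chromosomes == 27


def test_fusion_policies_and_errors():
    g, _ = simulate_pre1r(2, 5, seed=1)
    hh = apply_fusion(g, "C01", "C02", join_policy="head_head")
    tail = hh.chromosomes["C01+C02"][5:]
    orig = g.chromosomes["C02"]
    assert [x.gene_id for x in tail] == [x.gene_id for x in reversed(orig)]
    assert [x.strand for x in tail] == [-x.strand for x in reversed(orig)]
    with pytest.raises(ValueError):
        apply_fusion(g, "C01", "C01")
    with pytest.raises(KeyError):
        apply_fusion(g, "C01", "nope")


def test_fission_splits_at_breakpoint():
    g, _ = simulate_pre1r(1, 10, seed=1)
    out = apply_fission(g, "C01", 3)
    assert out.n_chromosomes == 2
    assert len(out.chromosomes["C01_p"]) == 3
    assert len(out.chromosomes["C01_q"]) == 7
    for bad in (0, 10, -1):
        with pytest.raises(ValueError):
            apply_fission(g, "C01", bad)


# ---------------------------------------------------------------------------
# gene loss
# ---------------------------------------------------------------------------


def _duplicated_genome(n_families: int, seed: int = 0):
    g, fam = simulate_pre1r(4, n_families // 4, seed=seed)
    return apply_wgd(g, fam, "1R")


def test_loss_extremes():
    g, _ = _duplicated_genome(400)
    assert gene_multiset(apply_gene_loss(g, 1.0, seed=1)) == gene_multiset(g)
    lost = apply_gene_loss(g, 0.0, seed=1)
    by_family = {}
    for _, _, gene in lost.genes():
        by_family.setdefault(gene.family_id, []).append(gene.gene_id)
    assert all(len(v) == 1 for v in by_family.values())


def test_loss_rate_matches_binomial_expectation():
    # 5000 families of 2 copies = 10000 duplicate copies; with the one-
    # survivor floor the expected retained fraction is r + (1 - r)^2 / 2
    g, _ = _duplicated_genome(5000, seed=7)
    assert g.n_genes == 10000
    r = 0.35
    out = apply_gene_loss(g, r, seed=11)
    expected = r + (1 - r) ** 2 / 2
    observed = out.n_genes / g.n_genes
    assert observed == pytest.approx(expected, abs=0.02)


def test_loss_rejects_bad_rate():
    g, _ = _duplicated_genome(40)
    with pytest.raises(ValueError):
        apply_gene_loss(g, 1.2, seed=1)


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------


def test_rearrangement_zero_rates_noop():
    g, _ = simulate_pre1r(3, 20, seed=1)
    assert apply_rearrangements(g, 0.0, 0.0, seed=5) == g
    with pytest.raises(ValueError):
        apply_rearrangements(g, -0.1, 0.0, seed=5)


def test_single_inversion_reverses_span_and_strands():
    g, _ = simulate_pre1r(1, 10, seed=1)
    out = apply_inversion(g, "C01", 2, 7)
    before = g.chromosomes["C01"]
    after = out.chromosomes["C01"]
    assert [x.gene_id for x in after[2:7]] == [x.gene_id for x in reversed(before[2:7])]
    assert [x.strand for x in after[2:7]] == [-x.strand for x in reversed(before[2:7])]
    assert after[:2] == before[:2] and after[7:] == before[7:]
    assert sorted(gene_multiset(out)) == sorted(gene_multiset(g))


def test_many_rearrangements_conserve_content():
    g, _ = simulate_pre1r(5, 40, seed=2)
    rng = np.random.default_rng(9)
    out = apply_n_rearrangements(g, 600, 400, rng)
    assert gene_multiset(out) == gene_multiset(g)


def test_translocation_swaps_tails():
    g, _ = simulate_pre1r(2, 10, seed=1)
    out = apply_translocation(g, "C01", 4, "C02", 6)
    assert len(out.chromosomes["C01"]) == 4 + 4
    assert len(out.chromosomes["C02"]) == 6 + 6
    assert gene_multiset(out) == gene_multiset(g)


@given(
    n_genes=st.integers(4, 20),
    cut=st.data(),
)
def test_fission_then_fusion_roundtrip(n_genes, cut):
    g, _ = simulate_pre1r(1, n_genes, seed=1)
    k = cut.draw(st.integers(1, n_genes - 1))
    split = apply_fission(g, "C01", k)
    rejoined = apply_fusion(split, "C01_p", "C01_q")
    assert [x.gene_id for x in rejoined.chromosomes["C01_p+C01_q"]] == [
        x.gene_id for x in g.chromosomes["C01"]
    ]


# ---------------------------------------------------------------------------
# descendants and whole scenarios
# ---------------------------------------------------------------------------


def test_evolve_descendants_zero_rates_identical():
    g, fam = simulate_pre1r(3, 20, seed=1)
    branches = [
        BranchSpec("d1", "A", n_inversions=0, n_translocations=0),
        BranchSpec("d2", "B", n_inversions=0, n_translocations=0),
    ]
    out = evolve_descendants(g, branches, seed=4)
    for d in out.values():
        assert chrom_content(d) == chrom_content(g)


def test_evolve_descendants_rejects_degenerate_trees():
    g, _ = simulate_pre1r(2, 10, seed=1)
    with pytest.raises(ValueError):
        evolve_descendants(g, [BranchSpec("only", "A")], seed=1)
    with pytest.raises(ValueError):
        evolve_descendants(
            g, [BranchSpec("x", "A"), BranchSpec("y", "A")], seed=1
        )


def test_scenario_chromosome_counts_follow_the_event_series(scenario_sim):
    counts = scenario_sim.history.chromosome_counts
    assert counts["pre1R"] == 17
    assert counts["post1R"] == 34
    assert counts["inter1R2R"] == 27
    assert counts["post2R"] == 54
    assert counts["euteleostomi"] == 50
    assert counts["amniota"] == 49


def test_scenario_seed_determinism():
    a = simulate_scenario(seed=12)
    b = simulate_scenario(seed=12)
    assert chrom_content(a.ancestor) == chrom_content(b.ancestor)
    assert [g.name for g in a.descendants] == [g.name for g in b.descendants]
    for ga, gb in zip(a.descendants, b.descendants):
        assert chrom_content(ga) == chrom_content(gb)


def test_replay_reproduces_every_snapshot(scenario_sim):
    produced = replay(scenario_sim.history)
    for label, snap in scenario_sim.history.snapshots.items():
        assert chrom_content(produced[label]) == chrom_content(snap), label


def test_every_extant_gene_traces_to_one_founder(scenario_sim):
    fam = scenario_sim.families
    for genome in scenario_sim.descendants:
        for _, _, gene in genome.genes():
            root = fam.root_of(gene.gene_id)
            assert fam.copies[root].parent is None
            assert fam.family_of(root) == gene.family_id
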