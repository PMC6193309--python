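"""Ohnology proportion test, partner graph, tetrad assembly, merge/split."""

import subprocess

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from paleokaryo.reconstruction import CAR
from paleokaryo.tetrads import (
    MergeEvidence,
    complete_tetrads,
    find_triads,
    merge_cars,
    ohnology_matrix,
    ohnology_test,
    partner_distribution,
    permutation_ohnology_test,
    significant_partners,
    split_car,
)


# ---------------------------------------------------------------------------
# the proportion test
# ---------------------------------------------------------------------------


def test_zero_links_give_p_one():
    assert ohnology_test(0, 0, 10, 100) == 1.0
    assert ohnology_test(0, 10, 0, 0) == 1.0


def test_strong_enrichment_is_significant_after_bonferroni():
    # all 50 of a CAR's links land on one partner where ~5 were expected:
    # far below a Bonferroni threshold for ~1000 tests
    p = ohnology_test(50, 50, 100, 1000)
    assert p < 0.05 / 1000


def test_uniform_share_is_not_significant():
    # links proportional to gene share
    p = ohnology_test(5, 100, 50, 1000)
    assert p > 0.05


@pytest.mark.parametrize(
    "table",
    [(7, 22, 24, 1600), (50, 60, 80, 900), (0, 10, 5, 100), (3, 5, 2, 40),
     (12, 30, 10, 500)],
)
def test_matches_r_prop_test(table):
    """The reference implementation of the one-sided two-proportion test."""
    x1, n1, x2, n2 = table
    r = subprocess.run(
        ["Rscript", "-e",
         f"cat(suppressWarnings(prop.test(c({x1},{x2}), c({n1},{n2}),"
         " alternative='greater'))$p.value)"],
        capture_output=True, text=True, check=True,
    )
    expected = float(r.stdout.strip())
    assert ohnology_test(x1, n1, x2, n2) == pytest.approx(expected, rel=1e-6, abs=1e-12)


@pytest.mark.parametrize("table", [(8, 60, 50, 1000), (9, 60, 50, 1000)])
def test_permutation_route_agrees_with_chi_squared(table):
    # at moderate significance the Monte-Carlo placement null and the
    # continuity-corrected chi-squared agree to within a small factor
    x1, n1, x2, n2 = table
    p_chi = ohnology_test(x1, n1, x2, n2)
    p_perm = permutation_ohnology_test(x1, n1, x2 / n2, seed=3, n_perm=100000)
    assert p_chi / 3 <= p_perm <= 3 * p_chi
    assert p_perm < 0.05


def test_type_one_error_under_permutation_null():
    """With links placed by gene share alone, the raw test should reject at
    about the nominal rate (the continuity correction makes it a little
    conservative)."""
    rng = np.random.default_rng(17)
    n_cars, genes_per_car, links_per_car = 20, 50, 120
    rows = []
    rejections = 0
    tests = 0
    for rep in range(40):
        # multinomial placement of each CAR's links over the other CARs
        share = np.full(n_cars - 1, 1.0 / (n_cars - 1))
        for i in range(n_cars):
            hits = rng.multinomial(links_per_car, share)
            others = [j for j in range(n_cars) if j != i]
            for j, h in zip(others, hits):
                if j < i:
                    continue
                p = ohnology_test(
                    int(h), links_per_car, genes_per_car,
                    genes_per_car * (n_cars - 1),
                )
                tests += 1
                rejections += p <= 0.05
    rate = rejections / tests
    assert 0.005 <= rate <= 0.08


# ---------------------------------------------------------------------------
# matrix, partner graph, distribution
# ---------------------------------------------------------------------------


def _pairs_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "family_id", "car_a", "car_b", "source"]
    )


def test_matrix_symmetry_and_bonferroni():
    rows = []
    k = 0
    for _ in range(6):
        rows.append((f"g{k}", f"g{k+1}", f"f{k}", "A", "B", "L"))
        k += 2
    rows.append((f"g{k}", f"g{k+1}", f"f{k}", "A", "C", "L"))
    mat = ohnology_matrix(_pairs_frame(rows))
    # one row per unordered pair, car_i < car_j
    assert (mat.car_i < mat.car_j).all()
    n_tests = 3  # three link-bearing CARs
    for r in mat.itertuples():
        assert r.adj_p == pytest.approx(min(1.0, r.raw_p * n_tests))


def test_empty_matrix_yields_empty_graph():
    mat = ohnology_matrix(_pairs_frame([]))
    graph = significant_partners(mat)
    assert graph.number_of_edges() == 0
    with pytest.raises(ValueError):
        partner_distribution(mat, [])


def test_single_car_has_zero_partners():
    rows = [("a", "b", "f", "A", "A", "L")]
    mat = ohnology_matrix(_pairs_frame(rows))
    dist = partner_distribution(mat, [0.05])
    assert dist.iloc[0]["mean"] == 0.0


def test_clean_two_wgd_simulation_gives_three_partners(clean_fit):
    sweep = clean_fit.partner_sweep([1e-2, 1e-6, 1e-10])
    assert (sweep["mean"] == 3.0).all()
    assert clean_fit.n_tetrads == 17


# ---------------------------------------------------------------------------
# triads and completion
# ---------------------------------------------------------------------------


def _matrix_from_p(pvals, n_tests=None):
    """Build a matrix frame from {('A','B'): raw_p}."""
    n = n_tests if n_tests is not None else len(pvals)
    rows = [
        (min(i, j), max(i, j), 5, p, min(1.0, p * n))
        for (i, j), p in pvals.items()
    ]
    return pd.DataFrame(rows, columns=["car_i", "car_j", "shared", "raw_p", "adj_p"])


def test_four_clique_stands_as_tetrad():
    strong = 1e-8
    pvals = {(a, b): strong for a in "ABCD" for b in "ABCD" if a < b}
    mat = _matrix_from_p(pvals)
    graph = significant_partners(mat)
    cliques = find_triads(graph, list("ABCD"))
    tets = complete_tetrads(cliques, graph, mat, {c: 30 for c in "ABCD"})
    assert len(tets) == 1
    assert tets[0].members == list("ABCD")
    assert not tets[0].unresolved


def test_triad_completed_with_small_car():
    # A-B-C fully significant; small CAR D significant to two members
    pvals = {("A", "B"): 1e-9, ("A", "C"): 1e-9, ("B", "C"): 1e-9,
             ("A", "D"): 1e-6, ("B", "D"): 1e-6, ("C", "D"): 0.2}
    mat = _matrix_from_p(pvals, n_tests=6)
    graph = significant_partners(mat)
    cliques = find_triads(graph, list("ABC"))  # D below the size cut
    tets = complete_tetrads(cliques, graph, mat, {"A": 30, "B": 30, "C": 30, "D": 8})
    assert len(tets) == 1
    assert tets[0].members == list("ABCD")
    assert tets[0].completed_with == ["D"]


def test_completion_tie_left_unresolved():
    # D and E carry identical sub-threshold evidence towards the triad:
    # neither may be picked
    pvals = {("A", "B"): 1e-9, ("A", "C"): 1e-9, ("B", "C"): 1e-9,
             ("A", "D"): 1e-4, ("B", "D"): 1e-4,
             ("A", "E"): 1e-4, ("B", "E"): 1e-4}
    mat = _matrix_from_p(pvals, n_tests=1000)
    graph = significant_partners(mat)
    tets = complete_tetrads([["A", "B", "C"]], graph, mat,
                            {c: 30 for c in "ABCDE"})
    assert len(tets) == 1
    assert tets[0].unresolved and len(tets[0].members) == 3


def test_scenario_recovers_seventeen_tetrads(scenario_fit):
    assert scenario_fit.n_tetrads == 17
    assert all(len(t.members) == 4 for t in scenario_fit.tetrads)


# ---------------------------------------------------------------------------
# merging and splitting
# ---------------------------------------------------------------------------


def _merge_matrix():
    # A and B are fragments: both ohnologous to X, not to each other;
    # C is ohnologous to A (a WGD copy, not a fragment)
    pvals = {("A", "X"): 1e-8, ("B", "X"): 1e-8, ("A", "C"): 1e-8,
             ("A", "B"): 0.8, ("B", "C"): 0.6, ("C", "X"): 1e-8}
    return _matrix_from_p(pvals, n_tests=6)


def test_merge_fragments_with_required_evidence():
    cars = [CAR("A", ["a1", "a2"]), CAR("B", ["b1", "b2"])]
    merged, report = merge_cars(
        cars, MergeEvidence(same_descendant_chromosome=True), _merge_matrix()
    )
    assert merged is not None
    assert merged.genes == ["a1", "a2", "b1", "b2"]
    assert report["decision"] == "merged"


def test_merge_refused_between_ohnologous_cars():
    cars = [CAR("A", ["a1"]), CAR("C", ["c1"])]
    merged, report = merge_cars(
        cars, MergeEvidence(same_descendant_chromosome=True), _merge_matrix()
    )
    assert merged is None
    assert "ohnologous" in report["decision"]


def test_merge_refused_without_required_evidence():
    cars = [CAR("A", ["a1"]), CAR("B", ["b1"])]
    merged, report = merge_cars(cars, MergeEvidence(), _merge_matrix())
    assert merged is None


def test_merge_requires_common_partner():
    pvals = {("A", "X"): 1e-8, ("B", "Y"): 1e-8, ("A", "B"): 0.9}
    cars = [CAR("A", ["a1"]), CAR("B", ["b1"])]
    merged, report = merge_cars(
        cars, MergeEvidence(alt_co_membership=True), _matrix_from_p(pvals, 3)
    )
    assert merged is None
    assert "common" in report["decision"]


def test_split_homogeneous_car_is_untouched():
    car = CAR("Z", [f"g{i}" for i in range(20)])
    labels = ["t1"] * 20
    out, report = split_car(car, labels, labels)
    assert len(out) == 1 and out[0] is car
    assert report["decision"].startswith("no split")


def test_split_chimeric_car_at_coincident_changepoint():
    car = CAR("Z", [f"g{i}" for i in range(20)])
    partner = ["t1"] * 10 + ["t2"] * 10
    homology = ["chrA"] * 11 + ["chrB"] * 9
    out, report = split_car(car, partner, homology)
    assert len(out) == 2
    cut = len(out[0])
    assert 9 <= cut <= 11
    assert out[0].car_id == "Za" and out[1].car_id == "Zb"
    assert out[0].genes + out[1].genes == car.genes


def test_split_refused_when_changepoints_disagree():
    car = CAR("Z", [f"g{i}" for i in range(30)])
    partner = ["t1"] * 5 + ["t2"] * 25
    homology = ["chrA"] * 25 + ["chrB"] * 5
    out, report = split_car(car, partner, homology, window=10)
    assert len(out) == 1
    assert report["decision"] == "no split: change points disagree"


def test_fragmented_chromosome_merged_on_simulation(scenario_fit):
    """On the default scenario every merge decision joins only fragments of
    one true chromosome, so the fitted CAR count matches the ancestor."""
    assert len(scenario_fit.large_cars) == 49
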