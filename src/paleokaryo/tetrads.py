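"""Identification of ohnologous CAR pairs and their assembly into tetrads.

After two whole-genome duplications every pre-1R chromosome is expected to
leave four ohnologous CARs (a tetrad), linked pairwise by shared ohnolog
pairs.  Whether two CARs share more ohnologs than chance expects is judged
by a one-sided two-proportion test (chi-squared with continuity
correction, the contrast being the focal CAR's link share against the
partner CAR's share of ohnolog-bearing genes), Bonferroni-corrected over
all tested CAR pairs.  Significant partners form a graph whose maximal
cliques of size >= 3 are triads/tetrads; triads are completed with smaller
or sub-threshold CARs, and fragmented CARs are merged (or chimeric ones
split) under explicit evidence rules before counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome
from .reconstruction import CAR

__all__ = [
    "ohnology_test",
    "permutation_ohnology_test",
    "ohnology_matrix",
    "significant_partners",
    "partner_distribution",
    "find_triads",
    "complete_tetrads",
    "Tetrad",
    "MergeEvidence",
    "merge_cars",
    "propose_merges",
    "split_car",
    "car_homology",
]


# ---------------------------------------------------------------------------
# The proportion test
# ---------------------------------------------------------------------------


def ohnology_test(shared: int, links_i: int, genes_j: int, genes_not_i: int) -> float:
    """One-sided two-proportion test for ohnology between two CARs.

    Compares the proportion ``shared / links_i`` of CAR i's ohnolog links
    that land on CAR j against CAR j's share ``genes_j / genes_not_i`` of
    ohnolog-bearing genes outside CAR i (the expectation under random
    placement).  Chi-squared with continuity correction, upper tail only;
    mirrors R's ``prop.test(..., alternative="greater")``.

    A CAR with no ohnolog links carries no evidence: p = 1.
    """
    if links_i == 0 or genes_not_i == 0:
        return 1.0
    x = np.array([shared, genes_j], dtype=float)
    n = np.array([links_i, genes_not_i], dtype=float)
    p_pool = x.sum() / n.sum()
    if p_pool in (0.0, 1.0):
        return 1.0
    expected = np.array(
        [[n[0] * p_pool, n[0] * (1 - p_pool)], [n[1] * p_pool, n[1] * (1 - p_pool)]]
    )
    observed = np.array([[x[0], n[0] - x[0]], [x[1], n[1] - x[1]]])
    yates = min(0.5, float(np.abs(observed - expected).min()))
    stat = float((((np.abs(observed - expected) - yates) ** 2) / expected).sum())
    delta = x[0] / n[0] - x[1] / n[1]
    z = np.sign(delta) * np.sqrt(stat)
    return float(stats.norm.sf(z))


def permutation_ohnology_test(
    shared: int,
    links_i: int,
    gene_share_j: float,
    seed: int = 0,
    n_perm: int = 2000,
) -> float:
    """Monte-Carlo alternative for small counts.

    Places CAR i's ``links_i`` link endpoints independently with
    probability ``gene_share_j`` of landing on CAR j and returns the upper
    tail probability of observing >= ``shared`` hits.  Used as the
    small-count fallback and as an independent oracle for the chi-squared
    route.
    """
    if links_i == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    draws = rng.binomial(links_i, gene_share_j, size=n_perm)
    return float((np.count_nonzero(draws >= shared) + 1) / (n_perm + 1))


def _link_tables(
    pairs: pd.DataFrame,
) -> Tuple[Counter, Counter, Dict[str, Set[str]]]:
    """Shared-pair counts per CAR pair, link totals per CAR, and
    ohnolog-bearing genes per CAR."""
    shared: Counter = Counter()
    links: Counter = Counter()
    bearing: Dict[str, Set[str]] = {}
    for row in pairs.itertuples():
        key = tuple(sorted((row.car_a, row.car_b)))
        shared[key] += 1
        links[row.car_a] += 1
        if row.car_b != row.car_a:
            links[row.car_b] += 1
        bearing.setdefault(row.car_a, set()).add(row.gene_a)
        bearing.setdefault(row.car_b, set()).add(row.gene_b)
    return shared, links, bearing


def ohnology_matrix(
    pairs: pd.DataFrame,
    min_car_genes: int = 1,
    car_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Pairwise ohnology tests between all CARs with at least one link.

    The test for an unordered CAR pair is computed from the side with fewer
    total links (ties broken by CAR id), which makes the matrix symmetric by
    construction.  Bonferroni adjustment multiplies by the number of tested
    pairs (all unordered pairs among link-bearing CARs), capped at 1.

    Returns a frame with columns car_i, car_j (car_i < car_j), shared,
    raw_p, adj_p.
    """
    shared, links, bearing = _link_tables(pairs)
    cars = sorted(
        c
        for c in links
        if car_sizes is None or car_sizes.get(c, 0) >= min_car_genes
    )
    total_bearing = sum(len(bearing.get(c, ())) for c in cars)
    n_tests = len(cars) * (len(cars) - 1) // 2
    rows = []
    for i in range(len(cars)):
        for j in range(i + 1, len(cars)):
            ci, cj = cars[i], cars[j]
            s = shared.get((ci, cj), 0)
            # direction: the CAR with fewer links is the focal sample
            focal, other = (
                (ci, cj) if (links[ci], ci) <= (links[cj], cj) else (cj, ci)
            )
            p = ohnology_test(
                s,
                links[focal],
                len(bearing.get(other, ())),
                total_bearing - len(bearing.get(focal, ())),
            )
            rows.append((ci, cj, s, p, min(1.0, p * n_tests)))
    return pd.DataFrame(
        rows, columns=["car_i", "car_j", "shared", "raw_p", "adj_p"]
    )


def significant_partners(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> nx.Graph:
    """Graph of significantly ohnologous CAR pairs.

    Edges with adjusted p <= alpha are ``strict``; edges significant only
    without the correction are kept with ``strict=False`` for the tetrad
    completion step.
    """
    graph = nx.Graph()
    cars = set(matrix.car_i) | set(matrix.car_j)
    graph.add_nodes_from(sorted(cars))
    col = "adj_p" if bonferroni else "raw_p"
    for row in matrix.itertuples():
        if getattr(row, col) <= alpha:
            graph.add_edge(row.car_i, row.car_j, strict=True,
                           raw_p=row.raw_p, adj_p=row.adj_p, shared=row.shared)
        elif row.raw_p <= alpha:
            graph.add_edge(row.car_i, row.car_j, strict=False,
                           raw_p=row.raw_p, adj_p=row.adj_p, shared=row.shared)
    return graph


def partner_distribution(
    matrix: pd.DataFrame,
    thresholds: Sequence[float],
    cars: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Partner counts per CAR across adjusted-p thresholds.

    A stable mean of ~3 partners per CAR across a wide threshold range is
    the signature of two WGDs (tetrads); ~1 indicates a single WGD.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold sweep must not be empty")
    nodes = sorted(
        set(matrix.car_i) | set(matrix.car_j) if cars is None else cars
    )
    rows = []
    for thr in thresholds:
        counts = {c: 0 for c in nodes}
        sig = matrix[matrix.adj_p <= thr]
        for row in sig.itertuples():
            if row.car_i in counts:
                counts[row.car_i] += 1
            if row.car_j in counts:
                counts[row.car_j] += 1
        values = np.array([counts[c] for c in nodes], dtype=float)
        rows.append(
            {
                "threshold": thr,
                "mean": float(values.mean()) if len(values) else 0.0,
                "median": float(np.median(values)) if len(values) else 0.0,
                "min": float(values.min()) if len(values) else 0.0,
                "max": float(values.max()) if len(values) else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Triads and tetrads
# ---------------------------------------------------------------------------


@dataclass
class Tetrad:
    tetrad_id: str
    members: List[str]
    completed_with: List[str] = field(default_factory=list)
    unresolved: bool = False
    log: List[str] = field(default_factory=list)
    completion_p: float = 0.0  # combined p of the weakest completion step
    seed_size: int = 3  # members in the original clique or edge seed

    def __len__(self) -> int:
        return len(self.members)


def find_triads(graph: nx.Graph, large_cars: Sequence[str]) -> List[List[str]]:
    """Maximal cliques of size >= 3 among large CARs (strict edges only)."""
    strict = nx.Graph(
        (u, v) for u, v, d in graph.edges(data=True) if d.get("strict")
    )
    sub = strict.subgraph([c for c in large_cars if c in strict])
    cliques = [sorted(c) for c in nx.find_cliques(sub) if len(c) >= 3]
    return sorted(cliques)


def complete_tetrads(
    cliques: Sequence[Sequence[str]],
    graph: nx.Graph,
    matrix: pd.DataFrame,
    car_sizes: Mapping[str, int],
    alpha: float = 0.05,
    fisher_alpha: float = 1e-4,
) -> List[Tetrad]:
    """Assemble tetrads from cliques, triads and uncovered significant edges.

    4-cliques of the Bonferroni-significant partner graph stand as tetrads.
    Triads, and Bonferroni-significant edges not inside any clique, are
    grown to four members one CAR at a time.  A candidate member is judged
    on its ohnology evidence towards all current members combined
    (Fisher's method over the raw p-values): it must carry either one
    Bonferroni-significant edge or two edges significant without
    correction, reach a combined p below ``fisher_alpha`` (stringent,
    guarding the multiplicity of candidate scans), and must not create a
    tetrad sharing three or more CARs with an established tetrad — two
    tetrads can share at most the two WGD copies of one inter-WGD fused
    chromosome, so a 3-CAR overlap is incompatible with the two-WGD
    model.  Growth is globally greedy (largest seeds first, then strongest
    evidence), each finished tetrad constraining the rest; candidate ties
    leave a seed unresolved rather than guessing.

    When an edge inside a true tetrad falls just short of significance the
    same four CARs can be reached from several seeds, so finished tetrads
    are deduplicated by member set, proper subsets of another tetrad are
    dropped, and seeds that never reach three members are discarded.
    """
    raw_p: Dict[Tuple[str, str], float] = {}
    adj_p: Dict[Tuple[str, str], float] = {}
    for row in matrix.itertuples():
        raw_p[(row.car_i, row.car_j)] = row.raw_p
        adj_p[(row.car_i, row.car_j)] = row.adj_p

    def get_p(a: str, b: str, table: Dict[Tuple[str, str], float]) -> float:
        return table.get((a, b) if a < b else (b, a), 1.0)

    blocking = [set(c) for c in cliques if len(c) >= 4]
    all_cars = sorted(set(matrix.car_i) | set(matrix.car_j))
    tetrads: List[Tetrad] = []
    pending: List[Tetrad] = []
    n_seeds = 0

    def new_seed(members: Sequence[str]) -> Tetrad:
        nonlocal n_seeds
        n_seeds += 1
        return Tetrad(f"s{n_seeds}", sorted(members), seed_size=len(members))

    clique_sets = [set(c) for c in cliques]
    for clique in sorted(map(sorted, cliques)):
        t = new_seed(clique)
        if len(clique) >= 4:
            if len(clique) > 4:
                t.unresolved = True
                t.log.append(f"clique of {len(clique)} members exceeds a tetrad")
            tetrads.append(t)
        else:
            pending.append(t)
    # Bonferroni-significant edges not inside any clique seed pair growth
    for u, v, d in sorted(graph.edges(data=True)):
        if d.get("strict") and not any(
            {u, v} <= cs for cs in clique_sets
        ):
            pending.append(new_seed([u, v]))

    def candidate_scores(seed: Tetrad) -> Dict[str, Tuple[int, float, int]]:
        scores: Dict[str, Tuple[int, float, int]] = {}
        members = set(seed.members)
        for cand in all_cars:
            if cand in members:
                continue
            if any(len((members | {cand}) & b) >= 3 for b in blocking):
                continue  # would overlap an established tetrad in >= 3 CARs
            raws = [get_p(cand, m, raw_p) for m in seed.members]
            n_strict = sum(
                1 for m in seed.members if get_p(cand, m, adj_p) <= alpha
            )
            n_relaxed = sum(1 for p in raws if p <= alpha)
            if len(seed.members) == 2:
                # growth from a bare edge lacks the corroboration of a
                # triad, so the step to three members must be fully
                # supported: a Bonferroni-significant edge plus evidence
                # towards both members
                if n_strict < 1 or n_relaxed < 2:
                    continue
            elif n_strict < 1 and n_relaxed < 2:
                continue
            fisher = stats.combine_pvalues(raws, method="fisher").pvalue
            if fisher <= fisher_alpha:
                # a true member shares ohnologs with *every* current member
                # (a raw p near 1 means no shared pairs at all), so breadth
                # of compatibility, then of support, ranks before combined
                # strength: the strongest edges belong to CARs shared with
                # an adjacent tetrad and would otherwise always win
                n_compat = sum(1 for p_ in raws if p_ <= 0.5)
                scores[cand] = (n_compat, n_relaxed, fisher, n_strict)
        return scores

    # Grow seeds globally, largest and most confident first: each finished
    # tetrad then constrains the remaining seeds, so a weakly supported
    # seed cannot steal a member of an established tetrad.
    while pending:
        # a seed wholly contained in an established tetrad is spent
        pending = [
            t for t in pending
            if not any(set(t.members) <= b for b in blocking)
        ]
        best_idx = None
        best_entry: Optional[Tuple[int, int, float, str]] = None
        per_seed: Dict[int, List[Tuple[str, Tuple[int, float, int]]]] = {}
        for i, t in enumerate(pending):
            scores = candidate_scores(t)
            if not scores:
                continue
            ranked = sorted(
                scores.items(),
                key=lambda kv: (-kv[1][0], -kv[1][1], kv[1][2], kv[0]),
            )
            per_seed[i] = ranked
            cand, (n_comp, n_rel, fisher, _) = ranked[0]
            entry = (-len(t.members), -n_comp, -n_rel, fisher, cand)
            if best_entry is None or entry < best_entry:
                best_entry, best_idx = entry, i
        if best_idx is None:
            for t in pending:
                if len(t.members) >= 3 and t.seed_size >= 3:
                    t.unresolved = True
                    t.log.append("no completion candidate")
                    tetrads.append(t)
            break
        t = pending.pop(best_idx)
        ranked = per_seed[best_idx]
        best, best_score = ranked[0]
        ties = [c for c, s in ranked[1:] if s[:3] == best_score[:3]]
        if ties:
            if len(t.members) >= 3 and t.seed_size >= 3:
                t.unresolved = True
                t.log.append(
                    f"completion tie between {best} and {ties} — left open"
                )
                tetrads.append(t)
            continue
        t.members.append(best)
        t.members.sort()
        t.completed_with.append(best)
        t.completion_p = max(t.completion_p, best_score[2])
        t.log.append(
            f"completed with {best} (combined p={best_score[2]:.2e}, "
            f"supported edges={best_score[1]})"
        )
        if len(t.members) >= 4:
            blocking.append(set(t.members))
            tetrads.append(t)
        else:
            pending.append(t)

    # deduplicate by member set; drop proper subsets of another tetrad
    by_members: Dict[frozenset, Tetrad] = {}
    for t in tetrads:
        key = frozenset(t.members)
        if key in by_members:
            kept = by_members[key]
            kept.completed_with = sorted(set(kept.completed_with) & set(t.completed_with))
            kept.unresolved = kept.unresolved and t.unresolved
            kept.completion_p = min(kept.completion_p, t.completion_p)
            kept.log.extend(l for l in t.log if l not in kept.log)
        else:
            by_members[key] = t
    keys = list(by_members)
    final = [
        by_members[k]
        for k in keys
        if not any(k < other for other in keys)
    ]

    # global consistency: two tetrads can share at most 2 CARs; a tetrad
    # overlapping others in >= 3 members is a completion artefact — remove
    # the most conflicted (then least-supported) one until consistent
    def conflicts(ts: List[Tetrad]) -> Dict[int, int]:
        counts = {i: 0 for i in range(len(ts))}
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                if len(set(ts[i].members) & set(ts[j].members)) >= 3:
                    counts[i] += 1
                    counts[j] += 1
        return counts

    while True:
        counts = conflicts(final)
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        candidates_idx = [i for i, n in counts.items() if n == worst]
        drop = max(
            candidates_idx,
            key=lambda i: (final[i].completion_p, tuple(final[i].members)),
        )
        final = [t for i, t in enumerate(final) if i != drop]

    # a CAR can sit in at most two tetrads (one fusion junction); shed the
    # weakest claimant while any CAR is claimed three times
    while True:
        claims: Dict[str, List[int]] = {}
        for i, t in enumerate(final):
            for m in t.members:
                claims.setdefault(m, []).append(i)
        over = sorted(m for m, idx in claims.items() if len(idx) > 2)
        if not over:
            break
        idxs = claims[over[0]]
        drop = max(
            idxs,
            key=lambda i: (
                final[i].seed_size < 3,
                final[i].completion_p,
                tuple(final[i].members),
            ),
        )
        final = [t for i, t in enumerate(final) if i != drop]

    final.sort(key=lambda t: t.members)
    for i, t in enumerate(final):
        t.tetrad_id = str(i + 1)
    return final


# ---------------------------------------------------------------------------
# CAR merging and splitting
# ---------------------------------------------------------------------------


@dataclass
class MergeEvidence:
    """Evidence row for assembling CARs, in the audit-table style.

    ``alt_co_membership`` and ``same_descendant_chromosome`` are the
    required (greyed) conditions — at least one must hold; outgroup
    homology and double conserved synteny are supporting but dispensable.
    """

    alt_co_membership: bool = False
    same_descendant_chromosome: bool = False
    same_outgroup_chromosome: bool = False
    same_dcs_pair: bool = False


def merge_cars(
    candidates: Sequence[CAR],
    evidence: MergeEvidence,
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    adjacency: Optional[nx.Graph] = None,
) -> Tuple[Optional[CAR], dict]:
    """Merge 2-5 CARs believed to be fragments of one chromosome.

    Conditions: (i) at least one required evidence flag holds; (ii) all
    candidates share at least one common significantly ohnologous CAR;
    (iii) no two candidates are significantly ohnologous to each other
    (that would make them WGD copies, not fragments).  Order and
    orientation of the merged CAR follow adjacency-graph support between
    fragment ends where available; otherwise fragments are concatenated in
    id order and the junction is logged as arbitrary.
    """
    if not 2 <= len(candidates) <= 5:
        raise ValueError("merge candidates must number 2 to 5")
    report: dict = {"cars": [c.car_id for c in candidates], "evidence": evidence}
    if not (evidence.alt_co_membership or evidence.same_descendant_chromosome):
        report["decision"] = "refused: no required evidence"
        return None, report
    sig: Dict[str, Set[str]] = {c.car_id: set() for c in candidates}
    ids = {c.car_id for c in candidates}
    for row in matrix.itertuples():
        if row.adj_p <= alpha:
            if row.car_i in sig:
                sig[row.car_i].add(row.car_j)
            if row.car_j in sig:
                sig[row.car_j].add(row.car_i)
    for cid in ids:
        if sig[cid] & (ids - {cid}):
            report["decision"] = "refused: candidates ohnologous to each other"
            return None, report
    common = set.intersection(*(sig[c] for c in ids)) - ids
    if not common:
        report["decision"] = "refused: no common ohnologous partner"
        return None, report
    report["common_partners"] = sorted(common)
    ordered, arbitrary = _order_fragments(candidates, adjacency)
    genes: List[str] = []
    orientations: List[int] = []
    for frag in ordered:
        genes.extend(frag.genes)
        orientations.extend(frag.orientations)
    merged = CAR("_".join(c.car_id for c in ordered), genes, orientations)
    report["decision"] = "merged"
    report["junction_order"] = "adjacency-supported" if not arbitrary else "arbitrary"
    return merged, report


def _order_fragments(
    candidates: Sequence[CAR], adjacency: Optional[nx.Graph]
) -> Tuple[List[CAR], bool]:
    frags = sorted(candidates, key=lambda c: c.car_id)
    if adjacency is None or len(frags) != 2:
        return frags, True
    a, b = frags
    ends = {
        ("tail", "head"): (a, b),
        ("head", "tail"): (b, a),
    }
    for (ea, eb), (first, second) in ends.items():
        ga = first.genes[-1]
        gb = second.genes[0]
        if adjacency.has_edge(ga, gb):
            return [first, second], False
    return frags, True


def propose_merges(
    cars: Sequence[CAR],
    matrix: pd.DataFrame,
    homology: Mapping[str, Mapping[str, Optional[str]]],
    reference_genomes: Sequence[str],
    alpha: float = 0.05,
    alt_cars: Optional[Sequence[CAR]] = None,
    adjacency: Optional[nx.Graph] = None,
    outgroup_genomes: Sequence[str] = (),
) -> Tuple[List[CAR], List[dict]]:
    """Scan CARs for fragment groups and merge them under the evidence rules.

    Groups are CARs sharing the identical modal chromosome in every
    reference genome, or co-residing on one CAR of an alternative
    reconstruction.  Each group is passed through :func:`merge_cars`;
    accepted merges replace their fragments.  Returns the updated CAR list
    and the audit reports.
    """
    by_id = {c.car_id: c for c in cars}
    alt_member: Dict[str, str] = {}
    if alt_cars:
        for alt in alt_cars:
            for g in alt.genes:
                alt_member[g] = alt.car_id
    groups: Dict[tuple, List[str]] = {}
    for c in cars:
        labels = tuple(homology.get(c.car_id, {}).get(g) for g in reference_genomes)
        if any(l is None for l in labels):
            continue
        groups.setdefault(labels, []).append(c.car_id)
    # alternative-reconstruction co-membership groups
    alt_groups: Dict[str, List[str]] = {}
    for c in cars:
        if not alt_member:
            break
        alt_ids = {alt_member.get(g) for g in c.genes} - {None}
        if len(alt_ids) == 1:
            alt_groups.setdefault(alt_ids.pop(), []).append(c.car_id)

    candidates: List[Tuple[List[str], MergeEvidence]] = []
    seen: Set[frozenset] = set()
    for labels, members in sorted(groups.items()):
        if len(members) >= 2 and frozenset(members) not in seen:
            seen.add(frozenset(members))
            out_same = bool(outgroup_genomes) and all(
                homology.get(m, {}).get(o) is not None
                and homology.get(m, {}).get(o)
                == homology.get(members[0], {}).get(o)
                for m in members
                for o in outgroup_genomes
            )
            candidates.append(
                (sorted(members),
                 MergeEvidence(
                     alt_co_membership=False,
                     same_descendant_chromosome=True,
                     same_outgroup_chromosome=out_same,
                 ))
            )
    for alt_id, members in sorted(alt_groups.items()):
        if len(members) >= 2 and frozenset(members) not in seen:
            seen.add(frozenset(members))
            candidates.append(
                (sorted(members), MergeEvidence(alt_co_membership=True))
            )

    merged_out: List[CAR] = list(cars)
    reports: List[dict] = []
    for members, evidence in candidates:
        if len(members) > 5:
            reports.append(
                {"cars": members, "decision": "refused: more than 5 fragments"}
            )
            continue
        frags = [by_id[m] for m in members if m in by_id]
        if len(frags) < 2 or any(
            m not in {c.car_id for c in merged_out} for m in members
        ):
            continue
        merged, report = merge_cars(frags, evidence, matrix, alpha, adjacency)
        reports.append(report)
        if merged is not None:
            merged_out = [c for c in merged_out if c.car_id not in set(members)]
            merged_out.append(merged)
            by_id[merged.car_id] = merged
    return merged_out, reports


def car_homology(
    cars: Sequence[CAR],
    genomes: Sequence[Genome],
    descendant_of: Mapping[str, Mapping[str, List[str]]],
) -> Dict[str, Dict[str, Optional[str]]]:
    """Modal chromosome of each CAR's descendants in each genome.

    ``descendant_of`` maps ancestral gene -> genome name -> extant gene ids
    (from :class:`~paleokaryo.reconstruction.AncestralGenes`).
    """
    chrom_maps = {g.name: g.chromosome_of() for g in genomes}
    out: Dict[str, Dict[str, Optional[str]]] = {}
    for car in cars:
        per_genome: Dict[str, Optional[str]] = {}
        for gname, chrom_of in chrom_maps.items():
            tally: Counter = Counter()
            for anc in car.genes:
                for ext in descendant_of.get(anc, {}).get(gname, ()):
                    if ext in chrom_of:
                        tally[chrom_of[ext]] += 1
            per_genome[gname] = tally.most_common(1)[0][0] if tally else None
        out[car.car_id] = per_genome
    return out


def split_car(
    car: CAR,
    partner_labels: Sequence[Optional[str]],
    homology_labels: Sequence[Optional[str]],
    window: int = 10,
    min_segment: int = 3,
) -> Tuple[List[CAR], dict]:
    """Split a CAR at a coincident change-point of two signals.

    ``partner_labels`` carries, per gene, the dominant ohnolog-partner
    label (e.g. the partner CAR set); ``homology_labels`` the descendant-
    chromosome homology.  The CAR is split only where both label sequences
    switch within ``window`` positions of each other; otherwise it is
    returned intact (distant switch points are flagged, not acted on).
    """
    if len(partner_labels) != len(car) or len(homology_labels) != len(car):
        raise ValueError("label tracks must match the CAR length")

    def change_point(labels: Sequence[Optional[str]]) -> Optional[int]:
        runs: List[Tuple[Optional[str], int, int]] = []
        known = [(i, l) for i, l in enumerate(labels) if l is not None]
        if not known:
            return None
        # majority label before/after each cut; pick the cut maximising
        # flank homogeneity difference
        best, best_score = None, 0.0
        for cut in range(min_segment, len(labels) - min_segment + 1):
            left = Counter(l for _, l in known if _ < cut)
            right = Counter(l for _, l in known if _ >= cut)
            if not left or not right:
                continue
            la, ln = left.most_common(1)[0]
            ra, rn = right.most_common(1)[0]
            if la == ra:
                continue
            score = ln / sum(left.values()) + rn / sum(right.values())
            if score > best_score:
                best, best_score = cut, score
        if best is None or best_score < 1.6:  # both flanks must be >= ~80% pure
            return None
        return best

    cp_partner = change_point(partner_labels)
    cp_homology = change_point(homology_labels)
    report = {
        "car": car.car_id,
        "partner_change": cp_partner,
        "homology_change": cp_homology,
    }
    if cp_partner is None or cp_homology is None:
        report["decision"] = "no split: signal(s) homogeneous"
        return [car], report
    if abs(cp_partner - cp_homology) > window:
        report["decision"] = "no split: change points disagree"
        return [car], report
    cut = (cp_partner + cp_homology) // 2
    a = CAR(car.car_id + "a", car.genes[:cut], car.orientations[:cut])
    b = CAR(car.car_id + "b", car.genes[cut:], car.orientations[cut:])
    report["decision"] = f"split at {cut}"
    return [a, b], report
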