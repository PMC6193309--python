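"""Ancestral gene-order reconstruction as Contiguous Ancestral Regions.

A graph-based parsimony reconstruction: ancestral genes are vertices, and an
edge joins two genes whenever their descendants are immediate neighbours in
both genomes of an informative comparison (one genome from each descendant
clade, or a descendant against an outgroup).  Edge weights count the
comparisons conserving the adjacency.  The graph is linearised greedily
along edges of decreasing weight, accepting an edge only while both
endpoints keep degree < 2 and no cycle forms; the resulting paths are the
CARs (Contiguous Ancestral Regions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .families import STEM_EPOCHS, FamilyTable, epoch_index
from .genome import Genome

__all__ = [
    "CAR",
    "AncestralGenes",
    "infer_ancestral_genes",
    "build_adjacency_graph",
    "linearize",
    "car_stats",
    "filter_cars",
    "car_placement",
]


@dataclass
class CAR:
    """A Contiguous Ancestral Region: an ordered run of ancestral genes."""

    car_id: str
    genes: List[str]
    orientations: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a CAR must contain at least one gene")
        if not self.orientations:
            self.orientations = [1] * len(self.genes)
        if len(self.orientations) != len(self.genes):
            raise ValueError("orientations must match genes")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed_(self) -> "CAR":
        return CAR(self.car_id, self.genes[::-1], [-o for o in self.orientations[::-1]])


@dataclass
class AncestralGenes:
    """Ancestral gene set for a target ancestor with descendant maps."""

    target_epoch: str
    #: ancestral copy id -> {genome name: [extant gene ids]}
    descendants: Dict[str, Dict[str, List[str]]]

    @property
    def gene_ids(self) -> List[str]:
        return sorted(self.descendants)

    def __len__(self) -> int:
        return len(self.descendants)


def infer_ancestral_genes(
    families: FamilyTable,
    genomes: Sequence[Genome],
    target_epoch: str,
    epoch_order: Sequence[str] = STEM_EPOCHS,
) -> AncestralGenes:
    """Infer the gene set of the target ancestor from its descendants.

    One ancestral gene exists per family copy alive at the target epoch that
    has at least one descendant among the supplied genomes (which must all
    descend from the target ancestor).  Genes whose copy id is unknown to
    the family table raise an error.
    """
    descendants: Dict[str, Dict[str, List[str]]] = {}
    for genome in genomes:
        for _, _, gene in genome.genes():
            if gene.gene_id not in families:
                raise KeyError(
                    f"gene {gene.gene_id!r} in genome {genome.name!r} has no "
                    "family copy record"
                )
            anc = families.ancestor_at(gene.gene_id, target_epoch, epoch_order)
            descendants.setdefault(anc, {}).setdefault(genome.name, []).append(
                gene.gene_id
            )
    return AncestralGenes(target_epoch, descendants)


def _project(
    genome: Genome,
    families: FamilyTable,
    ancestral: AncestralGenes,
    epoch_order: Sequence[str],
) -> Tuple[Dict[frozenset, Tuple[int, int]], set]:
    """Project a genome onto ancestral gene coordinates.

    Returns (adjacencies, present): ``adjacencies`` maps each unordered pair
    of ancestral genes that are immediate neighbours (after dropping
    unmapped genes) to a canonical relative-orientation tuple; ``present``
    is the set of ancestral genes with a descendant in this genome.
    """
    anc_ids = ancestral.descendants
    adjacencies: Dict[frozenset, Tuple[int, int]] = {}
    present: set = set()
    for chrom, genes in genome.chromosomes.items():
        mapped: List[Tuple[str, int]] = []
        for g in genes:
            anc = families.ancestor_at(g.gene_id, ancestral.target_epoch, epoch_order)
            if anc in anc_ids:
                mapped.append((anc, g.strand))
                present.add(anc)
        for (u, su), (v, sv) in zip(mapped, mapped[1:]):
            if u == v:
                continue
            key = frozenset((u, v))
            # canonical orientation in the frame "min(u,v) first"
            rel = (su, sv) if u < v else (-sv, -su)
            adjacencies.setdefault(key, rel)
    return adjacencies, present


def build_adjacency_graph(
    clade_a: Sequence[Genome],
    clade_b: Sequence[Genome],
    outgroups: Sequence[Genome],
    ancestral: AncestralGenes,
    families: FamilyTable,
    epoch_order: Sequence[str] = STEM_EPOCHS,
    include_within_clade: bool = False,
) -> nx.Graph:
    """Build the conservation-weighted ancestral adjacency graph.

    Compared genome pairs: every cross-clade pair, and every descendant
    paired with every outgroup.  An edge's weight is the number of compared
    pairs in which the adjacency is conserved in both genomes (a pair is
    informative for an edge only when both genomes retain descendants of
    both genes; a conserved adjacency implies that).  With
    ``include_within_clade`` the within-clade pairs are added too — an
    alternative parameterisation that can bridge adjacencies lost in one
    clade, used as corroborating evidence when assembling CARs.
    """
    if not clade_a or not clade_b:
        raise ValueError("each descendant clade needs at least one genome")
    projections = {
        g.name: _project(g, families, ancestral, epoch_order)
        for g in [*clade_a, *clade_b, *outgroups]
    }
    pairs: List[Tuple[str, str]] = [
        (a.name, b.name) for a in clade_a for b in clade_b
    ]
    for d in [*clade_a, *clade_b]:
        for o in outgroups:
            pairs.append((d.name, o.name))
    if include_within_clade:
        for clade in (clade_a, clade_b):
            for i in range(len(clade)):
                for j in range(i + 1, len(clade)):
                    pairs.append((clade[i].name, clade[j].name))

    graph = nx.Graph()
    graph.add_nodes_from(ancestral.gene_ids)
    graph.graph["n_comparisons"] = len(pairs)
    for na, nb in pairs:
        adj_a, _ = projections[na]
        adj_b, _ = projections[nb]
        small, large = (adj_a, adj_b) if len(adj_a) <= len(adj_b) else (adj_b, adj_a)
        for key, rel in small.items():
            if key in large:
                u, v = sorted(key)
                if graph.has_edge(u, v):
                    graph[u][v]["weight"] += 1
                    graph[u][v]["rel"][rel] += 1
                else:
                    graph.add_edge(u, v, weight=1, rel=Counter([rel]))
    return graph


class _DisjointSet:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        while self.parent.setdefault(x, x) != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def linearize(graph: nx.Graph, min_weight: int = 1) -> List[CAR]:
    """Greedy linearisation of the adjacency graph into CARs.

    Edges are taken in decreasing weight (ties broken lexicographically by
    the sorted gene-id pair); an edge is accepted only if both endpoints
    have degree < 2 among accepted edges and it closes no cycle.  Accepted
    edges form vertex-disjoint paths; every vertex, including isolated
    ones, ends up in exactly one CAR.  CAR ids are assigned in decreasing
    length order ("1" is the longest).
    """
    edges = sorted(
        (
            (u, v) if u < v else (v, u)
            for u, v, w in graph.edges(data="weight")
            if w >= min_weight
        ),
        key=lambda e: (-graph[e[0]][e[1]]["weight"], e[0], e[1]),
    )
    degree: Dict[str, int] = {}
    dsu = _DisjointSet()
    selected: Dict[str, List[str]] = {v: [] for v in graph.nodes}
    for u, v in edges:
        if degree.get(u, 0) >= 2 or degree.get(v, 0) >= 2:
            continue
        if dsu.find(u) == dsu.find(v):
            continue  # would close a cycle
        dsu.union(u, v)
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        selected[u].append(v)
        selected[v].append(u)

    paths: List[List[str]] = []
    visited: set = set()
    for start in sorted(graph.nodes):
        if start in visited or len(selected[start]) > 1:
            continue
        # start is an endpoint (degree <= 1): walk the path
        path = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxts = [n for n in selected[cur] if n != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            path.append(cur)
            visited.add(cur)
        paths.append(path)

    cars: List[CAR] = []
    order = sorted(paths, key=lambda p: (-len(p), p[0]))
    for i, path in enumerate(order):
        cars.append(CAR(str(i + 1), path, _orient_path(graph, path)))
    return cars


def _orient_path(graph: nx.Graph, path: List[str]) -> List[int]:
    """Propagate gene orientations along a path from conserved adjacencies."""
    orientations = [1]
    for a, b in zip(path, path[1:]):
        rel_counter: Counter = graph[a][b].get("rel", Counter())
        if rel_counter:
            rel = rel_counter.most_common(1)[0][0]
            sa, sb = rel if a < b else (-rel[1], -rel[0])  # re-frame to a-before-b
            orientations.append(sb if orientations[-1] == sa else -sb)
        else:
            orientations.append(orientations[-1])
    return orientations


def car_stats(cars: Sequence[CAR]) -> Dict[str, float]:
    """Segment count, gene total, mean length and gene-based N50.

    N50 is the smallest length L such that CARs of length >= L together
    hold at least half of all genes.
    """
    if not cars:
        raise ValueError("cannot compute statistics of an empty CAR list")
    lengths = sorted((len(c) for c in cars), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for L in lengths:
        cum += L
        if cum >= total / 2:
            n50 = L
            break
    return {
        "count": len(cars),
        "total_genes": total,
        "mean_length": total / len(cars),
        "n50": n50,
    }


def filter_cars(cars: Sequence[CAR], min_len: int = 50) -> List[CAR]:
    """Keep CARs strictly larger than ``min_len`` genes."""
    return [c for c in cars if len(c) > min_len]


def car_placement(cars: Sequence[CAR]) -> Dict[str, Tuple[str, int]]:
    """Map gene id -> (car_id, position)."""
    placement: Dict[str, Tuple[str, int]] = {}
    for car in cars:
        for pos, gid in enumerate(car.genes):
            if gid in placement:
                raise ValueError(f"gene {gid!r} appears in two CARs")
            placement[gid] = (car.car_id, pos)
    return placement
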