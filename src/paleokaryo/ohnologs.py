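"""WGD-derived duplicate (ohnolog) detection on reconstructed gene orders.

Candidate ohnologs are same-family ancestral gene pairs whose duplication
dates to the 1R-2R window.  A synteny-support filter keeps a candidate only
if another candidate from a different family lies within N gene positions
on the same pair of CARs ("List A"); pairs on a single CAR must be at least
2N positions apart to exclude tandem duplicates.  A consensus list is then
grown from the intersection of high-confidence lists, adding lower-tier
pairs greedily while no ohnolog family network ever connects more than four
CARs of at least ten genes — the compatibility constraint imposed by two
rounds of whole-genome duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .families import STEM_EPOCHS, FamilyTable
from .reconstruction import CAR, car_placement

__all__ = [
    "OhnologParams",
    "Pair",
    "candidate_pairs",
    "synteny_support_filter",
    "convert_external_list",
    "OhnologList",
    "ConsensusResult",
    "build_consensus",
    "group_families",
]

Pair = Tuple[str, str]  # canonical: gene_a < gene_b


@dataclass
class OhnologParams:
    """Tunables of the ohnolog detection stage.

    ``synteny_window`` (N) is the maximum gene-order distance at which a
    second candidate pair corroborates a candidate; ``same_car_min_distance``
    (2N) is the minimum separation for two ohnologs on one CAR;
    ``min_car_genes_for_span`` sets which CARs count towards the four-CAR
    family limit.
    """

    synteny_window: int = 45
    same_car_min_distance: int = 90
    min_car_genes_for_span: int = 10
    max_family_cars: int = 4
    epoch_window: Tuple[str, ...] = ("1R", "2R")

    def __post_init__(self) -> None:
        if self.synteny_window <= 0:
            raise ValueError("synteny window N must be positive")


def _canonical(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def candidate_pairs(
    cars: Sequence[CAR],
    families: FamilyTable,
    params: Optional[OhnologParams] = None,
    epoch_order: Sequence[str] = STEM_EPOCHS,
) -> pd.DataFrame:
    """All same-family CAR-placed gene pairs duplicated in the epoch window.

    Returns a frame with columns gene_a, gene_b, family_id, epoch, car_a,
    car_b, pos_a, pos_b (canonical order: gene_a < gene_b).
    """
    p = params or OhnologParams()
    placement = car_placement(cars)
    by_family: Dict[str, List[str]] = {}
    for gid in placement:
        by_family.setdefault(families.family_of(gid), []).append(gid)
    rows = []
    window = set(p.epoch_window)
    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                epoch = families.pair_epoch(a, b)
                if epoch not in window:
                    continue
                ca, pa = placement[a]
                cb, pb = placement[b]
                rows.append((a, b, fam, epoch, ca, cb, pa, pb))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "family_id", "epoch",
            "car_a", "car_b", "pos_a", "pos_b",
        ],
    )


def _car_pair_key(row) -> Tuple[str, str]:
    return tuple(sorted((row.car_a, row.car_b)))  # type: ignore[return-value]


def _aligned_positions(row, key: Tuple[str, str]) -> Tuple[int, int]:
    """Positions of the pair aligned to the canonical CAR pair ``key``.

    For a same-CAR pair the two positions are sorted; otherwise the first
    coordinate belongs to ``key[0]``.
    """
    if row.car_a == row.car_b:
        return (min(row.pos_a, row.pos_b), max(row.pos_a, row.pos_b))
    if row.car_a == key[0]:
        return (row.pos_a, row.pos_b)
    return (row.pos_b, row.pos_a)


def synteny_support_filter(
    candidates: pd.DataFrame,
    params: Optional[OhnologParams] = None,
) -> pd.DataFrame:
    """Keep candidates corroborated by a nearby candidate of another family.

    A candidate on CARs (c1, c2) survives iff some candidate from a
    different family has its members within <= N gene positions on c1 and on
    c2 respectively (boundary inclusive).  Candidates with both genes on one
    CAR are eligible only when separated by >= 2N positions.
    """
    p = params or OhnologParams()
    if candidates.empty:
        return candidates.copy()
    eligible = candidates[
        (candidates.car_a != candidates.car_b)
        | ((candidates.pos_a - candidates.pos_b).abs() >= p.same_car_min_distance)
    ]
    keep_idx: List[int] = []
    groups: Dict[Tuple[str, str], List[Tuple[int, str, int, int]]] = {}
    for idx, row in eligible.iterrows():
        key = _car_pair_key(row)
        x, y = _aligned_positions(row, key)
        groups.setdefault(key, []).append((idx, row.family_id, x, y))
    for key, rows in groups.items():
        for idx, fam, x, y in rows:
            for jdx, fam2, x2, y2 in rows:
                if jdx == idx or fam2 == fam:
                    continue
                if abs(x - x2) <= p.synteny_window and abs(y - y2) <= p.synteny_window:
                    keep_idx.append(idx)
                    break
    return candidates.loc[sorted(keep_idx)].copy()


def convert_external_list(
    extant_pairs: Iterable[Tuple[str, str]],
    families: FamilyTable,
    target_epoch: str,
    epoch_order: Sequence[str] = STEM_EPOCHS,
) -> Tuple[List[Pair], Dict[str, int]]:
    """Map extant gene-id pairs to ancestral pairs at the target epoch.

    Pairs whose members collapse onto a single ancestral gene (duplication
    after the target ancestor) are dropped; duplicates are deduplicated;
    unresolvable identifiers are skipped and counted in the report.
    """
    out: set = set()
    report = {"input": 0, "unresolvable": 0, "collapsed": 0, "converted": 0}
    for a, b in extant_pairs:
        report["input"] += 1
        if a not in families or b not in families:
            report["unresolvable"] += 1
            continue
        anc_a = families.ancestor_at(a, target_epoch, epoch_order)
        anc_b = families.ancestor_at(b, target_epoch, epoch_order)
        if anc_a == anc_b:
            report["collapsed"] += 1
            continue
        out.add(_canonical(anc_a, anc_b))
    report["converted"] = len(out)
    return sorted(out), report


# ---------------------------------------------------------------------------
# Consensus building
# ---------------------------------------------------------------------------


@dataclass
class OhnologList:
    """A ranked source list of candidate ohnolog pairs.

    ``rank`` 0 lists are the high-confidence tier whose intersection seeds
    the consensus; higher ranks are considered later.
    """

    name: str
    pairs: List[Pair]
    rank: int = 0


@dataclass
class ConsensusResult:
    pairs: pd.DataFrame  # gene_a, gene_b, family_id, car_a, car_b, source
    log: List[dict] = field(default_factory=list)
    rejected: List[dict] = field(default_factory=list)

    @property
    def pair_set(self) -> set:
        return {
            _canonical(a, b) for a, b in zip(self.pairs.gene_a, self.pairs.gene_b)
        }


class _FamilyNetworks:
    """Tracks the CAR span of each ohnolog family as pairs are accepted."""

    def __init__(
        self,
        placement: Mapping[str, Tuple[str, int]],
        car_sizes: Mapping[str, int],
        params: OhnologParams,
    ) -> None:
        self.placement = placement
        self.car_sizes = car_sizes
        self.params = params
        self.genes: Dict[str, set] = {}

    def _span(self, genes: Iterable[str]) -> set:
        return {
            self.placement[g][0]
            for g in genes
            if self.car_sizes.get(self.placement[g][0], 0)
            >= self.params.min_car_genes_for_span
        }

    def span_after(self, family: str, a: str, b: str) -> int:
        return len(self._span(self.genes.get(family, set()) | {a, b}))

    def span(self, family: str) -> int:
        return len(self._span(self.genes.get(family, set())))

    def accept(self, family: str, a: str, b: str) -> None:
        self.genes.setdefault(family, set()).update((a, b))


def build_consensus(
    lists: Sequence[OhnologList],
    families: FamilyTable,
    cars: Sequence[CAR],
    params: Optional[OhnologParams] = None,
) -> ConsensusResult:
    """Grow a consensus ohnolog-pair list under the two-WGD constraint.

    The seed is the intersection of all rank-0 lists.  Remaining pairs are
    grouped by support signature (which source lists contain them) and
    considered in decreasing support, then increasing best rank.  A pair is
    rejected when its genes belong to different families, when it would push
    a family network beyond four CARs of at least ten genes, when a same-CAR
    pair sits closer than 2N, or when a gene is not placed on a CAR.
    Accepted pairs are permanent (greedy, no backtracking); after each batch
    the span invariant is re-checked over all family networks.
    """
    p = params or OhnologParams()
    if not lists:
        raise ValueError("at least one ranked list is required")
    if any(l.rank is None for l in lists):
        raise ValueError("every list needs a rank")
    placement = car_placement(cars)
    car_sizes = {c.car_id: len(c) for c in cars}
    networks = _FamilyNetworks(placement, car_sizes, p)

    support: Dict[Pair, List[OhnologList]] = {}
    for lst in lists:
        for a, b in lst.pairs:
            support.setdefault(_canonical(a, b), []).append(lst)

    top = [l for l in lists if l.rank == 0]
    seed = set.intersection(*(set(map(lambda x: _canonical(*x), l.pairs)) for l in top))

    def batches():
        yield "seed", sorted(seed)
        rest = sorted(set(support) - seed)
        sig: Dict[Tuple[int, int, Tuple[str, ...]], List[Pair]] = {}
        for pair in rest:
            ls = support[pair]
            key = (-len(ls), min(l.rank for l in ls), tuple(sorted(l.name for l in ls)))
            sig.setdefault(key, []).append(pair)
        for key in sorted(sig):
            yield "+".join(key[2]), sorted(sig[key])

    accepted_rows: List[tuple] = []
    accepted: set = set()
    result = ConsensusResult(pairs=pd.DataFrame())
    for batch_name, batch_pairs in batches():
        n_ok = n_rej = 0
        for a, b in batch_pairs:
            if (a, b) in accepted:
                continue
            reason = _check_pair(a, b, families, placement, networks, p)
            if reason is not None:
                result.rejected.append(
                    {"batch": batch_name, "pair": (a, b), "reason": reason}
                )
                n_rej += 1
                continue
            fam = families.family_of(a)
            networks.accept(fam, a, b)
            accepted.add((a, b))
            accepted_rows.append(
                (a, b, fam, placement[a][0], placement[b][0], batch_name)
            )
            n_ok += 1
        # per-batch re-check of the span invariant (greedy acceptance is
        # per pair; this asserts the batch left every network compatible)
        breaches = [
            f for f in networks.genes if networks.span(f) > p.max_family_cars
        ]
        if breaches:  # pragma: no cover - invariant breach
            raise AssertionError(
                f"family networks exceed {p.max_family_cars} CARs: {breaches[:5]}"
            )
        result.log.append(
            {"batch": batch_name, "accepted": n_ok, "rejected": n_rej}
        )
    result.pairs = pd.DataFrame(
        accepted_rows,
        columns=["gene_a", "gene_b", "family_id", "car_a", "car_b", "source"],
    )
    return result


def _check_pair(
    a: str,
    b: str,
    families: FamilyTable,
    placement: Mapping[str, Tuple[str, int]],
    networks: _FamilyNetworks,
    p: OhnologParams,
) -> Optional[str]:
    if a not in families or b not in families:
        return "unknown_gene"
    if families.family_of(a) != families.family_of(b):
        return "different_families"
    if a not in placement or b not in placement:
        return "not_on_car"
    ca, pa = placement[a]
    cb, pb = placement[b]
    if ca == cb and abs(pa - pb) < p.same_car_min_distance:
        return "same_car_too_close"
    fam = families.family_of(a)
    if networks.span_after(fam, a, b) > p.max_family_cars:
        return "car_span_exceeded"
    return None


def group_families(consensus: pd.DataFrame) -> List[dict]:
    """Connected components of the consensus pair graph.

    Each component must carry a single family id (pairs are intra-family by
    construction); a mixed component signals an invariant breach upstream.
    Returns one record per ohnolog family with its genes, pairs and CARs.
    """
    graph = nx.Graph()
    fam_of: Dict[str, str] = {}
    car_of: Dict[str, str] = {}
    for row in consensus.itertuples():
        graph.add_edge(row.gene_a, row.gene_b)
        fam_of[row.gene_a] = fam_of[row.gene_b] = row.family_id
        car_of[row.gene_a] = row.car_a
        car_of[row.gene_b] = row.car_b
    out = []
    for comp in nx.connected_components(graph):
        fams = {fam_of[g] for g in comp}
        if len(fams) != 1:
            raise AssertionError(
                f"ohnolog family component mixes family ids: {sorted(fams)}"
            )
        genes = sorted(comp)
        out.append(
            {
                "family_id": fams.pop(),
                "genes": genes,
                "size": len(genes),
                "cars": sorted({car_of[g] for g in genes}),
            }
        )
    return sorted(out, key=lambda r: (r["family_id"], r["genes"]))
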