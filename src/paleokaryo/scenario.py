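"""Karyotype event-scenario inference from tetrads and outgroup linkage groups.

Tetrads that share CARs record chromosomal events around the two WGDs:
two tetrads sharing a *pair* of CARs arose either from an inter-WGD fusion
or an inter-WGD fission — indistinguishable from the duplicated genomes
alone, but resolved by an unduplicated outgroup proto-karyotype (the
chordate linkage groups, CLGs): a fusion joins two distinct CLGs in one
tetrad pair, a fission splits one CLG over two tetrads.  A single CAR
joining two tetrads records a fusion *after* the second WGD, dated by
parsimony over descendant and outgroup chromosome homologies.  The event
counts yield a karyotype timeline: each WGD doubles the chromosome number,
each fusion subtracts one.
"""

from __future__ import annotations

import math

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .families import STEM_EPOCHS, FamilyTable, epoch_index
from .genome import Genome
from .reconstruction import CAR
from .tetrads import Tetrad

__all__ = [
    "assign_tetrads_to_clgs",
    "classify_adjacent_tetrads",
    "detect_post2r_fusions",
    "ScenarioEvent",
    "Timeline",
    "build_timeline",
    "assign_genes_pre1r",
    "ortholog_dotplot",
    "family_retention_profile",
]


@dataclass
class ScenarioEvent:
    type: str  # WGD1|WGD2|fusion_pre1R|fusion_interWGD|fusion_post2R|fission
    operands: List[str]
    epoch: Optional[str] = None
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CLG assignment
# ---------------------------------------------------------------------------


def assign_tetrads_to_clgs(
    tetrads: Sequence[Tetrad],
    clgs: Mapping[str, frozenset],
    tetrad_families: Mapping[str, Set[str]],
    predominant_floor: float = 0.5,
    predominant_ratio: float = 2.0,
    pre1r_fusion_threshold: float = 0.75,
) -> pd.DataFrame:
    """Associate each tetrad with its predominant chordate linkage group.

    For every (tetrad, CLG) pair two fractions are reported: ``coverage``
    (the share of the CLG's families with a descendant in the tetrad) and
    ``purity`` (the share of the tetrad's CLG-assignable families belonging
    to that CLG).  The predominant CLG is the purity argmax, required to
    reach ``predominant_floor`` and exceed the runner-up by
    ``predominant_ratio``; tetrads below the floor stay unassigned.  A
    tetrad containing more than ``pre1r_fusion_threshold`` of each of two
    CLGs — while being the unique best home of each — is flagged as a
    chordate-epoch (pre-1R) fusion; the uniqueness condition keeps a CAR
    shared with an adjacent tetrad, which imports the neighbour's linkage
    group, from mimicking the fusion signal.
    """
    for clg_id, fams in clgs.items():
        if not fams:
            raise ValueError(f"linkage group {clg_id!r} is empty")
    coverage_by_clg: Dict[str, Dict[str, float]] = {c: {} for c in clgs}
    for t in tetrads:
        fams = tetrad_families.get(t.tetrad_id, set())
        for clg_id, clg_fams in clgs.items():
            coverage_by_clg[clg_id][t.tetrad_id] = (
                len(fams & clg_fams) / len(clg_fams)
            )
    best_home = {}
    for clg_id, per in coverage_by_clg.items():
        ranked = sorted(per.items(), key=lambda kv: (-kv[1], kv[0]))
        best_home[clg_id] = (
            ranked[0][0]
            if ranked and (len(ranked) == 1 or ranked[0][1] > ranked[1][1])
            else None
        )
    rows = []
    for t in tetrads:
        fams = tetrad_families.get(t.tetrad_id, set())
        tallies = {
            clg_id: len(fams & clg_fams) for clg_id, clg_fams in clgs.items()
        }
        assignable = sum(tallies.values())
        ranked = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
        predominant = None
        if assignable:
            best, best_n = ranked[0]
            runner_n = ranked[1][1] if len(ranked) > 1 else 0
            if best_n / assignable >= predominant_floor and (
                runner_n == 0 or best_n / max(runner_n, 1) >= predominant_ratio
            ):
                predominant = best
        fused_clgs = [
            clg_id
            for clg_id in clgs
            if coverage_by_clg[clg_id][t.tetrad_id] > pre1r_fusion_threshold
            and best_home[clg_id] == t.tetrad_id
        ]
        for clg_id, n in ranked:
            if n == 0:
                continue
            rows.append(
                {
                    "tetrad_id": t.tetrad_id,
                    "clg_id": clg_id,
                    "families": n,
                    "coverage": n / len(clgs[clg_id]),
                    "purity": n / assignable,
                    "predominant": clg_id == predominant,
                    "pre1r_fusion": len(fused_clgs) >= 2 and clg_id in fused_clgs,
                }
            )
        if predominant is None:
            rows.append(
                {
                    "tetrad_id": t.tetrad_id,
                    "clg_id": None,
                    "families": assignable,
                    "coverage": 0.0,
                    "purity": 0.0,
                    "predominant": False,
                    "pre1r_fusion": False,
                }
            )
    return pd.DataFrame(rows)


def _predominant_clg(table: pd.DataFrame, tetrad_id: str) -> Optional[str]:
    sel = table[(table.tetrad_id == tetrad_id) & table.predominant]
    if sel.empty:
        return None
    return sel.iloc[0].clg_id


# ---------------------------------------------------------------------------
# Adjacent-tetrad classification and post-2R fusions
# ---------------------------------------------------------------------------


def _shared_cars(tetrads: Sequence[Tetrad]) -> Dict[str, List[str]]:
    member_of: Dict[str, List[str]] = {}
    for t in tetrads:
        for m in t.members:
            member_of.setdefault(m, []).append(t.tetrad_id)
    return member_of


def classify_adjacent_tetrads(
    tetrads: Sequence[Tetrad],
    clgs: Optional[Mapping[str, frozenset]],
    car_families: Optional[Mapping[str, Set[str]]] = None,
    min_purity: float = 0.5,
) -> List[ScenarioEvent]:
    """Resolve tetrad pairs sharing two CARs into inter-WGD fusion or fission.

    Without an outgroup the two scenarios are equally parsimonious.  With
    the chordate linkage groups, the contrast is carried by the members
    each tetrad does *not* share: after an inter-WGD fusion the unshared
    members of the two tetrads descend from two distinct chordate
    chromosomes, whereas after a fission both sets descend from the same
    one (the CLG is split over two tetrads).  The majority CLG of each
    unshared member set is required to cover at least ``min_purity`` of its
    CLG-assignable families; otherwise the pair is left unresolved with
    both hypotheses reported.
    """
    member_of = _shared_cars(tetrads)
    pair_shares: Dict[Tuple[str, str], List[str]] = {}
    for car, owners in member_of.items():
        if len(owners) == 2:
            key = tuple(sorted(owners))  # type: ignore[assignment]
            pair_shares.setdefault(key, []).append(car)
        elif len(owners) > 2:
            raise ValueError(
                f"CAR {car!r} belongs to {len(owners)} tetrads; "
                "upstream invariant breached"
            )
    by_id = {t.tetrad_id: t for t in tetrads}

    def majority_clg(cars: Sequence[str]) -> Optional[str]:
        if clgs is None or car_families is None:
            return None
        fams: Set[str] = set()
        for c in cars:
            fams |= car_families.get(c, set())
        tallies = sorted(
            ((len(fams & members), clg_id) for clg_id, members in clgs.items()),
            key=lambda kv: (-kv[0], kv[1]),
        )
        assignable = sum(n for n, _ in tallies)
        if not assignable or tallies[0][0] / assignable < min_purity:
            return None
        return tallies[0][1]

    events: List[ScenarioEvent] = []
    for (ta, tb), shared in sorted(pair_shares.items()):
        if len(shared) < 2:
            continue  # single-CAR junction: handled as a post-2R fusion
        own_a = [m for m in by_id[ta].members if m not in shared]
        own_b = [m for m in by_id[tb].members if m not in shared]
        evidence: dict = {"shared_cars": sorted(shared)}
        if clgs is None or car_families is None:
            events.append(
                ScenarioEvent(
                    "unresolved", [ta, tb], "inter1R2R",
                    {**evidence, "reason": "no outgroup linkage groups"},
                )
            )
            continue
        ca = majority_clg(own_a)
        cb = majority_clg(own_b)
        evidence.update({"clg_a": ca, "clg_b": cb})
        if ca is None or cb is None:
            etype = "unresolved"
        elif ca != cb:
            etype = "fusion_interWGD"
        else:
            etype = "fission"
        events.append(ScenarioEvent(etype, [ta, tb], "inter1R2R", evidence))
    return events


def detect_post2r_fusions(
    tetrads: Sequence[Tetrad],
    car_homology: Mapping[str, Mapping[str, Optional[str]]],
    car_single: Mapping[str, Mapping[str, bool]],
    divergence: Mapping[str, str],
    epoch_order: Sequence[str] = STEM_EPOCHS,
) -> List[ScenarioEvent]:
    """Post-2R fusions: CARs joining two tetrads as a single junction.

    A CAR belonging to exactly two tetrads whose partner CARs are not
    shared records a chromosome fusion after the second WGD.  Dating is by
    parsimony: a CAR mapping to a single chromosome in *any* lineage
    diverging at epoch e proves the fusion predates e (a convergent
    identical fusion would cost more events), so the fusion is placed just
    before the earliest divergence showing the joined state.  A split in a
    lineage diverging later is attributed to that lineage's own
    rearrangements and logged as a synteny disruption, not used to re-date.
    """
    member_of = _shared_cars(tetrads)
    pair_shares: Dict[Tuple[str, str], List[str]] = {}
    for car, owners in member_of.items():
        if len(owners) == 2:
            key = tuple(sorted(owners))  # type: ignore[assignment]
            pair_shares.setdefault(key, []).append(car)
    events: List[ScenarioEvent] = []
    for (ta, tb), cars in sorted(pair_shares.items()):
        if len(cars) != 1:
            continue
        car = cars[0]
        singles = car_single.get(car, {})
        by_div = sorted(
            singles.items(),
            key=lambda kv: (epoch_index(divergence.get(kv[0]), epoch_order), kv[0]),
        )
        def div_idx(gname: str) -> float:
            return epoch_index(divergence.get(gname), epoch_order)

        single_genomes = [g for g, s in by_div if s]
        split_genomes = [g for g, s in by_div if not s]
        upper: Optional[str] = (
            divergence.get(single_genomes[0]) if single_genomes else None
        )
        upper_idx = div_idx(single_genomes[0]) if single_genomes else math.inf
        pre_splits = [g for g in split_genomes if div_idx(g) < upper_idx]
        disruptions = [g for g in split_genomes if div_idx(g) >= upper_idx]
        lower: Optional[str] = (
            divergence.get(max(pre_splits, key=div_idx)) if pre_splits else None
        )
        evidence = {
            "car": car,
            "homology": {g: car_homology.get(car, {}).get(g) for g, _ in by_div},
            "single_in": {g: s for g, s in by_div},
        }
        if disruptions:
            evidence["synteny_disruptions"] = disruptions
        events.append(
            ScenarioEvent(
                "fusion_post2R",
                [ta, tb],
                upper,
                {**evidence, "interval": (lower or "2R", upper)},
            )
        )
    return events


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------


@dataclass
class Timeline:
    """Chromosome counts per stem epoch with the events that connect them."""

    counts: Dict[str, int]
    events: List[ScenarioEvent]

    def validate(self) -> None:
        c = self.counts
        if c["post1R"] != 2 * c["pre1R"]:
            raise ValueError("first WGD must double the chromosome count")
        if c["post2R"] != 2 * c["inter1R2R"]:
            raise ValueError("second WGD must double the chromosome count")

    def as_rows(self) -> List[Tuple[str, int]]:
        return list(self.counts.items())


def build_timeline(
    n_tetrads: int,
    inter_wgd_events: Sequence[ScenarioEvent],
    post2r_events: Sequence[ScenarioEvent],
    pre1r_fusions: int = 0,
    dated_epochs: Sequence[str] = ("euteleostomi", "amniota"),
) -> Timeline:
    """Karyotype counts along the stem from the recovered events.

    pre-1R count = tetrad count; the first WGD doubles it; inter-WGD
    fusions subtract; the second WGD doubles again; post-2R fusions
    subtract at their dated epochs (undated events are listed but not
    subtracted).  Arithmetic self-consistency is enforced.
    """
    fusions_inter = [e for e in inter_wgd_events if e.type == "fusion_interWGD"]
    fissions = [e for e in inter_wgd_events if e.type == "fission"]
    counts: Dict[str, int] = {}
    counts["pre1R"] = n_tetrads
    counts["post1R"] = 2 * n_tetrads
    counts["inter1R2R"] = counts["post1R"] - len(fusions_inter) + len(fissions)
    counts["post2R"] = 2 * counts["inter1R2R"]
    running = counts["post2R"]
    for epoch in dated_epochs:
        dated = [e for e in post2r_events if e.epoch == epoch]
        running -= len(dated)
        counts[epoch] = running
    events: List[ScenarioEvent] = [
        ScenarioEvent("fusion_pre1R", [], "pre1R", {"count": pre1r_fusions})
    ] * (1 if pre1r_fusions else 0)
    events += list(inter_wgd_events) + list(post2r_events)
    timeline = Timeline(counts, events)
    timeline.validate()
    return timeline


# ---------------------------------------------------------------------------
# Pre-1R gene assignment
# ---------------------------------------------------------------------------


def assign_genes_pre1r(
    families: FamilyTable,
    tetrads: Sequence[Tetrad],
    placement: Mapping[str, Tuple[str, int]],
    ohnolog_genes: Set[str],
) -> pd.DataFrame:
    """Assign pre-duplication genes to pre-1R chromosomes (tetrads).

    A founder gene is assigned iff all its CAR-placed descendants fall in
    the CARs of exactly one tetrad; descendants across two tetrads are
    ambiguous and excluded.  On CARs shared between adjacent tetrads only
    ohnolog genes (members of the consensus list) are considered, since
    non-ohnologs on a shared CAR cannot tell the two tetrads apart.
    """
    member_of = _shared_cars(tetrads)
    tetrad_of_car: Dict[str, List[str]] = member_of
    by_family: Dict[str, List[str]] = {}
    for gid, (car, _) in placement.items():
        by_family.setdefault(families.family_of(gid), []).append(gid)
    rows = []
    for fam in sorted(by_family):
        # each descendant is consistent with the tetrad(s) owning its CAR; a
        # gene on a shared CAR is consistent with either owner, so the
        # assignment is the tetrad common to all descendants' owner sets
        owner_sets: List[Set[str]] = []
        for gid in by_family[fam]:
            car = placement[gid][0]
            owners = tetrad_of_car.get(car, [])
            if not owners:
                continue
            if len(owners) > 1 and gid not in ohnolog_genes:
                continue  # shared CAR: only ohnologs are informative
            owner_sets.append(set(owners))
        if not owner_sets:
            rows.append((fam, None, "no_placed_descendants"))
            continue
        common = set.intersection(*owner_sets)
        if len(common) == 1:
            rows.append((fam, common.pop(), "assigned"))
        else:
            rows.append((fam, None, "ambiguous"))
    return pd.DataFrame(rows, columns=["family_id", "pre1r_chromosome", "status"])


# ---------------------------------------------------------------------------
# Fragmented-descendant orthology patterns
# ---------------------------------------------------------------------------


def ortholog_dotplot(
    groups: Mapping[str, Sequence[str]],
    cars: Sequence[CAR],
    fragmented: Genome,
    families: FamilyTable,
    divergence_epoch: str,
    epoch_order: Sequence[str] = STEM_EPOCHS,
    min_orthologs: int = 2,
) -> pd.DataFrame:
    """Orthology-pattern comparison against a fragmented descendant genome.

    ``groups`` maps a chromosome-group id (a tetrad, or a duplicated pair in
    a single-WGD control) to its member CAR ids.  Each scaffold of the
    fragmented genome is attributed to the CAR with which it shares most
    orthologs (genes descending from the same ancestral copy at the
    divergence epoch of the fragmented lineage); scaffolds attributed to
    the same CAR form a scaffold group.  Returns one row per group with the
    number of distinct scaffold groups — the expected modal ratio is 1:4
    for a lineage sharing both WGDs, 1:2 for a single shared WGD.
    """
    car_of_anc: Dict[str, str] = {}
    anc_of_copy: Dict[str, str] = {}
    for car in cars:
        for gid in car.genes:
            anc = families.ancestor_at(gid, divergence_epoch, epoch_order)
            car_of_anc[anc] = car.car_id
    scaffold_hits: Dict[str, Counter] = {}
    for chrom, _, gene in fragmented.genes():
        anc = families.ancestor_at(gene.gene_id, divergence_epoch, epoch_order)
        if anc in car_of_anc:
            scaffold_hits.setdefault(chrom, Counter())[car_of_anc[anc]] += 1
    attributed: Dict[str, str] = {}
    for scaffold, hits in scaffold_hits.items():
        car_id, n = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if n >= min_orthologs:
            attributed[scaffold] = car_id
    rows = []
    for gid_, members in sorted(groups.items()):
        member_set = set(members)
        used_cars = sorted(
            {car for car in attributed.values() if car in member_set}
        )
        n_scaffolds = sum(1 for s, c in attributed.items() if c in member_set)
        rows.append(
            {
                "group_id": gid_,
                "n_member_cars": len(member_set),
                "n_scaffold_groups": len(used_cars),
                "n_scaffolds": n_scaffolds,
            }
        )
    return pd.DataFrame(rows)


def family_retention_profile(
    family_records: Sequence[dict],
) -> Dict[str, int]:
    """Histogram of ohnolog family sizes 2/3/4 (pairs, triplets, quartets).

    Counts only families whose members each sit on a distinct CAR; others
    (and families above size 4) are excluded and reported separately.
    """
    profile = {"pairs": 0, "triplets": 0, "quartets": 0, "excluded": 0}
    for rec in family_records:
        size = rec["size"]
        if size > 4 or len(rec["cars"]) != size:
            profile["excluded"] += 1
            continue
        if size == 2:
            profile["pairs"] += 1
        elif size == 3:
            profile["triplets"] += 1
        elif size == 4:
            profile["quartets"] += 1
        else:  # pragma: no cover - size-1 families carry no pairs
            profile["excluded"] += 1
    return profile
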