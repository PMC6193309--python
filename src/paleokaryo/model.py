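"""Model/Results interface over the whole inference chain.

:class:`AncestralKaryotypeModel` holds the observed data — extant gene
orders split into two descendant clades plus outgroups, the gene-family
table, and optionally chordate linkage groups and external ohnolog lists —
and :meth:`~AncestralKaryotypeModel.fit` runs reconstruction, ohnolog
detection, tetrad assembly and scenario inference, returning a
:class:`KaryotypeResults` with the estimates (CARs, consensus ohnologs,
tetrads, event scenario, karyotype timeline), their diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from . import io as pkio
from .families import STEM_EPOCHS, FamilyTable, epoch_index
from .genome import Genome
from .io import RunConfig
from .ohnologs import (
    OhnologList,
    OhnologParams,
    build_consensus,
    candidate_pairs,
    group_families,
    synteny_support_filter,
)
from .reconstruction import (
    CAR,
    AncestralGenes,
    build_adjacency_graph,
    car_placement,
    car_stats,
    filter_cars,
    infer_ancestral_genes,
    linearize,
)
from .scenario import (
    Timeline,
    assign_genes_pre1r,
    assign_tetrads_to_clgs,
    build_timeline,
    classify_adjacent_tetrads,
    detect_post2r_fusions,
    family_retention_profile,
)
from .tetrads import (
    Tetrad,
    car_homology,
    complete_tetrads,
    find_triads,
    ohnology_matrix,
    partner_distribution,
    propose_merges,
    significant_partners,
)

__all__ = ["AncestralKaryotypeModel", "KaryotypeResults"]


@dataclass
class KaryotypeResults:
    """Estimates and diagnostics of a fitted karyotype reconstruction."""

    config: RunConfig
    ancestral: AncestralGenes
    cars: List[CAR]
    large_cars: List[CAR]
    car_statistics: Dict[str, float]
    candidates: pd.DataFrame
    list_a: pd.DataFrame
    consensus: pd.DataFrame
    consensus_log: List[dict]
    families_profile: Dict[str, int]
    ohnolog_families: List[dict]
    matrix: pd.DataFrame
    partner_graph: nx.Graph
    tetrads: List[Tetrad]
    merge_reports: List[dict]
    clg_table: Optional[pd.DataFrame]
    events: List
    timeline: Optional[Timeline]
    pre1r_assignment: Optional[pd.DataFrame]
    manifest: Dict[str, object] = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    @property
    def n_tetrads(self) -> int:
        return len(self.tetrads)

    def partner_sweep(self, thresholds: Sequence[float]) -> pd.DataFrame:
        large_ids = [c.car_id for c in self.large_cars]
        return partner_distribution(self.matrix, thresholds, cars=large_ids)

    def summary(self) -> str:
        lines = ["Ancestral karyotype reconstruction", "=" * 42]
        man = self.manifest
        rows = [
            ("ancestral genes", man.get("n_ancestral_genes")),
            ("CAR segments", man.get("n_cars")),
            ("CAR N50 (genes)", man.get("car_n50")),
            ("chromosome-size CARs", man.get("n_large_cars")),
            ("candidate ohnolog pairs", man.get("n_candidates")),
            ("synteny-supported pairs (list A)", man.get("n_list_a")),
            ("consensus ohnolog pairs", man.get("n_consensus_pairs")),
            ("consensus ohnolog genes", man.get("n_consensus_genes")),
            ("ohnolog families", man.get("n_families")),
            ("  pairs / triplets / quartets",
             "{pairs} / {triplets} / {quartets}".format(**self.families_profile)),
            ("tetrads (pre-1R chromosomes)", self.n_tetrads),
            ("mean ohnolog partners per CAR", man.get("mean_partners")),
        ]
        for label, value in rows:
            lines.append(f"{label:<36}{value}")
        if self.timeline is not None:
            lines.append("-" * 42)
            lines.append("Karyotype timeline (chromosomes):")
            for epoch, n in self.timeline.counts.items():
                lines.append(f"  {epoch:<14}{n}")
            by_type = Counter(e.type for e in self.events)
            lines.append("Events: " + ", ".join(
                f"{t}={n}" for t, n in sorted(by_type.items())
            ))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pkio.write_cars(self.cars, out / "cars.tsv")
        pkio.write_pairs(self.consensus, out / "ohnolog_pairs.tsv")
        pkio.write_matrix(self.matrix, out / "ohnology_matrix.tsv")
        pkio.write_tetrads(self.tetrads, out / "tetrads.json")
        if self.timeline is not None:
            pkio.write_scenario(
                self.timeline, self.events, self.clg_table, out / "scenario.json"
            )
        if self.pre1r_assignment is not None:
            self.pre1r_assignment.to_csv(
                out / "pre1r_assignment.tsv", sep="\t", index=False
            )
        import json

        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


class AncestralKaryotypeModel:
    """Karyotype-history model built from extant gene orders.

    Parameters
    ----------
    clade_a, clade_b
        Genomes descending from the target ancestor, one list per clade
        (the conservation weighting compares genomes across clades).
    outgroups
        Genomes that diverged before the target ancestor (used for
        adjacency conservation and for dating post-2R fusions).
    families
        Gene-family copy trees with epoch-labelled duplications.
    divergence
        Genome name -> stem epoch at which its lineage diverged.
    clgs
        Chordate linkage groups (id -> family ids); optional, required to
        discriminate inter-WGD fusions from fissions.
    external_lists
        Additional ranked ohnolog-pair lists to blend into the consensus.
    config
        A :class:`~paleokaryo.io.RunConfig`; defaults to full-scale values.
    """

    def __init__(
        self,
        clade_a: Sequence[Genome],
        clade_b: Sequence[Genome],
        outgroups: Sequence[Genome],
        families: FamilyTable,
        divergence: Mapping[str, str],
        clgs: Optional[Mapping[str, frozenset]] = None,
        external_lists: Optional[Sequence[OhnologList]] = None,
        config: Optional[RunConfig] = None,
        epoch_order: Sequence[str] = STEM_EPOCHS,
    ) -> None:
        if not clade_a or not clade_b:
            raise ValueError("both descendant clades need at least one genome")
        self.clade_a = list(clade_a)
        self.clade_b = list(clade_b)
        self.outgroups = list(outgroups)
        self.families = families
        self.divergence = dict(divergence)
        self.clgs = dict(clgs) if clgs else None
        self.external_lists = list(external_lists or [])
        self.config = config or RunConfig()
        self.epoch_order = tuple(epoch_order)

    @classmethod
    def from_simulation(cls, sim, config: Optional[RunConfig] = None):
        """Build the model from a :class:`~paleokaryo.sim.ScenarioData`."""
        if config is None:
            gpc = sim.config.genes_per_chromosome
            mean_genes = (
                gpc if isinstance(gpc, int) else (gpc[0] + gpc[1]) / 2
            )
            # expected genes per post-2R chromosome after rediploidisation
            r = sim.config.retention
            if sim.config.n_wgds >= 2:
                surv = 4 * r + (1 - r) ** 4
                mean_chrom = mean_genes * surv / 4
            else:
                surv = 2 * r + (1 - r) ** 2
                mean_chrom = mean_genes * surv / 2
            config = RunConfig.scaled(mean_chrom)
        return cls(
            sim.clade_a,
            sim.clade_b,
            sim.outgroups,
            sim.families,
            sim.divergence,
            clgs=sim.clgs,
            config=config,
            epoch_order=sim.epoch_order,
        )

    # ------------------------------------------------------------------
    def fit(self) -> KaryotypeResults:
        cfg = self.config
        manifest: Dict[str, object] = {"config": cfg.__dict__.copy()}

        # 1. ancestral gene content and order -----------------------------
        ancestral = infer_ancestral_genes(
            self.families, self.clade_a + self.clade_b,
            cfg.target_epoch, self.epoch_order,
        )
        graph = build_adjacency_graph(
            self.clade_a, self.clade_b, self.outgroups, ancestral,
            self.families, self.epoch_order,
        )
        alt_graph = build_adjacency_graph(
            self.clade_a, self.clade_b, self.outgroups, ancestral,
            self.families, self.epoch_order, include_within_clade=True,
        )
        cars = linearize(graph, min_weight=cfg.min_edge_weight)
        alt_cars = linearize(alt_graph, min_weight=cfg.min_edge_weight)
        stats = car_stats(cars)
        manifest.update(
            n_ancestral_genes=len(ancestral),
            n_cars=int(stats["count"]),
            car_n50=int(stats["n50"]),
            car_total_genes=int(stats["total_genes"]),
        )

        # 2. ohnolog detection + ohnology matrix ---------------------------
        def ohnolog_stage(car_list: List[CAR]):
            params = OhnologParams(
                synteny_window=cfg.synteny_window,
                same_car_min_distance=cfg.same_car_min_distance,
                min_car_genes_for_span=cfg.min_car_genes_for_span,
                max_family_cars=cfg.max_family_cars,
                epoch_window=cfg.epoch_window,
            )
            cands = candidate_pairs(car_list, self.families, params, self.epoch_order)
            list_a = synteny_support_filter(cands, params)
            tiers = [
                OhnologList(
                    "A", list(zip(list_a.gene_a, list_a.gene_b)), rank=0
                )
            ] + list(self.external_lists)
            consensus = build_consensus(tiers, self.families, car_list, params)
            matrix = ohnology_matrix(consensus.pairs)
            return cands, list_a, consensus, matrix

        candidates, list_a, consensus, matrix = ohnolog_stage(cars)
        large = filter_cars(cars, cfg.min_car_len)

        # 3. merge reconstruction fragments --------------------------------
        # homology maps need descendants of ancestral genes in *all* genomes,
        # outgroups included (they carry the same gene copies, minus their
        # own losses)
        full_map = self._descendant_map(ancestral)
        ref_genomes = [self.clade_a[0], self.clade_b[0]]
        homology = car_homology(large, ref_genomes + self.outgroups, full_map)
        merged_large, merge_reports = propose_merges(
            large, matrix, homology,
            [g.name for g in ref_genomes],
            alpha=cfg.alpha, alt_cars=alt_cars, adjacency=graph,
            outgroup_genomes=[g.name for g in self.outgroups],
        )
        n_merges = sum(1 for r in merge_reports if r.get("decision") == "merged")
        if n_merges:
            merged_ids = {c.car_id for c in large} - {c.car_id for c in merged_large}
            cars = [c for c in cars if c.car_id not in merged_ids] + [
                c for c in merged_large if c.car_id not in {x.car_id for x in cars}
            ]
            candidates, list_a, consensus, matrix = ohnolog_stage(cars)
            large = sorted(
                filter_cars(cars, cfg.min_car_len), key=lambda c: c.car_id
            )
        else:
            large = merged_large
        manifest.update(
            n_large_cars=len(large),
            n_merges=n_merges,
            n_candidates=len(candidates),
            n_list_a=len(list_a),
            n_consensus_pairs=len(consensus.pairs),
            n_consensus_genes=len(
                set(consensus.pairs.gene_a) | set(consensus.pairs.gene_b)
            ),
        )

        # 4. tetrad assembly ------------------------------------------------
        graph_sig = significant_partners(matrix, cfg.alpha, cfg.bonferroni)
        large_ids = [c.car_id for c in large]
        car_sizes = {c.car_id: len(c) for c in cars}
        cliques = find_triads(graph_sig, large_ids)
        tetrads = complete_tetrads(
            cliques, graph_sig, matrix, car_sizes, alpha=cfg.alpha
        )
        fam_records = group_families(consensus.pairs)
        profile = family_retention_profile(fam_records)
        manifest["n_families"] = len(fam_records)

        strict_partner_counts = [
            sum(
                1 for n in graph_sig.neighbors(c)
                if graph_sig[c][n].get("strict")
            )
            if c in graph_sig
            else 0
            for c in large_ids
        ]
        manifest["mean_partners"] = (
            round(sum(strict_partner_counts) / len(strict_partner_counts), 3)
            if strict_partner_counts
            else 0.0
        )

        # 5. scenario inference ---------------------------------------------
        placement = car_placement(cars)
        clg_table = None
        events: List = []
        timeline = None
        pre1r_assignment = None
        if tetrads:
            car_by_id = {c.car_id: c for c in cars}
            car_families: Dict[str, Set[str]] = {
                c.car_id: {self.families.family_of(g) for g in c.genes}
                for c in cars
            }
            tetrad_families: Dict[str, Set[str]] = {
                t.tetrad_id: set().union(
                    *(car_families.get(m, set()) for m in t.members)
                )
                for t in tetrads
            }
            if self.clgs:
                clg_table = assign_tetrads_to_clgs(
                    tetrads, self.clgs, tetrad_families,
                    cfg.predominant_floor, cfg.predominant_ratio,
                    cfg.pre1r_fusion_threshold,
                )
            inter_events = classify_adjacent_tetrads(
                tetrads, self.clgs, car_families
            )
            all_genomes = self.clade_a + self.clade_b + self.outgroups
            member_cars = sorted({m for t in tetrads for m in t.members})
            hom_cars = [car_by_id[m] for m in member_cars if m in car_by_id]
            full_hom = car_homology(hom_cars, all_genomes, full_map)
            car_single = self._car_single(
                hom_cars, all_genomes, full_map, cfg.single_chromosome_frac
            )
            post2r_events = detect_post2r_fusions(
                tetrads, full_hom, car_single, self.divergence, self.epoch_order
            )
            split_reports = self._split_junction_cars(
                post2r_events, tetrads, car_by_id, consensus.pairs,
                placement, full_map,
            )
            manifest["n_junction_splits"] = sum(
                1 for r in split_reports if r["decision"].startswith("split")
            )
            dated_epochs = self._dated_epochs()
            pre1r_fusions = 0
            if clg_table is not None and not clg_table.empty:
                pre1r_fusions = int(
                    clg_table[clg_table.pre1r_fusion].tetrad_id.nunique()
                )
            timeline = build_timeline(
                len(tetrads), inter_events, post2r_events,
                pre1r_fusions=pre1r_fusions, dated_epochs=dated_epochs,
            )
            events = timeline.events
            ohno_genes = set(consensus.pairs.gene_a) | set(consensus.pairs.gene_b)
            pre1r_assignment = assign_genes_pre1r(
                self.families, tetrads, placement, ohno_genes
            )
            manifest.update(
                n_tetrads=len(tetrads),
                n_inter_wgd_fusions=sum(
                    1 for e in inter_events if e.type == "fusion_interWGD"
                ),
                n_inter_wgd_fissions=sum(
                    1 for e in inter_events if e.type == "fission"
                ),
                n_post2r_fusions=len(post2r_events),
                timeline={k: int(v) for k, v in timeline.counts.items()},
                n_pre1r_assigned=int(
                    (pre1r_assignment.status == "assigned").sum()
                ),
            )

        return KaryotypeResults(
            config=cfg,
            ancestral=ancestral,
            cars=cars,
            large_cars=large,
            car_statistics=stats,
            candidates=candidates,
            list_a=list_a,
            consensus=consensus.pairs,
            consensus_log=consensus.log,
            families_profile=profile,
            ohnolog_families=fam_records,
            matrix=matrix,
            partner_graph=graph_sig,
            tetrads=tetrads,
            merge_reports=merge_reports,
            clg_table=clg_table,
            events=events,
            timeline=timeline,
            pre1r_assignment=pre1r_assignment,
            manifest=manifest,
        )

    # ------------------------------------------------------------------
    def _split_junction_cars(
        self,
        post2r_events,
        tetrads: Sequence[Tetrad],
        car_by_id: Mapping[str, CAR],
        pairs: pd.DataFrame,
        placement: Mapping[str, Tuple[str, int]],
        full_map: Mapping[str, Mapping[str, List[str]]],
    ) -> List[dict]:
        """Split each post-2R fusion junction CAR into 'a'/'b' sub-CARs.

        Bookkeeping in the post-2R frame: the junction CAR keeps its fusion
        annotation, but the two halves are delimited where the dominant
        ohnolog-partner tetrad switches together with the second homology
        track — the linkage-group label of each gene's family when CLGs are
        available (a fusion predating every sampled lineage is a single
        chromosome in all of them, so descendant homology alone cannot see
        the junction), else the descendant-chromosome homology.  Reports
        are returned for the audit trail.
        """
        from .tetrads import split_car

        tetrad_of_car: Dict[str, List[str]] = {}
        for t in tetrads:
            for m in t.members:
                tetrad_of_car.setdefault(m, []).append(t.tetrad_id)
        partner_of: Dict[str, List[str]] = {}
        for row in pairs.itertuples():
            partner_of.setdefault(row.gene_a, []).append(row.car_b)
            partner_of.setdefault(row.gene_b, []).append(row.car_a)
        clg_of_family: Dict[str, str] = {}
        if self.clgs:
            for clg_id, fams in self.clgs.items():
                for f in fams:
                    clg_of_family[f] = clg_id
        ref = self.clade_a[0]
        chrom_of = ref.chromosome_of()
        reports: List[dict] = []
        for event in post2r_events:
            car = car_by_id.get(event.evidence.get("car"))
            if car is None:
                continue
            partner_track: List[Optional[str]] = []
            homology_track: List[Optional[str]] = []
            for gid in car.genes:
                tets: Counter = Counter()
                for pcar in partner_of.get(gid, ()):
                    for tid in tetrad_of_car.get(pcar, ()):
                        tets[tid] += 1
                partner_track.append(
                    tets.most_common(1)[0][0] if tets else None
                )
                if clg_of_family:
                    homology_track.append(
                        clg_of_family.get(self.families.family_of(gid))
                    )
                else:
                    exts = full_map.get(gid, {}).get(ref.name, ())
                    homology_track.append(
                        chrom_of.get(exts[0]) if exts else None
                    )
            _, report = split_car(
                car, partner_track, homology_track,
                window=self.config.split_window,
            )
            event.evidence["junction_split"] = report["decision"]
            reports.append(report)
        return reports

    def _descendant_map(
        self, ancestral: AncestralGenes
    ) -> Dict[str, Dict[str, List[str]]]:
        """Ancestral gene -> genome -> extant gene ids, over all genomes."""
        out: Dict[str, Dict[str, List[str]]] = {
            anc: dict(per) for anc, per in ancestral.descendants.items()
        }
        for genome in self.outgroups:
            for _, _, gene in genome.genes():
                anc = self.families.ancestor_at(
                    gene.gene_id, ancestral.target_epoch, self.epoch_order
                )
                if anc in out:
                    out[anc].setdefault(genome.name, []).append(gene.gene_id)
        return out

    def _dated_epochs(self) -> List[str]:
        """Stem epochs after the second WGD at which lineages diverge."""
        cut = epoch_index("2R", self.epoch_order)
        epochs = sorted(
            {
                e
                for e in self.divergence.values()
                if cut < epoch_index(e, self.epoch_order) < float("inf")
            },
            key=lambda e: epoch_index(e, self.epoch_order),
        )
        return epochs or ["euteleostomi", "amniota"]

    @staticmethod
    def _car_single(
        cars: Sequence[CAR],
        genomes: Sequence[Genome],
        descendant_of: Mapping[str, Mapping[str, List[str]]],
        frac: float,
    ) -> Dict[str, Dict[str, bool]]:
        """Whether each CAR maps to (mostly) one chromosome per genome."""
        chrom_maps = {g.name: g.chromosome_of() for g in genomes}
        out: Dict[str, Dict[str, bool]] = {}
        for car in cars:
            per: Dict[str, bool] = {}
            for gname, chrom_of in chrom_maps.items():
                tally: Counter = Counter()
                for anc in car.genes:
                    for ext in descendant_of.get(anc, {}).get(gname, ()):
                        if ext in chrom_of:
                            tally[chrom_of[ext]] += 1
                total = sum(tally.values())
                per[gname] = (
                    total > 0 and tally.most_common(1)[0][1] / total >= frac
                )
            out[car.car_id] = per
        return out
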