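"""Forward simulator of early vertebrate karyotype evolution.

The model: a pre-duplication chordate genome evolves through two successive
whole-genome duplications (1R, 2R), with chromosome fusions between and
after the WGDs, duplicate gene loss (rediploidisation), and
lineage-specific inversions and reciprocal translocations on the branches
leading to extant descendants.  Every stochastic operation records the
realised events so the whole history can be replayed deterministically and
used as ground truth for recovery tests.

All operations are pure: they return new :class:`~paleokaryo.genome.Genome`
objects (and, where copies are created, a new
:class:`~paleokaryo.families.FamilyTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .families import STEM_EPOCHS, FamilyTable
from .genome import Gene, Genome

__all__ = [
    "SimEvent",
    "TrueHistory",
    "BranchSpec",
    "ScenarioConfig",
    "ScenarioData",
    "simulate_pre1r",
    "apply_wgd",
    "apply_fusion",
    "apply_fission",
    "apply_gene_loss",
    "apply_rearrangements",
    "apply_n_rearrangements",
    "apply_inversion",
    "apply_translocation",
    "remove_genes",
    "evolve_descendants",
    "simulate_scenario",
    "replay",
]


# ---------------------------------------------------------------------------
# Event recording
# ---------------------------------------------------------------------------


@dataclass
class SimEvent:
    """A replayable primitive event.

    ``target`` names the genome the event applies to ("stem" or a branch
    name); ``params`` holds the realised, fully deterministic parameters.
    A ``snapshot`` event marks the point where a stem stage was recorded.
    """

    kind: str  # wgd|fusion|fission|loss|inversion|translocation|branch|snapshot
    epoch: str
    target: str
    params: dict


@dataclass
class TrueHistory:
    """Ground truth of a simulation: events, snapshots and ancestry maps."""

    events: List[SimEvent] = field(default_factory=list)
    snapshots: Dict[str, Genome] = field(default_factory=dict)
    #: chromosome -> frozenset of pre-1R chromosomes it carries material of
    pre1r_origin: Dict[str, frozenset] = field(default_factory=dict)
    #: chromosome -> frozenset of chordate chromosomes (for CLG ground truth)
    chordate_origin: Dict[str, frozenset] = field(default_factory=dict)
    chromosome_counts: Dict[str, int] = field(default_factory=dict)

    def true_tetrads(self, epoch: str = "post2R") -> Dict[str, List[str]]:
        """pre-1R chromosome -> chromosomes of ``epoch`` carrying its material."""
        genome = self.snapshots[epoch]
        tetrads: Dict[str, List[str]] = {}
        for chrom in genome.chromosomes:
            for origin in sorted(self.pre1r_origin[chrom]):
                tetrads.setdefault(origin, []).append(chrom)
        return tetrads


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

SamplerSpec = Union[int, Tuple[int, int], Callable[[np.random.Generator], int]]


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_count(sampler: SamplerSpec, rng: np.random.Generator) -> int:
    if isinstance(sampler, (int, np.integer)):
        n = int(sampler)
    elif isinstance(sampler, tuple):
        lo, hi = sampler
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(sampler(rng))
    if n <= 0:
        raise ValueError(f"gene count sampler produced non-positive count {n}")
    return n


def simulate_pre1r(
    n_chromosomes: int,
    gene_count_sampler: SamplerSpec,
    seed: Union[int, np.random.Generator],
    epoch: str = "pre1R",
    name: str = "pre1R",
) -> Tuple[Genome, FamilyTable]:
    """Draw a pre-duplication genome of single-copy families.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes (>= 1).
    gene_count_sampler
        Genes per chromosome: a constant, an inclusive ``(low, high)``
        uniform range, or a callable taking the RNG.
    seed
        Integer seed or a numpy Generator (shared generators advance).
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = _rng(seed)
    families = FamilyTable()
    chromosomes: Dict[str, List[Gene]] = {}
    k = 0
    for c in range(n_chromosomes):
        chrom = f"C{c + 1:02d}"
        n = _draw_count(gene_count_sampler, rng)
        genes = []
        for _ in range(n):
            fam = f"f{k:05d}"
            families.add_root(fam)
            strand = 1 if rng.random() < 0.5 else -1
            genes.append(Gene(fam, fam, strand))
            k += 1
        chromosomes[chrom] = genes
    return Genome(name, epoch, chromosomes), families


def apply_wgd(
    genome: Genome,
    families: FamilyTable,
    epoch: str,
    new_epoch: Optional[str] = None,
) -> Tuple[Genome, FamilyTable]:
    """Duplicate every chromosome and gene; record duplications at ``epoch``.

    Each gene copy ``x`` is replaced by children ``x.a`` / ``x.b`` placed on
    sister chromosomes ``<chrom>_1`` / ``<chrom>_2`` in the original order.
    """
    if genome.n_genes == 0 or genome.n_chromosomes == 0:
        raise ValueError("cannot duplicate an empty genome")
    fam = families.copy()
    chromosomes: Dict[str, List[Gene]] = {}
    for chrom, genes in genome.chromosomes.items():
        a_genes, b_genes = [], []
        for g in genes:
            ca, cb = g.gene_id + ".a", g.gene_id + ".b"
            fam.add_duplication(g.gene_id, [ca, cb], epoch)
            a_genes.append(Gene(ca, g.family_id, g.strand))
            b_genes.append(Gene(cb, g.family_id, g.strand))
        chromosomes[chrom + "_1"] = a_genes
        chromosomes[chrom + "_2"] = b_genes
    return Genome(genome.name, new_epoch or genome.epoch, chromosomes), fam


def apply_fusion(
    genome: Genome, chr_a: str, chr_b: str, join_policy: str = "head_tail"
) -> Genome:
    """Fuse two chromosomes into one named ``A+B``.

    Join policies describe how the two gene orders meet: ``head_tail`` keeps
    both orientations (A then B), ``head_head`` appends B reversed with
    flipped strands, ``tail_tail`` prepends A reversed.
    """
    if chr_a == chr_b:
        raise ValueError("cannot fuse a chromosome with itself")
    for c in (chr_a, chr_b):
        if c not in genome.chromosomes:
            raise KeyError(f"unknown chromosome {c!r}")
    a = genome.chromosomes[chr_a]
    b = genome.chromosomes[chr_b]
    if join_policy == "head_tail":
        merged = a + b
    elif join_policy == "head_head":
        merged = a + [g.flipped() for g in reversed(b)]
    elif join_policy == "tail_tail":
        merged = [g.flipped() for g in reversed(a)] + b
    else:
        raise ValueError(f"unknown join policy {join_policy!r}")
    chromosomes = {
        c: genes
        for c, genes in genome.chromosomes.items()
        if c not in (chr_a, chr_b)
    }
    chromosomes[f"{chr_a}+{chr_b}"] = merged
    return Genome(genome.name, genome.epoch, chromosomes)


def apply_fission(genome: Genome, chrom: str, breakpoint_index: int) -> Genome:
    """Split ``chrom`` before ``breakpoint_index`` into ``<chrom>_p`` / ``<chrom>_q``."""
    genes = genome.chromosomes.get(chrom)
    if genes is None:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 < breakpoint_index < len(genes):
        raise ValueError(
            f"breakpoint {breakpoint_index} out of range for {chrom!r} "
            f"of {len(genes)} genes"
        )
    chromosomes = {c: g for c, g in genome.chromosomes.items() if c != chrom}
    chromosomes[chrom + "_p"] = genes[:breakpoint_index]
    chromosomes[chrom + "_q"] = genes[breakpoint_index:]
    return Genome(genome.name, genome.epoch, chromosomes)


def apply_gene_loss(
    genome: Genome,
    retention_rate: float,
    seed: Union[int, np.random.Generator],
    removed_out: Optional[List[str]] = None,
) -> Genome:
    """Lose duplicate copies independently with probability ``1 - retention_rate``.

    Families present in a single copy are untouched; if all copies of a
    family would be lost, one survivor is kept (total family extinction is
    orthogonal to the karyotype question).  Realised losses are appended to
    ``removed_out`` when given.
    """
    if not 0.0 <= retention_rate <= 1.0:
        raise ValueError("retention_rate must lie in [0, 1]")
    rng = _rng(seed)
    by_family: Dict[str, List[str]] = {}
    for _, _, g in genome.genes():
        by_family.setdefault(g.family_id, []).append(g.gene_id)
    removed: set[str] = set()
    for fam in sorted(by_family):
        copies = by_family[fam]
        if len(copies) < 2:
            continue
        keep = rng.random(len(copies)) < retention_rate
        if not keep.any():
            keep[int(rng.integers(len(copies)))] = True
        for cid, k in zip(copies, keep):
            if not k:
                removed.add(cid)
    if removed_out is not None:
        removed_out.extend(sorted(removed))
    return remove_genes(genome, removed)


def remove_genes(genome: Genome, gene_ids) -> Genome:
    """Drop the given genes and re-compact indices; empty chromosomes vanish."""
    drop = set(gene_ids)
    chromosomes = {}
    for chrom, genes in genome.chromosomes.items():
        kept = [g for g in genes if g.gene_id not in drop]
        if kept:
            chromosomes[chrom] = kept
    return Genome(genome.name, genome.epoch, chromosomes)


def apply_inversion(genome: Genome, chrom: str, start: int, end: int) -> Genome:
    """Reverse the half-open gene run [start, end) and flip its strands."""
    genes = genome.chromosomes[chrom]
    if not (0 <= start < end <= len(genes)):
        raise ValueError(f"invalid inversion span [{start}, {end}) on {chrom!r}")
    new = (
        genes[:start]
        + [g.flipped() for g in reversed(genes[start:end])]
        + genes[end:]
    )
    chromosomes = dict(genome.chromosomes)
    chromosomes[chrom] = new
    return Genome(genome.name, genome.epoch, chromosomes)


def apply_translocation(
    genome: Genome, chr_a: str, break_a: int, chr_b: str, break_b: int
) -> Genome:
    """Reciprocal translocation: swap the tails of two chromosomes."""
    if chr_a == chr_b:
        raise ValueError("translocation requires two distinct chromosomes")
    a = genome.chromosomes[chr_a]
    b = genome.chromosomes[chr_b]
    if not (0 < break_a < len(a)) or not (0 < break_b < len(b)):
        raise ValueError("translocation breakpoints out of range")
    chromosomes = dict(genome.chromosomes)
    chromosomes[chr_a] = a[:break_a] + b[break_b:]
    chromosomes[chr_b] = b[:break_b] + a[break_a:]
    return Genome(genome.name, genome.epoch, chromosomes)


def apply_rearrangements(
    genome: Genome,
    inversion_rate: float,
    translocation_rate: float,
    seed: Union[int, np.random.Generator],
    mean_span: int = 8,
    events_out: Optional[List[SimEvent]] = None,
    target: str = "stem",
) -> Genome:
    """Apply Poisson numbers of inversions and reciprocal translocations.

    Rates are per gene: the expected event counts are ``rate * n_genes``.
    Inversion spans are geometric with the given mean.  Gene content is
    conserved exactly.
    """
    if inversion_rate < 0 or translocation_rate < 0:
        raise ValueError("rearrangement rates must be non-negative")
    rng = _rng(seed)
    n_inv = int(rng.poisson(inversion_rate * genome.n_genes))
    n_tra = int(rng.poisson(translocation_rate * genome.n_genes))
    return apply_n_rearrangements(
        genome, n_inv, n_tra, rng, mean_span=mean_span,
        events_out=events_out, target=target,
    )


def apply_n_rearrangements(
    genome: Genome,
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator,
    mean_span: int = 8,
    events_out: Optional[List[SimEvent]] = None,
    target: str = "stem",
) -> Genome:
    """Apply fixed numbers of inversions / translocations at random positions.

    Inversion sites are drawn proportionally to chromosome length; spans are
    geometric (mean ``mean_span``) clipped at the chromosome end.
    """
    g = genome
    ops = ["inv"] * n_inversions + ["tra"] * n_translocations
    for op in ops:
        chroms = sorted(g.chromosomes)
        lengths = np.array([len(g.chromosomes[c]) for c in chroms], dtype=float)
        if op == "inv":
            c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
            L = len(g.chromosomes[c])
            start = int(rng.integers(0, L))
            span = min(L - start, 1 + int(rng.geometric(1.0 / mean_span)))
            g = apply_inversion(g, c, start, start + span)
            if events_out is not None:
                events_out.append(
                    SimEvent("inversion", g.epoch, target,
                             {"chrom": c, "start": start, "end": start + span})
                )
        else:
            eligible = [c for c in chroms if len(g.chromosomes[c]) >= 2]
            if len(eligible) < 2:
                continue
            ia, ib = (int(i) for i in rng.choice(len(eligible), 2, replace=False))
            ca, cb = eligible[ia], eligible[ib]
            ba = int(rng.integers(1, len(g.chromosomes[ca])))
            bb = int(rng.integers(1, len(g.chromosomes[cb])))
            g = apply_translocation(g, ca, ba, cb, bb)
            if events_out is not None:
                events_out.append(
                    SimEvent("translocation", g.epoch, target,
                             {"chr_a": ca, "break_a": ba,
                              "chr_b": cb, "break_b": bb})
                )
    return g


# ---------------------------------------------------------------------------
# Descendant lineages
# ---------------------------------------------------------------------------


@dataclass
class BranchSpec:
    """A terminal branch of the lineage tree.

    ``divergence`` is the stem epoch at which the branch leaves the stem;
    ``clade`` groups descendants of the target ancestor ("A"/"B"), with
    "outgroup" for lineages that diverged earlier.
    """

    name: str
    clade: str
    divergence: str = "amniota"
    n_inversions: int = 2
    n_translocations: int = 1
    retention: float = 1.0  # extra lineage-specific duplicate retention


def _evolve_branch(
    ancestor: Genome,
    spec: BranchSpec,
    rng: np.random.Generator,
    mean_span: int,
    history: Optional[TrueHistory],
    source_label: str,
) -> Genome:
    g = ancestor.copy(name=spec.name, epoch=spec.name)
    if history is not None:
        history.events.append(
            SimEvent("branch", source_label, spec.name, {"source": source_label})
        )
    if spec.retention < 1.0:
        removed: List[str] = []
        g = apply_gene_loss(g, spec.retention, rng, removed_out=removed)
        if history is not None:
            history.events.append(
                SimEvent("loss", spec.name, spec.name, {"removed": removed})
            )
    events = history.events if history is not None else None
    g = apply_n_rearrangements(
        g, spec.n_inversions, spec.n_translocations, rng,
        mean_span=mean_span, events_out=events, target=spec.name,
    )
    if history is not None:
        history.snapshots[spec.name] = g
    return g


def evolve_descendants(
    ancestor: Genome,
    branches: Sequence[BranchSpec],
    seed: Union[int, np.random.Generator],
    mean_span: int = 8,
    history: Optional[TrueHistory] = None,
) -> Dict[str, Genome]:
    """Evolve independent descendant genomes from an ancestor.

    Requires at least one branch in each of clades "A" and "B" and at least
    two branches overall: the adjacency-graph conservation weighting needs
    genomes descending independently on both sides of the target ancestor.
    """
    if len(branches) < 2:
        raise ValueError("a lineage tree needs at least two descendant branches")
    per_clade: Dict[str, int] = {}
    for b in branches:
        per_clade[b.clade] = per_clade.get(b.clade, 0) + 1
    for clade in ("A", "B"):
        if per_clade.get(clade, 0) < 1:
            raise ValueError(f"no descendant branch in clade {clade!r}")
    rng = _rng(seed)
    return {
        b.name: _evolve_branch(
            ancestor, b, rng, mean_span, history, ancestor.epoch
        )
        for b in branches
    }


# ---------------------------------------------------------------------------
# Whole-scenario simulation
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Study conditions for a full simulated history.

    The defaults are the inferred vertebrate scenario at desk scale: a
    17-chromosome pre-1R genome of roughly 60 genes per chromosome, 1R,
    seven inter-WGD fusions, 2R, four fusions dated before the bony
    vertebrate ancestor and one more before the amniote ancestor, ~35%
    duplicate retention during rediploidisation, and mild lineage-specific
    rearrangement on each terminal branch.
    """

    n_chordate_chromosomes: int = 17
    genes_per_chromosome: SamplerSpec = (50, 70)
    pre1r_fusions: int = 0
    n_wgds: int = 2
    inter_wgd_fusions: int = 7
    inter_wgd_fissions: int = 0
    post2r_fusions_early: int = 4  # dated 2R -> euteleostomi
    post2r_fusions_late: int = 1  # dated euteleostomi -> amniota
    retention: float = 0.35
    n_per_clade: int = 2
    n_outgroups: int = 2
    branch_inversions: int = 2
    branch_translocations: int = 1
    inversion_mean_span: int = 8
    include_fragmented: bool = False
    fragment_fissions: int = 60  # scaffold-making fissions on the fragmented branch
    fragmented_retention: float = 0.35


@dataclass
class ScenarioData:
    """Everything a pipeline run needs, plus ground truth."""

    config: ScenarioConfig
    families: FamilyTable
    clade_a: List[Genome]
    clade_b: List[Genome]
    outgroups: List[Genome]
    fragmented: Optional[Genome]
    ancestor: Genome  # the reconstruction target (amniote-level)
    clgs: Dict[str, frozenset]  # linkage-group id -> family ids
    divergence: Dict[str, str]  # genome name -> stem epoch of divergence
    history: TrueHistory
    epoch_order: Tuple[str, ...] = STEM_EPOCHS

    @property
    def descendants(self) -> List[Genome]:
        return self.clade_a + self.clade_b


def _choose_fusion_plan(
    rng: np.random.Generator,
    chrom_origin: Dict[str, str],  # chromosome -> pre-1R origin
    n_fusions: int,
) -> List[Tuple[str, str]]:
    """Pick inter-WGD fusion pairs: distinct pre-1R origin pairs, each
    chromosome fused at most once, each pre-1R chromosome used at most once.

    The constraints keep every event separately resolvable downstream, which
    is the configuration the inferred history itself displays.
    """
    origins = sorted(set(chrom_origin.values()))
    if 2 * n_fusions > len(origins):
        raise ValueError(
            f"{n_fusions} fusions need {2 * n_fusions} distinct origins, "
            f"have {len(origins)}"
        )
    chosen = rng.choice(len(origins), size=2 * n_fusions, replace=False)
    pairs = []
    for i in range(n_fusions):
        oa, ob = origins[int(chosen[2 * i])], origins[int(chosen[2 * i + 1])]
        cands_a = sorted(c for c, o in chrom_origin.items() if o == oa)
        cands_b = sorted(c for c, o in chrom_origin.items() if o == ob)
        pairs.append(
            (
                cands_a[int(rng.integers(len(cands_a)))],
                cands_b[int(rng.integers(len(cands_b)))],
            )
        )
    return pairs


def simulate_scenario(
    config: Optional[ScenarioConfig] = None,
    seed: int = 0,
) -> ScenarioData:
    """Simulate the full inferred history and emit descendants + ground truth.

    The stem runs chordate -> (optional chordate-epoch fusions) -> 1R ->
    inter-WGD fusions -> 2R -> rediploidisation -> early post-2R fusions
    (bony-vertebrate ancestor) -> late fusion (amniote ancestor); descendant
    clades A and B split at the target ancestor, outgroups at the
    bony-vertebrate ancestor, and an optional fragmented (cyclostome-like)
    lineage right after the WGDs with independent duplicate loss.
    """
    cfg = config or ScenarioConfig()
    ss = np.random.SeedSequence(seed)
    r_genome, r_plan, r_loss, r_branch, r_frag = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    hist = TrueHistory()

    def stem_snapshot(label: str, genome: Genome) -> None:
        hist.snapshots[label] = genome
        hist.events.append(SimEvent("snapshot", label, "stem", {"label": label}))

    # chordate genome and linkage groups -----------------------------------
    genome, families = simulate_pre1r(
        cfg.n_chordate_chromosomes,
        cfg.genes_per_chromosome,
        r_genome,
        epoch="chordate",
        name="stem",
    )
    hist.snapshots["chordate"] = genome
    clgs = {
        f"CLG{i + 1:02d}": frozenset(g.family_id for g in genes)
        for i, (chrom, genes) in enumerate(genome.chromosomes.items())
    }
    chord_origin = {c: frozenset([c]) for c in genome.chromosomes}

    # optional chordate-epoch fusion(s) ------------------------------------
    for _ in range(cfg.pre1r_fusions):
        chroms = sorted(genome.chromosomes)
        ia, ib = (int(i) for i in r_plan.choice(len(chroms), 2, replace=False))
        a, b = chroms[ia], chroms[ib]
        genome = apply_fusion(genome, a, b)
        chord_origin[f"{a}+{b}"] = chord_origin.pop(a) | chord_origin.pop(b)
        hist.events.append(
            SimEvent("fusion", "pre1R", "stem", {"chr_a": a, "chr_b": b})
        )
    genome = genome.copy(epoch="pre1R")
    stem_snapshot("pre1R", genome)
    pre1r_origin = {c: frozenset([c]) for c in genome.chromosomes}

    # 1R --------------------------------------------------------------------
    genome, families = apply_wgd(genome, families, "1R", new_epoch="post1R")
    hist.events.append(SimEvent("wgd", "1R", "stem", {}))
    stem_snapshot("post1R", genome)
    pre1r_origin = {c: pre1r_origin[c.rsplit("_", 1)[0]] for c in genome.chromosomes}
    chord_origin = {c: chord_origin[c.rsplit("_", 1)[0]] for c in genome.chromosomes}

    # inter-WGD fusions ------------------------------------------------------
    inter_pairs: set = set()
    if cfg.n_wgds >= 2 and cfg.inter_wgd_fusions:
        single_origin = {c: sorted(pre1r_origin[c])[0] for c in genome.chromosomes}
        for a, b in _choose_fusion_plan(r_plan, single_origin, cfg.inter_wgd_fusions):
            genome = apply_fusion(genome, a, b)
            merged = f"{a}+{b}"
            inter_pairs.add(frozenset(pre1r_origin[a] | pre1r_origin[b]))
            pre1r_origin[merged] = pre1r_origin.pop(a) | pre1r_origin.pop(b)
            chord_origin[merged] = chord_origin.pop(a) | chord_origin.pop(b)
            hist.events.append(
                SimEvent("fusion", "inter1R2R", "stem", {"chr_a": a, "chr_b": b})
            )
    if cfg.n_wgds >= 2 and cfg.inter_wgd_fissions:
        for _ in range(cfg.inter_wgd_fissions):
            singles = sorted(
                c for c in genome.chromosomes
                if len(pre1r_origin[c]) == 1 and len(genome.chromosomes[c]) >= 10
            )
            c = singles[int(r_plan.integers(len(singles)))]
            L = len(genome.chromosomes[c])
            k = int(r_plan.integers(L // 3, 2 * L // 3 + 1))
            genome = apply_fission(genome, c, k)
            for part in (c + "_p", c + "_q"):
                pre1r_origin[part] = pre1r_origin[c]
                chord_origin[part] = chord_origin[c]
            del pre1r_origin[c], chord_origin[c]
            hist.events.append(
                SimEvent("fission", "inter1R2R", "stem", {"chrom": c, "breakpoint": k})
            )
    genome = genome.copy(epoch="inter1R2R")
    stem_snapshot("inter1R2R", genome)

    # 2R --------------------------------------------------------------------
    if cfg.n_wgds >= 2:
        genome, families = apply_wgd(genome, families, "2R", new_epoch="post2R")
        hist.events.append(SimEvent("wgd", "2R", "stem", {}))
        pre1r_origin = {
            c: pre1r_origin[c.rsplit("_", 1)[0]] for c in genome.chromosomes
        }
        chord_origin = {
            c: chord_origin[c.rsplit("_", 1)[0]] for c in genome.chromosomes
        }
    else:
        genome = genome.copy(epoch="post2R")
    stem_snapshot("post2R", genome)
    hist.pre1r_origin.update(pre1r_origin)
    hist.chordate_origin.update(chord_origin)

    # fragmented lineage (cyclostome-like): diverges right after the WGDs,
    # loses duplicates independently and fragments into scaffolds
    fragmented: Optional[Genome] = None
    if cfg.include_fragmented:
        frag = genome.copy(name="fragmented", epoch="fragmented")
        hist.events.append(
            SimEvent("branch", "post2R", "fragmented", {"source": "post2R"})
        )
        removed: List[str] = []
        frag = apply_gene_loss(
            frag, cfg.fragmented_retention, r_frag, removed_out=removed
        )
        hist.events.append(
            SimEvent("loss", "fragmented", "fragmented", {"removed": removed})
        )
        for _ in range(cfg.fragment_fissions):
            cands = sorted(
                c for c in frag.chromosomes if len(frag.chromosomes[c]) >= 4
            )
            if not cands:
                break
            weights = np.array(
                [len(frag.chromosomes[c]) for c in cands], dtype=float
            )
            c = cands[int(r_frag.choice(len(cands), p=weights / weights.sum()))]
            k = int(r_frag.integers(2, len(frag.chromosomes[c]) - 1))
            frag = apply_fission(frag, c, k)
            hist.events.append(
                SimEvent("fission", "fragmented", "fragmented",
                         {"chrom": c, "breakpoint": k})
            )
        frag = apply_n_rearrangements(
            frag, cfg.branch_inversions, 0, r_frag,
            mean_span=cfg.inversion_mean_span,
            events_out=hist.events, target="fragmented",
        )
        fragmented = frag
        hist.snapshots["fragmented"] = frag

    # rediploidisation on the stem ------------------------------------------
    removed: List[str] = []
    genome = apply_gene_loss(genome, cfg.retention, r_loss, removed_out=removed)
    genome = genome.copy(epoch="vertebrata")
    hist.events.append(SimEvent("loss", "vertebrata", "stem", {"removed": removed}))
    stem_snapshot("vertebrata", genome)

    # dated post-2R fusions ---------------------------------------------------
    used_origins: set = set()

    def _post2r_fusions(n: int, epoch: str) -> Genome:
        g = genome
        for _ in range(n):
            singles = sorted(
                c
                for c in g.chromosomes
                if len(hist.pre1r_origin[c]) == 1
                and not (hist.pre1r_origin[c] & used_origins)
            )
            for _attempt in range(200):
                ia, ib = (int(i) for i in r_plan.choice(len(singles), 2, replace=False))
                a, b = singles[ia], singles[ib]
                # distinct pre-1R origins, and not a pair of chromosomes whose
                # tetrads are already adjacent via an inter-WGD fusion: each
                # event must leave a separately resolvable sharing pattern
                pair = frozenset(hist.pre1r_origin[a] | hist.pre1r_origin[b])
                if (
                    hist.pre1r_origin[a] != hist.pre1r_origin[b]
                    and pair not in inter_pairs
                ):
                    break
            else:  # pragma: no cover - plan infeasible
                raise ValueError("could not draw a valid post-2R fusion pair")
            g = apply_fusion(g, a, b)
            merged = f"{a}+{b}"
            hist.pre1r_origin[merged] = hist.pre1r_origin[a] | hist.pre1r_origin[b]
            hist.chordate_origin[merged] = (
                hist.chordate_origin[a] | hist.chordate_origin[b]
            )
            used_origins.update(hist.pre1r_origin[merged])
            hist.events.append(
                SimEvent("fusion", epoch, "stem", {"chr_a": a, "chr_b": b})
            )
        return g

    if cfg.n_wgds >= 2:
        genome = _post2r_fusions(cfg.post2r_fusions_early, "euteleostomi")
    genome = genome.copy(epoch="euteleostomi")
    stem_snapshot("euteleostomi", genome)

    # outgroups diverge at the bony-vertebrate ancestor
    outgroups: List[Genome] = []
    for i in range(cfg.n_outgroups):
        spec = BranchSpec(
            f"outgroup{i + 1}", "outgroup", "euteleostomi",
            cfg.branch_inversions, cfg.branch_translocations,
        )
        outgroups.append(
            _evolve_branch(
                genome, spec, r_branch, cfg.inversion_mean_span, hist,
                "euteleostomi",
            )
        )

    if cfg.n_wgds >= 2:
        genome = _post2r_fusions(cfg.post2r_fusions_late, "amniota")
    genome = genome.copy(epoch="amniota", name="amniota")
    stem_snapshot("amniota", genome)

    # terminal descendant clades ---------------------------------------------
    desc_branches = [
        BranchSpec(
            f"{'a' if clade == 'A' else 'b'}{i + 1}", clade, "amniota",
            cfg.branch_inversions, cfg.branch_translocations,
        )
        for clade in ("A", "B")
        for i in range(cfg.n_per_clade)
    ]
    desc = evolve_descendants(
        genome, desc_branches, r_branch,
        mean_span=cfg.inversion_mean_span, history=hist,
    )
    clade_a = [desc[b.name] for b in desc_branches if b.clade == "A"]
    clade_b = [desc[b.name] for b in desc_branches if b.clade == "B"]

    divergence = {g.name: "amniota" for g in clade_a + clade_b}
    for g in outgroups:
        divergence[g.name] = "euteleostomi"
    if fragmented is not None:
        divergence[fragmented.name] = "vertebrata"

    for label, snap in hist.snapshots.items():
        hist.chromosome_counts[label] = snap.n_chromosomes

    return ScenarioData(
        config=cfg,
        families=families,
        clade_a=clade_a,
        clade_b=clade_b,
        outgroups=outgroups,
        fragmented=fragmented,
        ancestor=genome,
        clgs=clgs,
        divergence=divergence,
        history=hist,
        epoch_order=STEM_EPOCHS,
    )


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------


def replay(history: TrueHistory) -> Dict[str, Genome]:
    """Re-apply recorded events from the chordate genome.

    Returns reproduced genomes keyed like ``history.snapshots`` (stem stages
    under their epoch labels, branches under their names).  The replay
    invariant states these equal the recorded snapshots gene-for-gene.
    """
    genome = history.snapshots["chordate"].copy()
    families = FamilyTable()
    for _, _, g in genome.genes():
        families.add_root(g.family_id, g.gene_id)
    current: Dict[str, Genome] = {"stem": genome}
    produced: Dict[str, Genome] = {"chordate": genome.copy()}
    for ev in history.events:
        if ev.kind == "snapshot":
            produced[ev.params["label"]] = current["stem"].copy()
            continue
        if ev.kind == "branch":
            current[ev.target] = current["stem"].copy(
                name=ev.target, epoch=ev.target
            )
            continue
        g = current[ev.target]
        if ev.kind == "wgd":
            g, families = apply_wgd(g, families, ev.epoch)
        elif ev.kind == "fusion":
            g = apply_fusion(g, ev.params["chr_a"], ev.params["chr_b"])
        elif ev.kind == "fission":
            g = apply_fission(g, ev.params["chrom"], ev.params["breakpoint"])
        elif ev.kind == "loss":
            g = remove_genes(g, ev.params["removed"])
        elif ev.kind == "inversion":
            g = apply_inversion(
                g, ev.params["chrom"], ev.params["start"], ev.params["end"]
            )
        elif ev.kind == "translocation":
            g = apply_translocation(
                g, ev.params["chr_a"], ev.params["break_a"],
                ev.params["chr_b"], ev.params["break_b"],
            )
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown event kind {ev.kind!r}")
        current[ev.target] = g
    for name, g in current.items():
        if name != "stem":
            produced[name] = g
    return produced
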