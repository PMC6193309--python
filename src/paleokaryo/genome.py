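"""Core containers for gene-order data.

A :class:`Genome` is an ordered arrangement of genes on named chromosomes.
Gene order is implicit in list position (0-based); strands are +1/-1.
Gene identifiers double as family-copy identifiers, which is how a genome
connects to the gene-family table (:mod:`paleokaryo.families`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple


@dataclass(frozen=True)
class Gene:
    """A gene placed on a chromosome.

    Parameters
    ----------
    gene_id
        Unique identifier within a genome.  In simulated data this is the
        family-copy identifier, so the same gene in two descendant genomes
        shares its id.
    family_id
        Identifier of the gene family (ancestral lineage) the gene belongs to.
    strand
        Reading orientation, +1 (forward) or -1 (reverse).
    """

    gene_id: str
    family_id: str
    strand: int = 1

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")

    def flipped(self) -> "Gene":
        return replace(self, strand=-self.strand)


class Genome:
    """Ordered gene lists on named chromosomes.

    Chromosomes preserve insertion order; within a chromosome, gene order is
    list order.  All mutating evolutionary operations live in
    :mod:`paleokaryo.sim` and return new genomes.
    """

    def __init__(
        self,
        name: str,
        epoch: str,
        chromosomes: Mapping[str, Sequence[Gene]],
    ) -> None:
        self.name = name
        self.epoch = epoch
        self.chromosomes: Dict[str, List[Gene]] = {
            c: list(genes) for c, genes in chromosomes.items()
        }
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            if len(genes) == 0:
                raise ValueError(f"chromosome {chrom!r} is empty")
            for g in genes:
                if g.gene_id in seen:
                    raise ValueError(f"duplicated gene id {g.gene_id!r}")
                seen.add(g.gene_id)

    # -- basic queries ----------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def genes(self) -> Iterator[Tuple[str, int, Gene]]:
        """Yield (chromosome, index, gene) in genome order."""
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                yield chrom, i, g

    def gene_ids(self) -> set[str]:
        return {g.gene_id for _, _, g in self.genes()}

    def chromosome_of(self) -> Dict[str, str]:
        """Map gene_id -> chromosome name."""
        return {g.gene_id: c for c, _, g in self.genes()}

    def copy(self, name: str | None = None, epoch: str | None = None) -> "Genome":
        return Genome(
            name if name is not None else self.name,
            epoch if epoch is not None else self.epoch,
            {c: list(gs) for c, gs in self.chromosomes.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.name == other.name
            and self.epoch == other.epoch
            and list(self.chromosomes) == list(other.chromosomes)
            and all(
                self.chromosomes[c] == other.chromosomes[c] for c in self.chromosomes
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Genome {self.name!r} epoch={self.epoch!r} "
            f"{self.n_chromosomes} chromosomes, {self.n_genes} genes>"
        )


def adjacency_set(
    order: Sequence[str],
) -> set[frozenset]:
    """Unordered immediate-neighbour pairs of a sequence of gene ids."""
    return {
        frozenset((order[i], order[i + 1]))
        for i in range(len(order) - 1)
        if order[i] != order[i + 1]
    }


def genome_from_records(
    name: str,
    epoch: str,
    records: Iterable[Tuple[str, int, int, str, str]],
) -> Genome:
    """Build a genome from (chromosome, index, strand, gene_id, family_id) rows.

    Rows may arrive unsorted; indices on each chromosome must be exactly
    0..L-1 with no gaps or duplicates.
    """
    by_chrom: Dict[str, Dict[int, Gene]] = {}
    for chrom, idx, strand, gid, fid in records:
        slot = by_chrom.setdefault(chrom, {})
        if idx in slot:
            raise ValueError(f"duplicated index {idx} on chromosome {chrom!r}")
        slot[idx] = Gene(gid, fid, strand)
    chromosomes: Dict[str, List[Gene]] = {}
    for chrom in sorted(by_chrom):
        slots = by_chrom[chrom]
        if sorted(slots) != list(range(len(slots))):
            raise ValueError(
                f"indices on chromosome {chrom!r} are not consecutive from 0"
            )
        chromosomes[chrom] = [slots[i] for i in range(len(slots))]
    return Genome(name, epoch, chromosomes)
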