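"""Gene-family copy trees with epoch-labelled duplication events.

Each gene family is a tree of *copies* rooted at a single pre-duplication
gene.  A whole-genome duplication replaces every live copy by two children
tagged with the duplication epoch ("1R", "2R", or a lineage label for
small-scale events).  Extant genes are leaves; ancestral genes at a target
epoch are the copies alive at that epoch.

Epoch labels are ordered by :data:`STEM_EPOCHS` (the stem lineage from the
chordate ancestor to the reconstruction target).  Labels not on the stem are
treated as post-ancestral (lineage-specific).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

#: Default stem-lineage epoch order, oldest first.  "1R"/"2R" are the two
#: whole-genome duplications; "vertebrata" is the immediate post-2R ancestor,
#: followed by the bony-vertebrate and amniote ancestors.
STEM_EPOCHS: Tuple[str, ...] = (
    "chordate",
    "pre1R",
    "1R",
    "inter1R2R",
    "2R",
    "vertebrata",
    "euteleostomi",
    "amniota",
)


def epoch_index(epoch: Optional[str], order: Sequence[str] = STEM_EPOCHS) -> float:
    """Position of an epoch on the stem; +inf for off-stem (lineage) labels.

    ``None`` (the root copy, which predates all duplications) maps to -inf.
    """
    if epoch is None:
        return -math.inf
    try:
        return float(order.index(epoch))
    except ValueError:
        return math.inf


@dataclass
class FamilyCopy:
    copy_id: str
    family_id: str
    parent: Optional[str]  # None for the founder copy
    epoch: Optional[str]  # epoch of the duplication that created this copy

    def __post_init__(self) -> None:
        if self.parent is None and self.epoch is not None:
            raise ValueError("founder copy cannot carry a duplication epoch")


class FamilyTable:
    """All family copy trees of a simulation or dataset."""

    def __init__(self) -> None:
        self.copies: Dict[str, FamilyCopy] = {}
        self._children: Dict[str, List[str]] = {}

    # -- construction -----------------------------------------------------
    def add_root(self, family_id: str, copy_id: Optional[str] = None) -> str:
        cid = copy_id if copy_id is not None else family_id
        if cid in self.copies:
            raise ValueError(f"copy id {cid!r} already present")
        self.copies[cid] = FamilyCopy(cid, family_id, None, None)
        self._children[cid] = []
        return cid

    def add_duplication(
        self, parent_copy: str, child_ids: Sequence[str], epoch: str
    ) -> None:
        """Record a duplication of ``parent_copy`` into ``child_ids`` at ``epoch``."""
        parent = self.copies[parent_copy]
        for cid in child_ids:
            if cid in self.copies:
                raise ValueError(f"copy id {cid!r} already present")
            self.copies[cid] = FamilyCopy(cid, parent.family_id, parent_copy, epoch)
            self._children[cid] = []
            self._children[parent_copy].append(cid)

    # -- queries ----------------------------------------------------------
    def __contains__(self, copy_id: str) -> bool:
        return copy_id in self.copies

    def __len__(self) -> int:
        return len(self.copies)

    def family_of(self, copy_id: str) -> str:
        return self.copies[copy_id].family_id

    def children(self, copy_id: str) -> List[str]:
        return self._children[copy_id]

    def family_ids(self) -> set[str]:
        return {c.family_id for c in self.copies.values()}

    def roots(self) -> Iterator[FamilyCopy]:
        for c in self.copies.values():
            if c.parent is None:
                yield c

    def root_of(self, copy_id: str) -> str:
        cid = copy_id
        while self.copies[cid].parent is not None:
            cid = self.copies[cid].parent  # type: ignore[assignment]
        return cid

    def lineage(self, copy_id: str) -> List[str]:
        """Copy ids from founder down to ``copy_id`` (inclusive)."""
        chain = [copy_id]
        while self.copies[chain[-1]].parent is not None:
            chain.append(self.copies[chain[-1]].parent)  # type: ignore[arg-type]
        return chain[::-1]

    def ancestor_at(
        self,
        copy_id: str,
        target_epoch: str,
        order: Sequence[str] = STEM_EPOCHS,
    ) -> str:
        """The ancestor of ``copy_id`` alive at ``target_epoch``.

        Walks up the copy tree to the deepest copy created at or before the
        target epoch.  A copy with no duplications since the target is its
        own ancestor.
        """
        t = epoch_index(target_epoch, order)
        cid = copy_id
        while epoch_index(self.copies[cid].epoch, order) > t:
            parent = self.copies[cid].parent
            if parent is None:  # pragma: no cover - defensive
                break
            cid = parent
        return cid

    def pair_epoch(self, a: str, b: str) -> Optional[str]:
        """Epoch of the duplication event that separated copies ``a`` and ``b``.

        Returns ``None`` when the copies belong to different families (no
        common duplication) or when one copy is an ancestor of the other.
        """
        if self.family_of(a) != self.family_of(b):
            return None
        la, lb = self.lineage(a), self.lineage(b)
        common = 0
        for x, y in zip(la, lb):
            if x != y:
                break
            common += 1
        if common >= len(la) or common >= len(lb):
            return None  # one is an ancestor of the other
        # Children of the LCA on both paths share the duplication epoch.
        return self.copies[la[common]].epoch

    def alive_at(
        self, target_epoch: str, order: Sequence[str] = STEM_EPOCHS
    ) -> List[str]:
        """All copies alive at ``target_epoch`` by tree structure alone.

        A copy is alive if it was created at or before the epoch and none of
        its children were.  Losses are not modelled here; callers restrict to
        copies with surviving descendants (see
        :func:`paleokaryo.reconstruction.infer_ancestral_genes`).
        """
        t = epoch_index(target_epoch, order)
        out = []
        for cid, c in self.copies.items():
            if epoch_index(c.epoch, order) > t:
                continue
            if all(
                epoch_index(self.copies[k].epoch, order) > t
                for k in self._children[cid]
            ):
                out.append(cid)
        return out

    # -- (de)serialisation -------------------------------------------------
    def records(self) -> Iterator[Tuple[str, str, str, str]]:
        """(family_id, copy_id, parent_copy_id, duplication_epoch) rows."""
        for cid in sorted(self.copies):
            c = self.copies[cid]
            yield (c.family_id, cid, c.parent or "", c.epoch or "")

    @classmethod
    def from_records(
        cls, rows: Iterable[Tuple[str, str, str, str]]
    ) -> "FamilyTable":
        table = cls()
        pending: List[Tuple[str, str, str, str]] = []
        for fam, cid, parent, epoch in rows:
            if parent == "" or parent is None:
                table.add_root(fam, cid)
            else:
                pending.append((fam, cid, parent, epoch))
        # children may reference parents in any order; iterate until settled
        remaining = pending
        while remaining:
            progressed = []
            deferred = []
            for fam, cid, parent, epoch in remaining:
                if parent in table.copies:
                    table.add_duplication(parent, [cid], epoch)
                    progressed.append(cid)
                else:
                    deferred.append((fam, cid, parent, epoch))
            if not progressed:
                missing = sorted({p for _, _, p, _ in deferred})
                raise ValueError(f"unknown parent copies: {missing[:5]}")
            remaining = deferred
        return table

    def copy(self) -> "FamilyTable":
        new = FamilyTable()
        new.copies = dict(self.copies)
        new._children = {k: list(v) for k, v in self._children.items()}
        return new
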