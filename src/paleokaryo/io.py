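"""Readers/writers for the package's TSV/JSON dialects and the run config.

All tabular files are plain TSV with one header line; readers validate
headers and invariants (consecutive 0-based gene indices, unique ids) and
report offending line numbers.  ``.gz`` paths are handled transparently.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .families import FamilyTable
from .genome import Gene, Genome, genome_from_records
from .reconstruction import CAR
from .tetrads import Tetrad

__all__ = [
    "RunConfig",
    "read_genome", "write_genome",
    "read_families", "write_families",
    "read_cars", "write_cars",
    "read_pairs", "write_pairs",
    "write_matrix",
    "read_tetrads", "write_tetrads",
    "read_clgs", "write_clgs",
    "write_scenario",
]

PathLike = Union[str, Path]


def _open(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_header(got: Sequence[str], want: Sequence[str], path: PathLike) -> None:
    if list(got) != list(want):
        raise ValueError(
            f"{path}: bad header {list(got)!r}, expected {list(want)!r}"
        )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All pipeline tunables with their field defaults.

    The defaults are the operating point for chromosome-scale data
    (hundreds of genes per CAR): synteny window N = 45 genes, same-CAR
    ohnolog floor 2N = 90, CARs larger than 50 genes treated as
    chromosome-size, families limited to 4 CARs of at least 10 genes, and
    Bonferroni-adjusted alpha 0.05.  For smaller simulated genomes use
    :meth:`scaled`, which re-expresses the size thresholds relative to the
    expected chromosome size.
    """

    synteny_window: int = 45
    same_car_min_distance: int = 90
    min_car_len: int = 50
    min_car_genes_for_span: int = 10
    max_family_cars: int = 4
    alpha: float = 0.05
    bonferroni: bool = True
    merge_window: int = 10
    split_window: int = 10
    epoch_window: Tuple[str, ...] = ("1R", "2R")
    min_edge_weight: int = 1
    single_chromosome_frac: float = 0.9
    predominant_floor: float = 0.5
    predominant_ratio: float = 2.0
    pre1r_fusion_threshold: float = 0.75
    target_epoch: str = "amniota"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synteny_window <= 0:
            raise ValueError("synteny_window must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_car_len < 0 or self.min_car_genes_for_span < 0:
            raise ValueError("size thresholds must be non-negative")

    @classmethod
    def scaled(cls, mean_chromosome_genes: float, **overrides) -> "RunConfig":
        """Config with size thresholds scaled to the expected chromosome size.

        The chromosome-size CAR filter is ~40% of the mean chromosome and
        the family-span floor ~20%, preserving the proportions the
        defaults have at full scale.
        """
        cfg = cls(
            min_car_len=max(4, round(0.4 * mean_chromosome_genes)),
            min_car_genes_for_span=max(3, round(0.2 * mean_chromosome_genes)),
            **overrides,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with _open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "epoch_window" in data:
            data["epoch_window"] = tuple(data["epoch_window"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        data = asdict(self)
        data["epoch_window"] = list(data["epoch_window"])
        with _open(path, "wt") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome files
# ---------------------------------------------------------------------------

GENOME_COLUMNS = ["chromosome", "index", "strand", "gene_id", "family_id"]


def write_genome(genome: Genome, path: PathLike) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(GENOME_COLUMNS) + "\n")
        for chrom in sorted(genome.chromosomes):
            for i, g in enumerate(genome.chromosomes[chrom]):
                strand = "+" if g.strand == 1 else "-"
                fh.write(f"{chrom}\t{i}\t{strand}\t{g.gene_id}\t{g.family_id}\n")


def read_genome(path: PathLike, name: Optional[str] = None, epoch: str = "extant") -> Genome:
    records = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, GENOME_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, idx, strand, gid, fid = parts
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                idx_i = int(idx)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad index {idx!r}") from exc
            records.append((chrom, idx_i, 1 if strand == "+" else -1, gid, fid))
    return genome_from_records(name or Path(path).stem, epoch, records)


# ---------------------------------------------------------------------------
# Family files
# ---------------------------------------------------------------------------

FAMILY_COLUMNS = ["family_id", "copy_id", "parent_copy_id", "duplication_epoch"]


def write_families(families: FamilyTable, path: PathLike) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(FAMILY_COLUMNS) + "\n")
        for row in families.records():
            fh.write("\t".join(row) + "\n")


def read_families(path: PathLike) -> FamilyTable:
    rows = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, FAMILY_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rows.append(tuple(parts))
    return FamilyTable.from_records(rows)


# ---------------------------------------------------------------------------
# CAR files
# ---------------------------------------------------------------------------

CAR_COLUMNS = ["car_id", "position", "gene_id", "orientation"]


def write_cars(cars: Sequence[CAR], path: PathLike) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(CAR_COLUMNS) + "\n")
        for car in cars:
            for pos, (gid, o) in enumerate(zip(car.genes, car.orientations)):
                fh.write(f"{car.car_id}\t{pos}\t{gid}\t{'+' if o == 1 else '-'}\n")


def read_cars(path: PathLike) -> List[CAR]:
    slots: Dict[str, Dict[int, Tuple[str, int]]] = {}
    order: List[str] = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, CAR_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            cid, pos, gid, orient = parts
            if cid not in slots:
                slots[cid] = {}
                order.append(cid)
            pos_i = int(pos)
            if pos_i in slots[cid]:
                raise ValueError(f"{path}:{lineno}: duplicated position {pos_i}")
            slots[cid][pos_i] = (gid, 1 if orient == "+" else -1)
    cars = []
    for cid in order:
        positions = slots[cid]
        if sorted(positions) != list(range(len(positions))):
            raise ValueError(f"{path}: CAR {cid!r} positions not consecutive")
        genes = [positions[i][0] for i in range(len(positions))]
        orients = [positions[i][1] for i in range(len(positions))]
        cars.append(CAR(cid, genes, orients))
    return cars


# ---------------------------------------------------------------------------
# Pair / matrix / tetrad / CLG / scenario files
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["gene_a", "gene_b", "car_a", "car_b", "family_id", "source"]


def write_pairs(pairs, path: PathLike) -> None:
    """Write a consensus pair frame (gene_a, gene_b, car_a, car_b, family_id, source)."""
    with _open(path, "wt") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for row in pairs.itertuples():
            fh.write(
                f"{row.gene_a}\t{row.gene_b}\t{row.car_a}\t{row.car_b}"
                f"\t{row.family_id}\t{row.source}\n"
            )


def read_pairs(path: PathLike):
    import pandas as pd

    with _open(path) as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    _check_header(frame.columns, PAIR_COLUMNS, path)
    return frame


def write_matrix(matrix, path: PathLike) -> None:
    with _open(path, "wt") as fh:
        matrix.to_csv(fh, sep="\t", index=False)


def write_tetrads(tetrads: Sequence[Tetrad], path: PathLike) -> None:
    data = [
        {
            "tetrad_id": t.tetrad_id,
            "members": t.members,
            "completed_with": t.completed_with,
            "unresolved": t.unresolved,
            "log": t.log,
        }
        for t in tetrads
    ]
    with _open(path, "wt") as fh:
        json.dump(data, fh, indent=1)


def read_tetrads(path: PathLike) -> List[Tetrad]:
    with _open(path) as fh:
        data = json.load(fh)
    return [
        Tetrad(
            d["tetrad_id"], list(d["members"]),
            list(d.get("completed_with", [])), bool(d.get("unresolved", False)),
            list(d.get("log", [])),
        )
        for d in data
    ]


CLG_COLUMNS = ["clg_id", "family_id"]


def write_clgs(clgs: Mapping[str, frozenset], path: PathLike) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(CLG_COLUMNS) + "\n")
        for clg_id in sorted(clgs):
            for fam in sorted(clgs[clg_id]):
                fh.write(f"{clg_id}\t{fam}\n")


def read_clgs(path: PathLike) -> Dict[str, frozenset]:
    out: Dict[str, set] = {}
    seen: Dict[str, str] = {}
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, CLG_COLUMNS, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            clg_id, fam = line.split("\t")
            if fam in seen and seen[fam] != clg_id:
                raise ValueError(
                    f"{path}:{lineno}: family {fam!r} in two linkage groups"
                )
            seen[fam] = clg_id
            out.setdefault(clg_id, set()).add(fam)
    return {k: frozenset(v) for k, v in out.items()}


def write_scenario(timeline, events, clg_table, path: PathLike) -> None:
    """Scenario JSON: timeline counts, typed events, tetrad-CLG table."""
    payload = {
        "timeline": dict(timeline.counts),
        "events": [
            {
                "type": e.type,
                "operands": e.operands,
                "epoch": e.epoch,
                "evidence": _jsonable(e.evidence),
            }
            for e in events
        ],
        "clg_table": (
            clg_table.to_dict(orient="records") if clg_table is not None else None
        ),
    }
    with _open(path, "wt") as fh:
        json.dump(payload, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
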