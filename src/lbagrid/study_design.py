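"""Taxon registry, sequential-pruning series and analysis-grid accounting.

This module encodes the bookkeeping that structures a sensitivity
analysis over supermatrices: a registry of terminals grouped into
order-level clades and subgroups, a user-declared series of pruning
steps that successively removes basally branching subgroups of one
focal clade, and the cross product of gene-occupancy families with
taxon subsets (plus method/tertile axes) that enumerates every
analysis to be run.

Occupancy families are labelled ``G1, G2, ...`` in order of
*decreasing* occupancy threshold (G1 densest, hence shortest matrix);
taxon subsets are labelled ``T0, T-1, ...`` in order of increasing
pruning.  Subgroup labels are matched case-sensitively after
whitespace trimming.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ROLES = ("ingroup", "outgroup")

RATE_TERTILES = ("slow", "intermediate", "fast")

METHODS = (
    "partitioned_ml",
    "pmsf_c20",
    "pmsf_c60",
    "astral",
    "rate_tertile_ml",
    "rate_tertile_astral",
)


@dataclass(frozen=True)
class TaxonRecord:
    name: str
    group: str
    subgroup: str = ""
    role: str = "ingroup"

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.strip())
        object.__setattr__(self, "group", self.group.strip())
        object.__setattr__(self, "subgroup", self.subgroup.strip())
        object.__setattr__(self, "role", self.role.strip())
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "ingroup" and not self.group:
            raise ValueError(f"ingroup terminal {self.name!r} needs a group")


@dataclass(frozen=True)
class PruningStep:
    index: int
    removed_subgroups: tuple[str, ...]
    removed_count: int | None = None

    def __init__(self, index, removed_subgroups, removed_count=None):
        object.__setattr__(self, "index", int(index))
        object.__setattr__(
            self, "removed_subgroups", tuple(s.strip() for s in removed_subgroups)
        )
        object.__setattr__(self, "removed_count", removed_count)


@dataclass(frozen=True)
class OccupancyFamily:
    label: str
    threshold: float

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("occupancy threshold must be in (0, 1]")


@dataclass(frozen=True)
class MatrixGridCell:
    occupancy_family: str
    taxon_subset: str
    method: str = "partitioned_ml"
    tertile: str | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        is_tertile_method = self.method.startswith("rate_tertile")
        if is_tertile_method != (self.tertile is not None):
            raise ValueError("tertile must be set iff the method is a rate-tertile method")
        if self.tertile is not None and self.tertile not in RATE_TERTILES:
            raise ValueError(f"tertile must be one of {RATE_TERTILES}")


@dataclass
class AnalysisPlan:
    cells: list[MatrixGridCell]
    provenance: dict[MatrixGridCell, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)


# ---- operations -----------------------------------------------------

def validate_registry(registry: list[TaxonRecord]) -> None:
    if not registry:
        raise ValueError("registry is empty")
    seen = set()
    for rec in registry:
        if rec.name in seen:
            raise ValueError(f"duplicate terminal name: {rec.name!r}")
        seen.add(rec.name)


def taxon_census(registry: list[TaxonRecord]) -> pd.DataFrame:
    """Per-group counts plus ingroup/outgroup/total rows.

    Group rows are sorted by label; the summary rows come last.
    """
    validate_registry(registry)
    counts: dict[str, int] = {}
    for rec in registry:
        counts[rec.group] = counts.get(rec.group, 0) + 1
    ingroup = sum(1 for r in registry if r.role == "ingroup")
    outgroup = len(registry) - ingroup
    rows = [{"group": g, "count": counts[g]} for g in sorted(counts)]
    rows.append({"group": "(ingroup)", "count": ingroup})
    rows.append({"group": "(outgroup)", "count": outgroup})
    rows.append({"group": "(total)", "count": len(registry)})
    return pd.DataFrame(rows)


@dataclass
class TaxonSubset:
    label: str
    names: tuple[str, ...]
    focal_count: int


def pruning_series(
    registry: list[TaxonRecord],
    steps: list[PruningStep],
    focal_group: str,
) -> list[TaxonSubset]:
    """Sequentially apply *steps*, each removing whole subgroups of the
    focal group; returns subsets T0 (full) through T-k."""
    validate_registry(registry)
    if [s.index for s in steps] != list(range(1, len(steps) + 1)):
        raise ValueError("pruning step indices must be consecutive from 1")
    all_removed: list[str] = []
    for step in steps:
        for sub in step.removed_subgroups:
            if sub in all_removed:
                raise ValueError(f"subgroup {sub!r} removed by more than one step")
            all_removed.append(sub)
    focal_subgroups = {r.subgroup for r in registry if r.group == focal_group}
    unknown = set(all_removed) - focal_subgroups
    if unknown:
        raise ValueError(
            f"subgroup(s) {sorted(unknown)} not found under focal group {focal_group!r}"
        )

    def focal_count(names):
        by_name = {r.name: r for r in registry}
        return sum(1 for n in names if by_name[n].group == focal_group)

    current = [r.name for r in registry]
    subsets = [TaxonSubset("T0", tuple(current), focal_count(current))]
    for step in steps:
        doomed = {
            r.name
            for r in registry
            if r.group == focal_group and r.subgroup in step.removed_subgroups
        }
        if step.removed_count is not None and len(doomed) != step.removed_count:
            raise ValueError(
                f"step {step.index} expected to remove {step.removed_count} terminals, "
                f"matched {len(doomed)}"
            )
        current = [n for n in current if n not in doomed]
        subsets.append(TaxonSubset(f"T-{step.index}", tuple(current), focal_count(current)))
    return subsets


def occupancy_families(thresholds: list[float]) -> list[OccupancyFamily]:
    """Label thresholds G1..Gk in order of decreasing threshold
    (G1 = densest = shortest matrix)."""
    ordered = sorted(thresholds, reverse=True)
    return [OccupancyFamily(f"G{i + 1}", t) for i, t in enumerate(ordered)]


def build_matrix_grid(
    families: list[OccupancyFamily],
    subsets: list[TaxonSubset],
    method: str = "partitioned_ml",
) -> list[MatrixGridCell]:
    """Row-major (family-outer) cross product of families and subsets."""
    if not families or not subsets:
        raise ValueError("need at least one family and one subset")
    return [
        MatrixGridCell(f.label, s.label, method=method)
        for f in families
        for s in subsets
    ]


def enumerate_analyses(plan_spec: list[dict]) -> AnalysisPlan:
    """Flatten a declared plan into cells and a total count.

    Each entry of *plan_spec* is a mapping with keys ``method``,
    ``families`` (labels), ``subsets`` (labels) and, for rate-tertile
    methods, ``tertiles``.  Duplicate cells are rejected.
    """
    cells: list[MatrixGridCell] = []
    provenance: dict[MatrixGridCell, str] = {}
    seen = set()
    for entry in plan_spec:
        method = entry["method"]
        tertiles = entry.get("tertiles") or [None]
        for fam in entry["families"]:
            for sub in entry["subsets"]:
                for tert in tertiles:
                    cell = MatrixGridCell(fam, sub, method=method, tertile=tert)
                    if cell in seen:
                        raise ValueError(f"duplicate analysis cell: {cell}")
                    seen.add(cell)
                    cells.append(cell)
                    provenance[cell] = entry.get("note", "")
    return AnalysisPlan(cells=cells, provenance=provenance)


# ---- I/O ------------------------------------------------------------

def read_registry(path: str | Path) -> list[TaxonRecord]:
    """TSV with header ``name  group  subgroup  role``."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                TaxonRecord(
                    name=row["name"],
                    group=row.get("group", "") or "",
                    subgroup=row.get("subgroup", "") or "",
                    role=row.get("role", "ingroup") or "ingroup",
                )
            )
    validate_registry(records)
    return records


def write_registry(registry: list[TaxonRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "group", "subgroup", "role"])
        for rec in registry:
            writer.writerow([rec.name, rec.group, rec.subgroup, rec.role])
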