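"""Compound Series Matrices (CSMs).

A CSM organizes structurally related analog series in multi-target activity
space. It is built in two fragmentation rounds:

1. MMPs are generated from the original compounds; every core occurring in
   at least one MMP defines an analog series (core + the substituents of
   all compounds fragmenting to it).
2. MMPs are generated *from the cores themselves*; series whose cores fall
   into one connected component of this core-level MMP graph — cores
   distinguished by a structural change at a single site — are merged into
   one matrix. No further fragmentation rounds are applied.

Rows of a CSM are the related cores, columns the union of their
substituents. A (core, substituent) cell holds the unique real compound
with that decomposition, annotated with its target count T, or is *virtual*:
a chemically sensible but unsynthesized combination. Virtual cells in
columns of promiscuous compounds are design candidates for similar target
profiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import CellCollisionError, EmptySubmatrixError, MalformedInputError
from .fragmentation import (
    MatchedMolecularPair,
    SizeLimits,
    core_level_mmps,
    enumerate_fragmentations,
    generate_mmps,
    passes_size_restrictions,
    reassemble,
)
from ._chem import heavy_atom_count, mol_from_smiles
from .errors import StructureError

__all__ = [
    "AnalogSeries",
    "CSMCell",
    "CompoundSeriesMatrix",
    "CSMStatistics",
    "DesignCandidate",
    "build_series",
    "build_csms",
    "csm_statistics",
    "extract_promiscuous_submatrix",
    "design_candidates",
    "write_csm_json",
    "read_csm_json",
    "write_csm_csv",
]


@dataclass(frozen=True)
class AnalogSeries:
    """Compounds sharing one core, keyed by their substituent."""

    core: str
    members: tuple[tuple[str, str], ...]  # (substituent, compound_id), sorted

    @property
    def substituents(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.members)

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.members)


@dataclass(frozen=True)
class CSMCell:
    """One matrix cell: a real compound with its target count, or virtual."""

    status: str  # "real" | "virtual"
    compound_id: str | None = None
    target_count: int = 0
    targets: frozenset[str] = frozenset()


@dataclass
class CompoundSeriesMatrix:
    """Grid of related cores (rows) × substituents (columns).

    ``cells`` maps every (core, substituent) coordinate to a
    :class:`CSMCell`; real + virtual cells tile the full grid.
    """

    rows: list[str]
    columns: list[str]
    cells: dict[tuple[str, str], CSMCell]

    @property
    def real_cells(self) -> dict[tuple[str, str], CSMCell]:
        return {k: c for k, c in self.cells.items() if c.status == "real"}

    @property
    def virtual_cells(self) -> set[tuple[str, str]]:
        return {k for k, c in self.cells.items() if c.status == "virtual"}

    @property
    def n_compounds(self) -> int:
        return len(self.real_cells)

    @property
    def targets_covered(self) -> frozenset[str]:
        out: set[str] = set()
        for cell in self.real_cells.values():
            out |= cell.targets
        return frozenset(out)

    def family_span(self, families: Mapping[str, str]) -> frozenset[str]:
        """Distinct target families over all targets of all real cells."""
        return frozenset(families.get(t, "other") for t in self.targets_covered)

    @property
    def is_multi_target(self) -> bool:
        """True when at least one compound is promiscuous (T >= 2)."""
        return any(c.target_count >= 2 for c in self.real_cells.values())


@dataclass(frozen=True)
class CSMStatistics:
    """Collection-level CSM statistics; the family-span histogram is taken
    over multi-target CSMs."""

    n_csms: int
    n_multi_target_csms: int
    n_single_family: int
    n_multi_family: int
    family_span_histogram: dict[int, int]


@dataclass(frozen=True)
class DesignCandidate:
    """A virtual compound assembled from a row core and a column
    substituent."""

    smiles: str
    core: str
    substituent: str


def _sort_key(fragment: str) -> tuple[int, str]:
    mol = mol_from_smiles(fragment)
    return (heavy_atom_count(mol), fragment)


def build_series(
    dataset_or_structures,
    limits: SizeLimits | None = None,
) -> list[AnalogSeries]:
    """Analog series from compound-level MMPs (first fragmentation round).

    Accepts a curated dataset or a plain id → SMILES mapping. For every
    core occurring in at least one MMP, the series collects *all* compounds
    with a size-restriction-passing fragmentation to that core; a compound
    may belong to several series via different cores.
    """
    limits = limits or SizeLimits()
    structures: Mapping[str, str] = getattr(
        dataset_or_structures, "compounds", dataset_or_structures
    )
    mmps = generate_mmps(structures, limits)
    series_cores = {m.core for m in mmps}
    members: dict[str, dict[str, str]] = {core: {} for core in series_cores}
    for cid, smiles in structures.items():
        for f in enumerate_fragmentations(smiles, cid):
            if f.core in series_cores and passes_size_restrictions(f, limits):
                members[f.core][f.substituent] = cid
    return [
        AnalogSeries(core, tuple(sorted(members[core].items())))
        for core in sorted(series_cores)
        if len(members[core]) >= 2
    ]


def build_csms(
    series: Sequence[AnalogSeries],
    limits: SizeLimits | None = None,
    target_sets: Mapping[str, Iterable[str]] | None = None,
) -> list[CompoundSeriesMatrix]:
    """Merge analog series with related cores into matrices (second round).

    Core-level MMPs are computed over the series cores; each connected
    component with at least two cores becomes one CSM. Rows and columns are
    ordered by heavy-atom count, then lexicographically. ``target_sets``
    (compound id → targets) annotates real cells; compounds absent from it
    count zero targets.
    """
    if not series:
        raise MalformedInputError("build_csms needs at least one series")
    limits = limits or SizeLimits()
    target_sets = target_sets or {}
    by_core = {s.core: s for s in series}
    core_graph = nx.Graph()
    core_graph.add_nodes_from(by_core)
    for mmp in core_level_mmps(by_core.keys(), limits):
        core_graph.add_edge(mmp.compound_a, mmp.compound_b)

    csms: list[CompoundSeriesMatrix] = []
    for component in nx.connected_components(core_graph):
        if len(component) < 2:
            continue
        rows = sorted(component, key=_sort_key)
        col_set: set[str] = set()
        for core in rows:
            col_set.update(by_core[core].substituents)
        columns = sorted(col_set, key=_sort_key)
        cells: dict[tuple[str, str], CSMCell] = {}
        for core in rows:
            row_members = dict(by_core[core].members)
            for sub in columns:
                if sub in row_members:
                    cid = row_members[sub]
                    prev = cells.get((core, sub))
                    if prev is not None and prev.compound_id != cid:
                        raise CellCollisionError(
                            f"compounds {prev.compound_id!r} and {cid!r} both map "
                            f"to cell ({core!r}, {sub!r})"
                        )
                    targets = frozenset(target_sets.get(cid, ()))
                    cells[(core, sub)] = CSMCell("real", cid, len(targets), targets)
                else:
                    cells[(core, sub)] = CSMCell("virtual")
        csms.append(CompoundSeriesMatrix(rows, columns, cells))
    # deterministic order: by first row core
    csms.sort(key=lambda m: m.rows[0])
    return csms


def csm_statistics(
    csms: Sequence[CompoundSeriesMatrix],
    families: Mapping[str, str],
) -> CSMStatistics:
    """Multi-target and family-span statistics of a CSM collection."""
    n_multi = 0
    n_single_family = 0
    histogram: dict[int, int] = {}
    for m in csms:
        if not m.is_multi_target:
            continue
        n_multi += 1
        span = len(m.family_span(families))
        histogram[span] = histogram.get(span, 0) + 1
        if span <= 1:
            n_single_family += 1
    return CSMStatistics(
        n_csms=len(csms),
        n_multi_target_csms=n_multi,
        n_single_family=n_single_family,
        n_multi_family=n_multi - n_single_family,
        family_span_histogram=dict(sorted(histogram.items())),
    )


def extract_promiscuous_submatrix(
    csm: CompoundSeriesMatrix,
    min_target_count: int,
) -> CompoundSeriesMatrix:
    """The submatrix spanned by real cells with T >= ``min_target_count``.

    Rows and columns with no surviving real cell are dropped; virtual cells
    are recomputed on the reduced grid. Raises
    :class:`EmptySubmatrixError` when nothing survives.
    """
    if min_target_count < 1:
        raise MalformedInputError("min_target_count must be >= 1")
    kept = {
        k: c for k, c in csm.real_cells.items() if c.target_count >= min_target_count
    }
    if not kept:
        raise EmptySubmatrixError(
            f"no real cell reaches target count {min_target_count}"
        )
    rows = [r for r in csm.rows if any(k[0] == r for k in kept)]
    columns = [c for c in csm.columns if any(k[1] == c for k in kept)]
    cells: dict[tuple[str, str], CSMCell] = {}
    for r in rows:
        for c in columns:
            cells[(r, c)] = kept.get((r, c), CSMCell("virtual"))
    return CompoundSeriesMatrix(rows, columns, cells)


def design_candidates(
    csm: CompoundSeriesMatrix,
    column: str,
) -> list[DesignCandidate]:
    """Virtual compounds of one substituent column, assembled from the row
    cores. Chemically invalid reassemblies are skipped with a warning."""
    if column not in csm.columns:
        raise MalformedInputError(f"column {column!r} is not in this matrix")
    out: list[DesignCandidate] = []
    for core in csm.rows:
        if csm.cells[(core, column)].status != "virtual":
            continue
        try:
            smiles = reassemble(core, column)
        except StructureError as exc:
            warnings.warn(f"skipping candidate ({core!r}, {column!r}): {exc}")
            continue
        out.append(DesignCandidate(smiles, core, column))
    return out


# ---------------------------------------------------------------------------
# exports

def write_csm_json(csms: Sequence[CompoundSeriesMatrix], path) -> None:
    payload = []
    for m in csms:
        payload.append(
            {
                "rows": m.rows,
                "columns": m.columns,
                "cells": [
                    {
                        "core": core,
                        "substituent": sub,
                        "status": cell.status,
                        "compound_id": cell.compound_id,
                        "target_count": cell.target_count,
                        "targets": sorted(cell.targets),
                    }
                    for (core, sub), cell in sorted(m.cells.items())
                ],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_csm_json(path) -> list[CompoundSeriesMatrix]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    csms = []
    for entry in payload:
        cells = {
            (c["core"], c["substituent"]): CSMCell(
                c["status"],
                c["compound_id"],
                c["target_count"],
                frozenset(c["targets"]),
            )
            for c in entry["cells"]
        }
        csms.append(CompoundSeriesMatrix(entry["rows"], entry["columns"], cells))
    return csms


def write_csm_csv(csm: CompoundSeriesMatrix, path) -> None:
    """Wide CSV: one row per core, cells `compound_id:T` or `VIRTUAL`."""
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["core"] + csm.columns)
        for core in csm.rows:
            row = [core]
            for sub in csm.columns:
                cell = csm.cells[(core, sub)]
                row.append(
                    "VIRTUAL"
                    if cell.status == "virtual"
                    else f"{cell.compound_id}:{cell.target_count}"
                )
            writer.writerow(row)
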