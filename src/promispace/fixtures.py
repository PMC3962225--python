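"""Synthetic ground-truth datasets for the whole pipeline.

Real curated activity collections (ChEMBL-style K_i/IC50 subsets, binary
profiling matrices) are database snapshots that cannot be shipped; these
generators produce small datasets with the same *structure* and a complete
ground-truth record, so every downstream operation can be tested against
known answers.

Two generators:

* :func:`generate_analog_grid` — analog series with planted cores and
  substituents on a full cores × substituents grid, minus seeded random
  deletions (the future virtual cells). Cores within one scaffold family
  differ by H→F replacements or fluorine positional isomerism, which makes
  them core-level MMP relatives *by construction* while guaranteeing that
  no two compounds share an unplanned fragmentation core; the default
  substituent library is likewise chosen with pairwise-distinct inner
  structure ("stems"), so chain homologs that would create alternative
  shared cores are excluded. Per-compound target counts follow a
  zero-truncated geometric distribution — matching the heavy single-target
  skew of curated activity data — with targets partitioned into families.

* :func:`generate_binary_matrix` — a compound × target 0/1 profiling
  matrix with planted promiscuity-cliff pairs (structural MMP partners with
  target counts differing by exactly a chosen delta) on a background of
  cycloalkanes of distinct ring sizes. Cycloalkanes contain no acyclic
  bonds, hence have no fragmentations and can never form MMPs: the
  background is MMP-free by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from ._chem import attach, heavy_atom_count, mol_from_smiles
from .errors import MalformedInputError, StructureError
from .io import ActivityRecord, CuratedDataset, curate

__all__ = [
    "CORE_LIBRARY",
    "SUBSTITUENT_LIBRARY",
    "FixtureSpec",
    "GridGroundTruth",
    "BinaryGroundTruth",
    "generate_analog_grid",
    "generate_binary_matrix",
    "write_ground_truth_json",
]

#: Scaffold families. Within a family, cores differ from the base scaffold
#: by a fluorine at varying ring positions; across families the ring systems
#: differ, so series from different families are never merged.
CORE_LIBRARY: dict[str, list[str]] = {
    "benzene": [
        "[*:1]c1ccccc1",
        "[*:1]c1ccccc1F",
        "[*:1]c1cccc(F)c1",
        "[*:1]c1ccc(F)cc1",
    ],
    "pyridine": [
        # 3-pyridyl attachment: asymmetric ring, so the two fluorine
        # positions below are genuinely distinct molecules
        "[*:1]c1cccnc1",
        "[*:1]c1ccc(F)nc1",
        "[*:1]c1cc(F)cnc1",
    ],
    "thiophene": [
        "[*:1]c1cccs1",
        "[*:1]c1ccc(F)s1",
        "[*:1]c1cc(F)cs1",
    ],
    "naphthalene": [
        "[*:1]c1ccc2ccccc2c1",
        "[*:1]c1ccc2ccc(F)cc2c1",
        "[*:1]c1ccc2cc(F)ccc2c1",
    ],
}

#: R-groups with pairwise-distinct stems (no chain homolog pairs).
SUBSTITUENT_LIBRARY: list[str] = [
    "[*:1]C",        # methyl
    "[*:1]O",        # hydroxy
    "[*:1]N",        # amino
    "[*:1]C#N",      # cyano
    "[*:1]OC",       # methoxy
    "[*:1]C(C)C",    # isopropyl
    "[*:1]N(C)C",    # dimethylamino
    "[*:1]CC#N",     # cyanomethyl
]

TARGET_FAMILIES = ("GPCR-A", "kinase", "ion channel", "protease", "NHR")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted analog grid.

    families: scaffold families to use (keys of CORE_LIBRARY); the series
        count is the total number of cores across them.
    substituents: R-group fragments (one attachment point each).
    deletion_fraction: fraction of grid cells deleted at random; deletion
        always leaves at least two compounds per series.
    n_targets: size of the target panel.
    family_sizes: targets per target family, in TARGET_FAMILIES order.
    t_geometric_p: success parameter of the zero-truncated geometric
        target-count sampler (default 0.6: ~40% multi-target compounds,
        matching the single-target-dominated skew of curated data).
    """

    families: tuple[str, ...] = ("benzene", "pyridine")
    substituents: tuple[str, ...] = tuple(SUBSTITUENT_LIBRARY[:6])
    deletion_fraction: float = 0.2
    n_targets: int = 20
    family_sizes: tuple[int, ...] | None = None
    t_geometric_p: float = 0.6
    seed: int = 0

    def cores(self) -> list[str]:
        """Planted cores in canonical fragment form, per family."""
        out: list[str] = []
        for fam in self.families:
            if fam not in CORE_LIBRARY:
                raise MalformedInputError(f"unknown scaffold family {fam!r}")
            out.extend(_canonical_fragment(c) for c in CORE_LIBRARY[fam])
        return out

    def __post_init__(self):
        if not 0 <= self.deletion_fraction < 1:
            raise MalformedInputError("deletion_fraction must be in [0, 1)")
        if len(set(self.substituents)) < 2:
            raise MalformedInputError("need at least two distinct substituents")


@dataclass
class GridGroundTruth:
    """Exact expected outcome of the analog-grid pipeline."""

    compounds: dict[str, str]                      # id -> canonical SMILES
    cell_of: dict[tuple[str, str], str]            # (core, sub) -> id, surviving
    deleted_cells: list[tuple[str, str]]           # planted virtual coordinates
    deleted_smiles: dict[tuple[str, str], str]     # what reassembly must return
    series: dict[str, dict[str, str]]              # core -> {sub -> id}
    csm_layouts: list[dict] = field(default_factory=list)  # rows/columns/virtual per CSM
    target_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    target_counts: dict[str, int] = field(default_factory=dict)
    target_families: dict[str, str] = field(default_factory=dict)


def _canonical_fragment(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"invalid planted fragment {smiles!r}")
    return Chem.MolToSmiles(mol)


def _frag_sort_key(fragment: str) -> tuple[int, str]:
    return (heavy_atom_count(mol_from_smiles(fragment)), fragment)


def _sample_zt_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    """Zero-truncated geometric draw, capped at the panel size."""
    t = int(rng.geometric(p))
    return min(t, cap)


def _target_panel(spec: FixtureSpec) -> tuple[list[str], dict[str, str]]:
    sizes = spec.family_sizes
    if sizes is None:
        base = spec.n_targets // len(TARGET_FAMILIES)
        sizes = [base] * len(TARGET_FAMILIES)
        for i in range(spec.n_targets - base * len(TARGET_FAMILIES)):
            sizes[i] += 1
    if sum(sizes) != spec.n_targets:
        raise MalformedInputError("family_sizes must sum to n_targets")
    targets, families = [], {}
    i = 0
    for fam, size in zip(TARGET_FAMILIES, sizes):
        for _ in range(size):
            tid = f"T{i:03d}"
            targets.append(tid)
            families[tid] = fam
            i += 1
    return targets, families


def generate_analog_grid(spec: FixtureSpec) -> tuple[CuratedDataset, GridGroundTruth]:
    """Planted analog grid: full cores × substituents, seeded deletions,
    zero-truncated-geometric target profiles. Returns the curated dataset
    together with its exact expected decomposition."""
    rng = np.random.default_rng(spec.seed)
    cores = spec.cores()
    subs = [_canonical_fragment(s) for s in spec.substituents]

    # assemble the full grid
    grid: dict[tuple[str, str], str] = {}
    for core in cores:
        for sub in subs:
            grid[(core, sub)] = attach(core, sub)
    if len(set(grid.values())) != len(grid):
        raise StructureError("planted grid contains duplicate structures")

    # seeded deletions, keeping >= 2 members per series
    coords = sorted(grid)
    n_delete = int(spec.deletion_fraction * len(coords))
    order = rng.permutation(len(coords))
    remaining = {core: len(subs) for core in cores}
    deleted: list[tuple[str, str]] = []
    for idx in order:
        if len(deleted) == n_delete:
            break
        core, sub = coords[idx]
        if remaining[core] > 2:
            deleted.append((core, sub))
            remaining[core] -= 1
    deleted_set = set(deleted)

    surviving = {coord: smi for coord, smi in grid.items() if coord not in deleted_set}
    ids = {
        coord: f"CPD{i:04d}" for i, coord in enumerate(sorted(surviving))
    }

    # target panel and per-compound profiles
    targets, target_families = _target_panel(spec)
    target_sets: dict[str, frozenset[str]] = {}
    records: list[ActivityRecord] = []
    for coord in sorted(surviving):
        cid = ids[coord]
        t = _sample_zt_geometric(rng, spec.t_geometric_p, spec.n_targets)
        chosen = rng.choice(len(targets), size=t, replace=False)
        tset = frozenset(targets[j] for j in chosen)
        target_sets[cid] = tset
        for tid in sorted(tset):
            value = float(10 ** rng.uniform(0, 3.999))  # 1 nM .. <10 µM
            records.append(
                ActivityRecord(
                    compound_id=cid,
                    smiles=surviving[coord],
                    target_id=tid,
                    target_family=target_families[tid],
                    measurement_type="Ki",
                    relation="=",
                    value_nm=value,
                )
            )

    dataset = curate(records, "Ki", 10000.0)

    # expected series and CSM layouts (one CSM per scaffold family)
    series: dict[str, dict[str, str]] = {}
    for (core, sub), cid in ids.items():
        series.setdefault(core, {})[sub] = cid
    layouts: list[dict] = []
    for fam in spec.families:
        fam_cores = [
            c
            for c in (_canonical_fragment(x) for x in CORE_LIBRARY[fam])
            if c in series
        ]
        rows = sorted(fam_cores, key=_frag_sort_key)
        col_set: set[str] = set()
        for c in rows:
            col_set.update(series[c])
        columns = sorted(col_set, key=_frag_sort_key)
        virtual = {
            (c, s) for c in rows for s in columns if (c, s) not in ids
        }
        layouts.append({"rows": rows, "columns": columns, "virtual": virtual})
    layouts.sort(key=lambda l: l["rows"][0])

    gt = GridGroundTruth(
        compounds={ids[c]: surviving[c] for c in sorted(surviving)},
        cell_of={c: ids[c] for c in sorted(surviving)},
        deleted_cells=sorted(deleted_set),
        deleted_smiles={c: grid[c] for c in sorted(deleted_set)},
        series=series,
        csm_layouts=layouts,
        target_sets=target_sets,
        target_counts={cid: len(ts) for cid, ts in target_sets.items()},
        target_families=target_families,
    )
    return dataset, gt


@dataclass
class BinaryGroundTruth:
    """Planted content of a binary profiling matrix."""

    planted_pairs: list[tuple[str, str, int]]  # (id_low, id_high, delta)
    target_counts: dict[str, int]
    compounds: dict[str, str]


_PLANT_SUBS = ("[*:1]C", "[*:1]OC")


def generate_binary_matrix(
    n_compounds: int = 60,
    n_targets: int = 100,
    base_activity_rate: float = 0.02,
    n_planted_cliff_pairs: int = 5,
    delta: int = 55,
    seed: int = 0,
) -> tuple[pd.DataFrame, BinaryGroundTruth]:
    """Binary compound × target matrix with planted promiscuity cliffs.

    Each planted pair shares a distinct scaffold core and differs by a
    methyl→methoxy exchange (an MMP by construction) with target counts
    differing by exactly ``delta``. Background compounds are cycloalkanes
    of distinct ring sizes — fragmentation-free, hence MMP-free — with
    activities drawn per-target at ``base_activity_rate``.

    Returns the wide matrix (columns: compound_id, smiles, one per target)
    and the ground truth.
    """
    if delta > n_targets:
        raise MalformedInputError(f"delta {delta} exceeds the target panel size {n_targets}")
    core_pool = [c for fam in CORE_LIBRARY.values() for c in fam]
    if n_planted_cliff_pairs > len(core_pool):
        raise MalformedInputError(
            f"at most {len(core_pool)} planted pairs supported, got {n_planted_cliff_pairs}"
        )
    n_background = n_compounds - 2 * n_planted_cliff_pairs
    if n_background < 0:
        raise MalformedInputError("n_compounds too small for the planted pairs")

    rng = np.random.default_rng(seed)
    targets = [f"T{i:03d}" for i in range(n_targets)]
    rows: list[tuple[str, str, frozenset[str]]] = []
    planted: list[tuple[str, str, int]] = []

    for i in range(n_planted_cliff_pairs):
        core = core_pool[i]
        id_low, id_high = f"PLOW{i:02d}", f"PHIGH{i:02d}"
        t_low = int(rng.integers(0, min(6, n_targets - delta + 1)))
        t_high = t_low + delta
        low_targets = rng.choice(n_targets, size=t_low, replace=False)
        high_targets = rng.choice(n_targets, size=t_high, replace=False)
        rows.append((id_low, attach(core, _PLANT_SUBS[0]), frozenset(targets[j] for j in low_targets)))
        rows.append((id_high, attach(core, _PLANT_SUBS[1]), frozenset(targets[j] for j in high_targets)))
        planted.append((id_low, id_high, delta))

    for i in range(n_background):
        ring_size = 3 + i
        smiles = "C1" + "C" * (ring_size - 2) + "C1"
        mask = rng.random(n_targets) < base_activity_rate
        active = frozenset(t for t, m in zip(targets, mask) if m)
        rows.append((f"BG{i:03d}", smiles, active))

    data = {
        "compound_id": [r[0] for r in rows],
        "smiles": [r[1] for r in rows],
    }
    for t in targets:
        data[t] = [1 if t in r[2] else 0 for r in rows]
    df = pd.DataFrame(data)
    gt = BinaryGroundTruth(
        planted_pairs=planted,
        target_counts={r[0]: len(r[2]) for r in rows},
        compounds={r[0]: r[1] for r in rows},
    )
    return df, gt


def write_ground_truth_json(gt: GridGroundTruth | BinaryGroundTruth, path) -> None:
    """Serialize a ground-truth record as JSON."""
    if isinstance(gt, GridGroundTruth):
        payload = {
            "kind": "analog_grid",
            "compounds": gt.compounds,
            "cells": [[core, sub, cid] for (core, sub), cid in sorted(gt.cell_of.items())],
            "deleted_cells": [list(c) for c in gt.deleted_cells],
            "target_counts": gt.target_counts,
            "target_families": gt.target_families,
        }
    else:
        payload = {
            "kind": "binary_matrix",
            "planted_pairs": [list(p) for p in gt.planted_pairs],
            "target_counts": gt.target_counts,
            "compounds": gt.compounds,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
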