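"""Reading, curation and deduplication of compound activity data.

Activity data arrive either as a long-format table of potency measurements
(equilibrium constants K_i or assay-dependent IC50 values, in nM, with a
relation symbol) or as a wide binary compound × target matrix from profiling
experiments. Curation mirrors the conventions of high-confidence activity
data mining:

* K_i and IC50 measurements are never mixed — one type is selected;
* records with approximate relation symbols (">", "<", "~") are excluded,
  only exact ("=") measurements are kept;
* a potency cutoff (default 10 µM = 10000 nM) defines activity;
* compounds are identified by their desalted canonical structure, so ids
  pointing at the same molecule are merged;
* replicate measurements for one compound–target pair are aggregated by
  geometric mean (potencies live on a log scale); activity status requires
  only one qualifying measurement.

The curated dataset feeds per-compound target profiles: the set of targets a
compound is active against, whose size T is the promiscuity degree used
throughout the package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from ._chem import canonical_smiles
from .errors import EmptyDatasetError, MalformedInputError

__all__ = [
    "ActivityRecord",
    "CuratedDataset",
    "TargetProfile",
    "read_activity_table",
    "read_wide_binary",
    "read_sdf_structures",
    "curate",
    "build_profiles",
    "write_long_csv",
]

MEASUREMENT_TYPES = ("Ki", "IC50", "binary")
RELATIONS = ("=", ">", "<", "~")
APPROXIMATE_RELATIONS = (">", "<", "~")

LONG_HEADER = [
    "compound_id",
    "smiles",
    "target_id",
    "target_family",
    "measurement_type",
    "relation",
    "value_nM",
]


@dataclass(frozen=True)
class ActivityRecord:
    """One compound–target measurement.

    Potency records (Ki/IC50) carry a relation symbol and a positive value
    in nM; binary records carry only an active flag.
    """

    compound_id: str
    smiles: str
    target_id: str
    target_family: str = "other"
    measurement_type: str = "Ki"
    relation: str | None = "="
    value_nm: float | None = None
    active_flag: bool | None = None

    def __post_init__(self):
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise MalformedInputError(
                f"unknown measurement_type {self.measurement_type!r} "
                f"for compound {self.compound_id!r}"
            )
        if self.measurement_type == "binary":
            if self.active_flag is None or self.value_nm is not None or self.relation is not None:
                raise MalformedInputError(
                    f"binary record for {self.compound_id!r} must carry "
                    "active_flag and no value/relation"
                )
        else:
            if self.relation not in RELATIONS:
                raise MalformedInputError(
                    f"unknown relation {self.relation!r} for compound {self.compound_id!r}"
                )
            if self.value_nm is None or not self.value_nm > 0:
                raise MalformedInputError(
                    f"nonpositive or missing potency {self.value_nm!r} "
                    f"for compound {self.compound_id!r}"
                )


@dataclass(frozen=True)
class TargetProfile:
    """The targets a compound is active against; T = len(targets)."""

    compound_id: str
    targets: frozenset[str]

    @property
    def target_count(self) -> int:
        return len(self.targets)


@dataclass
class CuratedDataset:
    """Curated single-measurement-type dataset.

    compounds maps each retained compound id to its desalted canonical
    SMILES; activities holds one aggregated record per compound–target pair;
    merged_ids maps every input id to the representative id it was merged
    into (identity for unmerged compounds).
    """

    compounds: dict[str, str]
    activities: list[ActivityRecord]
    measurement_type: str
    merged_ids: dict[str, str] = field(default_factory=dict)

    @property
    def active_pairs(self) -> set[tuple[str, str]]:
        return {(r.compound_id, r.target_id) for r in self.activities}

    def target_families(self) -> dict[str, str]:
        """target id → family label, as recorded on the activities."""
        return {r.target_id: r.target_family for r in self.activities}


class WideMatrix(NamedTuple):
    """A wide binary matrix: activity records for the 1-cells plus the full
    compound universe (all-zero rows included) and the target column order."""

    records: list[ActivityRecord]
    compounds: dict[str, str]  # id -> smiles, every row
    target_ids: list[str]

    @property
    def n_inactive(self) -> int:
        active = {r.compound_id for r in self.records}
        return sum(1 for c in self.compounds if c not in active)


def _parse_long_row(row: dict, line_no: int) -> ActivityRecord:
    for key in LONG_HEADER:
        if row.get(key) in (None, ""):
            if key in ("relation", "value_nM") and row.get("measurement_type") == "binary":
                continue
            raise MalformedInputError(f"row {line_no}: missing field {key!r}")
    mtype = row["measurement_type"]
    if mtype == "binary":
        return ActivityRecord(
            compound_id=row["compound_id"],
            smiles=row["smiles"],
            target_id=row["target_id"],
            target_family=row["target_family"],
            measurement_type="binary",
            relation=None,
            value_nm=None,
            active_flag=True,
        )
    try:
        value = float(row["value_nM"])
    except ValueError as exc:
        raise MalformedInputError(
            f"row {line_no}: field 'value_nM' is not a number: {row['value_nM']!r}"
        ) from exc
    if not value > 0:
        raise MalformedInputError(f"row {line_no}: field 'value_nM' must be positive, got {value}")
    try:
        return ActivityRecord(
            compound_id=row["compound_id"],
            smiles=row["smiles"],
            target_id=row["target_id"],
            target_family=row["target_family"],
            measurement_type=mtype,
            relation=row["relation"],
            value_nm=value,
        )
    except MalformedInputError as exc:
        raise MalformedInputError(f"row {line_no}: {exc}") from exc


def read_activity_table(path, format: str = "long_csv") -> list[ActivityRecord]:
    """Read activity records from a long CSV or a wide binary CSV.

    Long CSV header: ``compound_id,smiles,target_id,target_family,
    measurement_type,relation,value_nM``. Wide binary CSV: first column
    ``compound_id``, second ``smiles``, one 0/1 column per target; one
    binary record is emitted per 1-cell (use :func:`read_wide_binary` to
    also retain all-zero rows). SMILES strings pass through unmodified.
    """
    if format == "long_csv":
        records = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != LONG_HEADER:
                raise MalformedInputError(
                    f"{path}: expected header {LONG_HEADER}, got {reader.fieldnames}"
                )
            for line_no, row in enumerate(reader, start=2):
                records.append(_parse_long_row(row, line_no))
        return records
    if format == "wide_binary_csv":
        return read_wide_binary(path).records
    raise MalformedInputError(
        f"unknown format {format!r}; use 'long_csv' or 'wide_binary_csv' "
        "(SDF structures: read_sdf_structures)"
    )


def read_wide_binary(path) -> WideMatrix:
    """Read a wide binary compound × target matrix, keeping all-zero rows."""
    records: list[ActivityRecord] = []
    compounds: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[:2] != ["compound_id", "smiles"]:
            raise MalformedInputError(
                f"{path}: wide binary header must start with compound_id,smiles"
            )
        target_ids = header[2:]
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise MalformedInputError(
                    f"{path}: row {line_no} has {len(row)} fields, expected {len(header)}"
                )
            cid, smiles = row[0], row[1]
            compounds[cid] = smiles
            for tid, cell in zip(target_ids, row[2:]):
                if cell not in ("0", "1"):
                    raise MalformedInputError(
                        f"{path}: row {line_no}, target {tid!r}: cell must be 0 or 1, got {cell!r}"
                    )
                if cell == "1":
                    records.append(
                        ActivityRecord(
                            compound_id=cid,
                            smiles=smiles,
                            target_id=tid,
                            measurement_type="binary",
                            relation=None,
                            active_flag=True,
                        )
                    )
    return WideMatrix(records, compounds, target_ids)


def read_sdf_structures(path) -> dict[str, str]:
    """Read structures from an SDF; returns compound_id → SMILES.

    Activity values still come from CSV tables; the SDF only supplies
    structures, keyed by a ``compound_id`` property (falling back to the
    molecule title).
    """
    from rdkit import Chem

    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise MalformedInputError(f"{path}: unparseable SDF record at index {i}")
        if mol.HasProp("compound_id"):
            cid = mol.GetProp("compound_id")
        else:
            cid = mol.GetProp("_Name")
        if not cid:
            raise MalformedInputError(f"{path}: SDF record {i} has no compound_id")
        out[cid] = Chem.MolToSmiles(mol)
    return out


def _geometric_mean(values: list[float]) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def curate(
    records: Iterable[ActivityRecord],
    measurement_type: str,
    potency_threshold_nm: float = 10000.0,
) -> CuratedDataset:
    """Filter, deduplicate and aggregate raw records into a curated dataset.

    Keeps records of the requested measurement type; for potency types only
    exact ("=") measurements at or below the activity cutoff survive — any
    approximate annotation (">", "<", "~") is excluded. Compound ids whose
    desalted canonical structures coincide are merged (activities unioned,
    the lexicographically smallest id representing the group). Replicate
    measurements for one compound–target pair collapse to their geometric
    mean. Raises :class:`EmptyDatasetError` when nothing survives.
    """
    records = list(records)
    if not records:
        raise EmptyDatasetError("no input records")
    if measurement_type not in MEASUREMENT_TYPES:
        raise MalformedInputError(f"unknown measurement_type {measurement_type!r}")

    kept: list[ActivityRecord] = []
    for rec in records:
        if rec.measurement_type != measurement_type:
            continue
        if measurement_type == "binary":
            if rec.active_flag:
                kept.append(rec)
        elif rec.relation == "=" and rec.value_nm <= potency_threshold_nm:
            kept.append(rec)
    if not kept:
        raise EmptyDatasetError(
            f"no records survive curation (type={measurement_type!r}, "
            f"threshold={potency_threshold_nm} nM)"
        )

    # structure-keyed merge of compound ids
    structure_of: dict[str, str] = {}
    for rec in kept:
        if rec.compound_id not in structure_of:
            structure_of[rec.compound_id] = canonical_smiles(rec.smiles, rec.compound_id)
    rep_of_structure: dict[str, str] = {}
    for cid in sorted(structure_of):
        rep_of_structure.setdefault(structure_of[cid], cid)
    merged_ids = {cid: rep_of_structure[structure_of[cid]] for cid in structure_of}

    # aggregate per (representative compound, target)
    grouped: dict[tuple[str, str], list[ActivityRecord]] = {}
    for rec in kept:
        grouped.setdefault((merged_ids[rec.compound_id], rec.target_id), []).append(rec)

    activities: list[ActivityRecord] = []
    for (rep, target), recs in sorted(grouped.items()):
        first = recs[0]
        if measurement_type == "binary":
            value = None
        else:
            value = _geometric_mean([r.value_nm for r in recs])
        activities.append(
            ActivityRecord(
                compound_id=rep,
                smiles=structure_of[rep],
                target_id=target,
                target_family=first.target_family,
                measurement_type=measurement_type,
                relation=None if measurement_type == "binary" else "=",
                value_nm=value,
                active_flag=True if measurement_type == "binary" else None,
            )
        )

    compounds = {rep: structure_of[rep] for rep in sorted(set(merged_ids.values()))}
    return CuratedDataset(compounds, activities, measurement_type, merged_ids)


def build_profiles(dataset: CuratedDataset) -> list[TargetProfile]:
    """One target profile per curated compound, ordered by compound id."""
    targets: dict[str, set[str]] = {}
    for rec in dataset.activities:
        targets.setdefault(rec.compound_id, set()).add(rec.target_id)
    return [
        TargetProfile(cid, frozenset(tids)) for cid, tids in sorted(targets.items())
    ]


def write_long_csv(records: Iterable[ActivityRecord], path) -> None:
    """Write records in the long CSV dialect (round-trips through
    :func:`read_activity_table`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LONG_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    r.smiles,
                    r.target_id,
                    r.target_family,
                    r.measurement_type,
                    r.relation if r.relation is not None else "",
                    repr(r.value_nm) if r.value_nm is not None else "",
                ]
            )
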