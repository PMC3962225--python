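"""Single-cut molecular fragmentation and matched-molecular-pair generation.

A matched molecular pair (MMP) is a pair of compounds that differ only by the
exchange of two substructures at a single site — a chemical transformation.
Pairs are found by the fragmentation-and-indexing strategy: every eligible
acyclic single bond of each molecule is cut once, the resulting (core,
substituent) fragment pairs are canonicalised and indexed by core, and any
two compounds sharing a core with different substituents form an MMP.

Transformation size restrictions keep exchanges small and chemically
meaningful: the substituent may not exceed a heavy-atom cap, the core must be
at least a fixed multiple of the substituent, and the two exchanged
substituents may not differ by more than a heavy-atom delta.

Two levels of fragmentation are supported. At the compound level, cut
fragments carry a ``[*:1]`` attachment point. Cores themselves can then be
fragmented a second time (``core_level_mmps``); the original ``[*:1]`` marker
is treated as an inert atom that is never cut, and the second cut introduces
``[*:2]``. Core-level fragmentation additionally enumerates hydrogen
substituents so that cores differing by an H→R replacement are related.
No third fragmentation round exists.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem

from ._chem import heavy_atom_count, mol_from_smiles
from .errors import MalformedInputError, StructureError

__all__ = [
    "SizeLimits",
    "Fragmentation",
    "MatchedMolecularPair",
    "enumerate_fragmentations",
    "passes_size_restrictions",
    "generate_mmps",
    "core_level_mmps",
    "reassemble",
    "write_mmp_csv",
    "read_mmp_csv",
]

#: Canonical SMILES of the hydrogen substituent used in core-level cuts.
HYDROGEN_SUBSTITUENT_1 = "[H][*:1]"
HYDROGEN_SUBSTITUENT_2 = "[H][*:2]"


@dataclass(frozen=True)
class SizeLimits:
    """Transformation size restrictions (heavy-atom based).

    max_substituent: largest substituent allowed on either side of a pair.
    core_to_substituent_ratio: the core must have at least this many times
        the substituent's heavy atoms.
    max_exchange_delta: largest allowed heavy-atom difference between the
        two exchanged substituents of an MMP.
    """

    max_substituent: int = 13
    core_to_substituent_ratio: float = 2.0
    max_exchange_delta: int = 8


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition of a parent structure.

    ``core`` is the larger fragment, ``substituent`` the smaller (ties broken
    lexicographically on the canonical fragment strings); each carries exactly
    one new attachment point.
    """

    parent_id: str
    core: str
    substituent: str
    core_heavy_atoms: int
    substituent_heavy_atoms: int


@dataclass(frozen=True)
class MatchedMolecularPair:
    """Two compounds exchanging ``substituent_a`` → ``substituent_b`` on a
    shared core. ``substituent_a < substituent_b`` lexicographically, which
    fixes compound order and makes the stored object unique."""

    compound_a: str
    compound_b: str
    core: str
    substituent_a: str
    substituent_b: str

    @property
    def transformation(self) -> tuple[str, str]:
        return (self.substituent_a, self.substituent_b)

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset((self.compound_a, self.compound_b))


def _as_mol(structure: str | Chem.Mol, compound_id: str | None = None) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    return mol_from_smiles(structure, compound_id)


def _canonical_fragment(mol: Chem.Mol, map_num: int) -> tuple[str, int]:
    """Canonical SMILES and heavy-atom count of a cut fragment; the new
    dummy atom (isotope-labelled by FragmentOnBonds) is rewritten as a
    map-numbered wildcard."""
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() == 9:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(map_num)
    return Chem.MolToSmiles(mol), heavy_atom_count(mol)


def _order_core_sub(frag_a: tuple[str, int], frag_b: tuple[str, int]) -> tuple[tuple[str, int], tuple[str, int]]:
    """Assign core (larger side) and substituent; lexicographic tie-break."""
    if frag_a[1] != frag_b[1]:
        return (frag_a, frag_b) if frag_a[1] > frag_b[1] else (frag_b, frag_a)
    return (frag_a, frag_b) if frag_a[0] <= frag_b[0] else (frag_b, frag_a)


def enumerate_fragmentations(
    structure: str | Chem.Mol,
    parent_id: str = "",
    include_hydrogen: bool = False,
) -> frozenset[Fragmentation]:
    """All single-cut fragmentations of a molecule.

    Every acyclic single bond between two heavy atoms is cut once. Existing
    wildcard attachment points (from a previous fragmentation round) are
    inert: their bonds are never cut and they do not count as heavy atoms.
    With ``include_hydrogen`` (core-level mode), one extra fragmentation per
    chemically distinct C–H/N–H/... position is produced, with the hydrogen
    atom as the substituent.

    The new attachment point is ``[*:1]``, or ``[*:2]`` when the input
    already carries a ``[*:1]`` marker.
    """
    mol = _as_mol(structure, parent_id or None)
    has_marker = any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())
    map_num = 2 if has_marker else 1

    out: set[Fragmentation] = set()
    cuttable = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]
    for bond_idx in cuttable:
        # isotope 9 temporarily tags the new dummies so they can be told
        # apart from a pre-existing [*:1] marker
        pieces = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(9, 9)])
        frags = Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=True)
        if len(frags) != 2:  # pragma: no cover - single acyclic cut always splits
            continue
        fa = _canonical_fragment(frags[0], map_num)
        fb = _canonical_fragment(frags[1], map_num)
        (core, core_n), (sub, sub_n) = _order_core_sub(fa, fb)
        out.add(Fragmentation(parent_id, core, sub, core_n, sub_n))

    if include_hydrogen:
        h_sub = HYDROGEN_SUBSTITUENT_2 if map_num == 2 else HYDROGEN_SUBSTITUENT_1
        n_heavy = heavy_atom_count(mol)
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
                continue
            rw = Chem.RWMol(mol)
            dummy = Chem.Atom(0)
            dummy.SetAtomMapNum(map_num)
            di = rw.AddAtom(dummy)
            rw.AddBond(atom.GetIdx(), di, Chem.BondType.SINGLE)
            rw.GetAtomWithIdx(atom.GetIdx()).SetNoImplicit(False)
            try:
                core_mol = rw.GetMol()
                Chem.SanitizeMol(core_mol)
            except (Chem.AtomValenceException, ValueError):  # pragma: no cover
                continue
            out.add(
                Fragmentation(parent_id, Chem.MolToSmiles(core_mol), h_sub, n_heavy, 0)
            )
    return frozenset(out)


def passes_size_restrictions(f: Fragmentation, limits: SizeLimits) -> bool:
    """True iff the fragmentation respects the substituent cap and the
    core-to-substituent ratio."""
    return (
        f.substituent_heavy_atoms <= limits.max_substituent
        and f.core_heavy_atoms
        >= limits.core_to_substituent_ratio * f.substituent_heavy_atoms
    )


def _make_mmp(core: str, id_a: str, sub_a: str, id_b: str, sub_b: str) -> MatchedMolecularPair:
    if sub_b < sub_a:
        id_a, id_b, sub_a, sub_b = id_b, id_a, sub_b, sub_a
    return MatchedMolecularPair(id_a, id_b, core, sub_a, sub_b)


def _pair_mmps_from_index(
    index: Mapping[str, list[tuple[str, str, int, int]]],
    limits: SizeLimits,
) -> set[MatchedMolecularPair]:
    """Candidate MMPs from a core→[(id, sub, sub_heavy, core_heavy)] index,
    deduplicated so each unordered compound pair keeps its largest shared
    core (tie: lexicographically smallest core string)."""
    best: dict[frozenset[str], tuple[int, str, MatchedMolecularPair]] = {}
    for core, entries in index.items():
        core_heavy = entries[0][3]
        for i in range(len(entries)):
            id_a, sub_a, ha, _ = entries[i]
            for j in range(i + 1, len(entries)):
                id_b, sub_b, hb, _ = entries[j]
                if id_a == id_b or sub_a == sub_b:
                    continue
                if abs(ha - hb) > limits.max_exchange_delta:
                    continue
                pair = frozenset((id_a, id_b))
                mmp = _make_mmp(core, id_a, sub_a, id_b, sub_b)
                key = (core_heavy, core)
                prev = best.get(pair)
                if prev is None or key[0] > prev[0] or (key[0] == prev[0] and core < prev[1]):
                    best[pair] = (core_heavy, core, mmp)
    return {mmp for _, _, mmp in best.values()}


def _build_index(
    structures: Mapping[str, str | Chem.Mol],
    limits: SizeLimits,
    include_hydrogen: bool,
) -> dict[str, list[tuple[str, str, int, int]]]:
    index: dict[str, list[tuple[str, str, int, int]]] = defaultdict(list)
    for cid, structure in structures.items():
        for f in enumerate_fragmentations(structure, cid, include_hydrogen=include_hydrogen):
            if passes_size_restrictions(f, limits):
                index[f.core].append((cid, f.substituent, f.substituent_heavy_atoms, f.core_heavy_atoms))
    return index


def generate_mmps(
    structures: Mapping[str, str | Chem.Mol],
    limits: SizeLimits | None = None,
) -> set[MatchedMolecularPair]:
    """All transformation-size-restricted MMPs over a compound set.

    ``structures`` maps compound id → structure (SMILES or Mol); a curated
    dataset's ``compounds`` mapping can be passed directly. Each unordered
    compound pair contributes at most one MMP (largest shared core).
    """
    limits = limits or SizeLimits()
    index = _build_index(structures, limits, include_hydrogen=False)
    return _pair_mmps_from_index(index, limits)


def core_level_mmps(
    cores: Iterable[str],
    limits: SizeLimits | None = None,
) -> set[MatchedMolecularPair]:
    """MMPs between core fragments (the second fragmentation round).

    Cores are treated as molecules whose ``[*:1]`` attachment marker is
    inert. Hydrogen substituents are enumerated so that cores differing by
    an H→R replacement at one position are paired. The resulting pairs
    relate cores distinguished by a structural change at a single site;
    their fragments carry ``[*:2]`` and are never fragmented further.
    """
    limits = limits or SizeLimits()
    structures: dict[str, str] = {c: c for c in set(cores)}
    index = _build_index(structures, limits, include_hydrogen=True)
    return _pair_mmps_from_index(index, limits)


def reassemble(core: str, substituent: str) -> str:
    """Canonical SMILES of core + substituent joined at their attachment
    points (map 1 for compound-level fragments, map 2 for core-level)."""
    from ._chem import attach

    map_num = 2 if ":2]" in substituent else 1
    return attach(core, substituent, map_num=map_num)


# ---------------------------------------------------------------------------
# CSV round-trip

_MMP_HEADER = ["compound_a", "compound_b", "core", "substituent_a", "substituent_b"]


def write_mmp_csv(mmps: Iterable[MatchedMolecularPair], path) -> None:
    rows = sorted(
        (m.compound_a, m.compound_b, m.core, m.substituent_a, m.substituent_b)
        for m in mmps
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MMP_HEADER)
        writer.writerows(rows)


def read_mmp_csv(path) -> set[MatchedMolecularPair]:
    out: set[MatchedMolecularPair] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _MMP_HEADER:
            raise MalformedInputError(f"{path}: expected MMP header {_MMP_HEADER}, got {header}")
        for i, row in enumerate(reader, start=2):
            if len(row) != 5:
                raise MalformedInputError(f"{path}: row {i} has {len(row)} fields, expected 5")
            out.add(MatchedMolecularPair(*row))
    return out
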