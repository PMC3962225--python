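"""Thin RDKit helpers shared across modules.

Centralises SMILES parsing, canonicalisation, salt stripping and fragment
reassembly so every module speaks the same canonical dialect. Attachment
points are wildcard atoms carrying an atom-map index (``[*:1]`` for the
compound-level cut, ``[*:2]`` for the second, core-level cut).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import StructureError

# RDKit is chatty on stderr; errors are surfaced as exceptions instead.
RDLogger.DisableLog("rdApp.*")

_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()


def mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES {smiles!r}", compound_id)
    return mol


def desalt(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest covalent unit (counterion / solvate stripping)."""
    if len(Chem.GetMolFrags(mol)) == 1:
        return mol
    return _LARGEST_FRAGMENT.choose(mol)


def canonical_smiles(smiles: str, compound_id: str | None = None) -> str:
    """Desalted canonical SMILES used as the structure identity key."""
    return Chem.MolToSmiles(desalt(mol_from_smiles(smiles, compound_id)))


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-wildcard atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def molecular_weight(smiles: str, compound_id: str | None = None) -> float:
    """Average molecular weight (Da) of the desalted structure."""
    return Descriptors.MolWt(desalt(mol_from_smiles(smiles, compound_id)))


def attach(core_smiles: str, substituent_smiles: str, map_num: int = 1) -> str:
    """Join two fragments at their matching ``[*:map_num]`` attachment points.

    Returns the canonical SMILES of the assembled molecule. The hydrogen
    substituent ``[H][*:n]`` is handled by capping the attachment point.
    Raises :class:`StructureError` when the fragments cannot be joined into
    a chemically valid molecule.
    """
    core = Chem.MolFromSmiles(core_smiles)
    sub = Chem.MolFromSmiles(substituent_smiles, sanitize=False)
    if core is None or sub is None:
        raise StructureError(
            f"unparseable fragment in ({core_smiles!r}, {substituent_smiles!r})"
        )
    try:
        Chem.SanitizeMol(sub)
        combined = Chem.CombineMols(core, sub)
        joined = Chem.molzip(combined)
        joined = Chem.RemoveHs(joined)
        Chem.SanitizeMol(joined)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError, RuntimeError) as exc:
        raise StructureError(
            f"cannot assemble {core_smiles!r} + {substituent_smiles!r}: {exc}"
        ) from exc
    smiles = Chem.MolToSmiles(joined)
    if "*" in smiles and map_num == 1:
        # level-1 assembly must consume every attachment point
        raise StructureError(
            f"dangling attachment point assembling {core_smiles!r} + {substituent_smiles!r}"
        )
    return smiles
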