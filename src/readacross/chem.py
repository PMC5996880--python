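"""Chemical structure handling.

SMILES canonicalization, MolPrint2D atom-environment fingerprints and the
Tanimoto (Jaccard) similarity used for neighbor search.

A MolPrint2D fingerprint describes each heavy atom of a molecule by its own
atom type together with the multisets of atom types found at bond distance 1
and 2.  Two molecules are similar when they share many such atom
environments; similarity is quantified as |A ∩ B| / |A ∪ B| on the sets of
distinct environments.  Atom environments are generated dynamically from the
structure and do not rely on a predefined fragment catalogue, so they can
pick up substructures that fixed keys (FP3/FP4/MACCS) miss.

Atom typing here is the element symbol, lower-cased for aromatic atoms
("C" vs "c").  This is deliberately toolkit-independent; a different typing
scheme can be plugged in via the ``atom_typer`` argument of
:func:`molprint2d`.  Hydrogens are not part of the environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

#: Canonicalization dialect identifier, recorded in dataset metadata so that
#: duplicate detection is reproducible across runs.
CANONICALIZATION = f"rdkit-{rdkit.__version__}"

#: Environment radius in bonds (MolPrint2D convention).
ENVIRONMENT_DEPTH = 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule.

    Carries the offending SMILES and, when known, a record label so that
    bad rows in an input table can be reported individually.
    """

    def __init__(self, smiles: str, record: str | None = None):
        self.smiles = smiles
        self.record = record
        where = f" (record {record})" if record is not None else ""
        super().__init__(f"unparsable SMILES{where}: {smiles!r}")


class UndefinedSimilarityError(ValueError):
    """Tanimoto similarity of two empty fingerprints is undefined (0/0)."""


@dataclass(frozen=True)
class Structure:
    """A canonicalized molecule with its fingerprint and basic descriptors.

    Attributes
    ----------
    input_smiles : str
        The SMILES as given by the caller.
    canonical_smiles : str
        Canonical SMILES under the dialect named in :data:`CANONICALIZATION`;
        identical for any two valid spellings of the same molecule and used
        for duplicate detection and leakage control.
    fingerprint : frozenset of str
        Distinct MolPrint2D atom environments (set semantics, no counts).
    mol_weight : float
        Average molecular weight in g/mol, used for mg -> mmol conversion.
    heavy_atoms : int
        Number of non-hydrogen atoms.
    """

    input_smiles: str
    canonical_smiles: str
    fingerprint: frozenset[str]
    mol_weight: float
    heavy_atoms: int

    def __repr__(self) -> str:  # keep neighbor tables readable
        return f"Structure({self.canonical_smiles!r})"


def default_atom_typer(atom: Chem.Atom) -> str:
    """Element symbol, lower-cased when aromatic (e.g. 'C' vs 'c')."""
    symbol = atom.GetSymbol()
    return symbol.lower() if atom.GetIsAromatic() else symbol


def _mol_from_smiles(smiles: str, record: str | None = None) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), record)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, record)
    return mol


def molprint2d(mol: Chem.Mol, atom_typer=default_atom_typer) -> frozenset[str]:
    """MolPrint2D atom environments of a molecule as a set of strings.

    One environment per heavy atom: the central atom type followed by the
    sorted atom types at bond distance 1 and 2.  Sorting makes the
    serialization independent of atom order, so any SMILES spelling of the
    same molecule yields the same feature set.  Duplicate environments
    (symmetry-equivalent atoms) collapse; the result therefore has at most
    as many features as heavy atoms.
    """
    n = mol.GetNumAtoms()
    if n == 0:
        return frozenset()
    dist = Chem.GetDistanceMatrix(mol)
    types = [atom_typer(mol.GetAtomWithIdx(i)) for i in range(n)]
    features = set()
    for i in range(n):
        shell1 = sorted(types[j] for j in range(n) if dist[i][j] == 1)
        shell2 = sorted(types[j] for j in range(n) if dist[i][j] == 2)
        features.add(f"{types[i]};1:{','.join(shell1)};2:{','.join(shell2)}")
    return frozenset(features)


def canonicalize(smiles: str, record: str | None = None) -> Structure:
    """Parse a SMILES and compute canonical form, fingerprint and descriptors.

    Raises :class:`SmilesParseError` for unparsable input or for "molecules"
    without heavy atoms; the optional ``record`` label is attached to the
    error so callers can report which table row failed.
    """
    mol = _mol_from_smiles(smiles, record)
    heavy = mol.GetNumHeavyAtoms()
    if heavy < 1:
        raise SmilesParseError(smiles, record)
    return Structure(
        input_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        fingerprint=molprint2d(mol),
        mol_weight=Descriptors.MolWt(mol),
        heavy_atoms=heavy,
    )


def tanimoto(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard/Tanimoto index |A ∩ B| / |A ∪ B| of two feature sets."""
    if not a and not b:
        raise UndefinedSimilarityError("similarity of two empty fingerprints is undefined")
    a = set(a)
    b = set(b)
    return len(a & b) / len(a | b)
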