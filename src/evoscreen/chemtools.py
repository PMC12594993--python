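"""Chemistry primitives shared across the package.

Everything here is a thin, deterministic layer over RDKit: product assembly
from a (reaction, synthons) genotype, canonical molecule keys, Morgan
(extended-connectivity) fingerprints, Tanimoto similarity, heavy-atom counts
and Bemis-Murcko scaffolds.  Stereochemistry and protonation states are
deliberately ignored throughout: molecules are compared and keyed by their
canonical SMILES as RDKit writes it from the input connectivity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .library_model import CombinatorialLibrary, LigandGenotype

# RDKit is chatty about unsanitizable reaction products; failures are
# surfaced through AssemblyError instead.
RDLogger.DisableLog("rdApp.*")


class AssemblyError(ValueError):
    """Raised when a genotype's synthons cannot react under its SMARTS."""

    def __init__(self, message: str, genotype=None):
        super().__init__(message)
        self.genotype = genotype


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan/ECFP fingerprint parameters used library-wide.

    Defaults (radius 2, 2048 bits, i.e. ECFP4) are pinned so that similarity
    thresholds — mutation windows and the 0.95 duplicate penalty — mean the
    same thing in every run.
    """

    radius: int = 2
    n_bits: int = 2048

    def as_dict(self) -> dict:
        return {"kind": "morgan", "radius": self.radius, "n_bits": self.n_bits}


@functools.lru_cache(maxsize=8)
def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint_mol(mol: Chem.Mol, config: FingerprintConfig):
    """Binary Morgan fingerprint of an RDKit molecule."""
    return _generator(config.radius, config.n_bits).GetFingerprint(mol)


def fingerprint_smiles(smiles: str, config: FingerprintConfig):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return fingerprint_mol(mol, config)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Two all-zero fingerprints are defined as identical (similarity 1.0);
    RDKit itself returns 0.0 for that degenerate pair.
    """
    if fp_a.GetNumBits() != fp_b.GetNumBits():
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.GetNumBits()} vs {fp_b.GetNumBits()}"
        )
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def bulk_tanimoto(fp, fps) -> list[float]:
    """Tanimoto of one fingerprint against a sequence (vectorized in RDKit)."""
    if not fps:
        return []
    if fp.GetNumOnBits() == 0:
        return [1.0 if other.GetNumOnBits() == 0 else 0.0 for other in fps]
    return DataStructs.BulkTanimotoSimilarity(fp, list(fps))


@dataclass(frozen=True)
class ProductMolecule:
    """An assembled product: canonical SMILES key, size and fingerprint."""

    canonical_smiles: str
    heavy_atoms: int
    fingerprint: object

    @classmethod
    def from_mol(cls, mol: Chem.Mol, config: FingerprintConfig) -> "ProductMolecule":
        return cls(
            canonical_smiles=Chem.MolToSmiles(mol),
            heavy_atoms=mol.GetNumHeavyAtoms(),
            fingerprint=fingerprint_mol(mol, config),
        )

    @classmethod
    def from_smiles(cls, smiles: str, config: FingerprintConfig) -> "ProductMolecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_mol(mol, config)


@functools.lru_cache(maxsize=1024)
def reaction_from_smarts(smarts: str):
    rxn = AllChem.ReactionFromSmarts(smarts)
    if rxn is None:
        raise ValueError(f"unparsable reaction SMARTS: {smarts!r}")
    rxn.Initialize()
    return rxn


def assemble_product(
    genotype: "LigandGenotype",
    library: "CombinatorialLibrary",
    use_cache: bool = True,
) -> ProductMolecule:
    """Run a genotype's reaction SMARTS on its ordered synthons.

    The reaction may propose several product candidates (multiple matches of
    a reactant template); the lexicographically smallest canonical SMILES is
    chosen so assembly is deterministic.  A chemically impossible combination
    raises :class:`AssemblyError` rather than crashing — callers assign a
    worst-possible fitness.

    Results are memoized per library (a genotype always maps to the same
    product), which makes re-evaluating duplicate individuals essentially
    free.
    """
    key = genotype.key()
    if use_cache:
        cached = library._product_cache.get(key)
        if cached is not None:
            if isinstance(cached, AssemblyError):
                raise cached
            return cached

    reaction = library.reaction(genotype.reaction_id)
    rxn = reaction_from_smarts(reaction.smarts)
    reactants = tuple(
        library.synthon(genotype.reaction_id, i, sid).mol
        for i, sid in enumerate(genotype.synthon_ids)
    )
    candidates: set[str] = set()
    for product_tuple in rxn.RunReactants(reactants):
        for product in product_tuple:
            try:
                Chem.SanitizeMol(product)
            except Exception:
                continue
            candidates.add(Chem.MolToSmiles(product))
    if not candidates:
        err = AssemblyError(
            f"reaction {reaction.reaction_id} produced no valid product for "
            f"synthons {genotype.synthon_ids}",
            genotype=genotype,
        )
        if use_cache:
            library._product_cache[key] = err
        raise err
    smiles = min(candidates)
    product = ProductMolecule.from_smiles(smiles, library.fingerprint_config)
    if use_cache:
        library._product_cache[key] = product
    return product


def heavy_atom_count(molecule) -> int:
    """Number of non-hydrogen atoms (implicit and explicit H excluded)."""
    if isinstance(molecule, ProductMolecule):
        return molecule.heavy_atoms
    if isinstance(molecule, Chem.Mol):
        return molecule.GetNumHeavyAtoms()
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {molecule!r}")
    return mol.GetNumHeavyAtoms()


def murcko_scaffold(molecule) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; acyclic molecules map to ''."""
    if isinstance(molecule, ProductMolecule):
        smiles = molecule.canonical_smiles
    elif isinstance(molecule, Chem.Mol):
        smiles = Chem.MolToSmiles(molecule)
    else:
        smiles = molecule
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)
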