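"""Model of a reaction-defined (make-on-demand) combinatorial library.

A library is a set of chemical reactions, each with an ordered list of
reagent positions, and per position a list of purchasable building blocks
("synthons").  A molecule is identified not by its structure but by its
*genotype*: a reaction id plus one synthon id per position.  Every genotype
that satisfies the closure invariants below corresponds to a synthesizable
product, which is the property the evolutionary search relies on — it never
leaves the make-on-demand space.

File dialects (tab-separated, with header):

* reactions file: ``reaction_id  smarts  n_positions``
* reagents file:  ``smiles  synthon_id  reaction_id  position`` (0-based)
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemtools import FingerprintConfig, fingerprint_mol, reaction_from_smarts

logger = logging.getLogger(__name__)


class LibraryValidationError(ValueError):
    """A structural problem in the reaction/reagent definitions."""


@dataclass(frozen=True)
class SynthonRecord:
    """One building block: id, SMILES (reaction handles intact), fingerprint.

    Fingerprints are computed once at load time; every similarity lookup in
    mutation, crossover and diversity selection reuses them.
    """

    synthon_id: str
    smiles: str
    fingerprint: object = None
    mol: object = field(default=None, repr=False, compare=False)


@dataclass
class ReactionRecord:
    reaction_id: str
    smarts: str
    positions: list  # list of lists of SynthonRecord, one list per reagent position

    def __post_init__(self):
        if len(self.positions) < 2:
            raise LibraryValidationError(
                f"reaction {self.reaction_id!r} has {len(self.positions)} "
                "position(s); at least two components are required"
            )

    @property
    def arity(self) -> int:
        return len(self.positions)

    @property
    def product_count(self) -> int:
        return count_products(self)


def count_products(reaction: ReactionRecord) -> int:
    """Size of a reaction's product space: the product of its position sizes."""
    n = 1
    for pos in reaction.positions:
        n *= len(pos)
    return n


@dataclass(frozen=True)
class LigandGenotype:
    """A molecule identity: (reaction id, ordered synthon ids)."""

    reaction_id: str
    synthon_ids: tuple

    def key(self) -> tuple:
        return (self.reaction_id, self.synthon_ids)


@dataclass
class CombinatorialLibrary:
    reactions: list
    fingerprint_config: FingerprintConfig = field(default_factory=FingerprintConfig)
    _by_id: dict = field(init=False, repr=False)
    _synthon_index: dict = field(init=False, repr=False)
    _product_cache: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise LibraryValidationError("duplicate reaction ids in library")
        self._by_id = {r.reaction_id: r for r in self.reactions}
        self._synthon_index = {
            (r.reaction_id, i, s.synthon_id): s
            for r in self.reactions
            for i, pos in enumerate(r.positions)
            for s in pos
        }

    @property
    def total_products(self) -> int:
        return sum(count_products(r) for r in self.reactions)

    def reaction(self, reaction_id: str) -> ReactionRecord:
        try:
            return self._by_id[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def synthon(self, reaction_id: str, position: int, synthon_id: str) -> SynthonRecord:
        try:
            return self._synthon_index[(reaction_id, position, synthon_id)]
        except KeyError:
            raise KeyError(
                f"synthon {synthon_id!r} not at position {position} of "
                f"reaction {reaction_id!r}"
            ) from None

    def validate_genotype(self, genotype: LigandGenotype) -> None:
        """Raise unless the genotype satisfies the closure invariants."""
        reaction = self.reaction(genotype.reaction_id)
        if len(genotype.synthon_ids) != reaction.arity:
            raise ValueError(
                f"genotype arity {len(genotype.synthon_ids)} != reaction "
                f"arity {reaction.arity} for {genotype.reaction_id!r}"
            )
        for i, sid in enumerate(genotype.synthon_ids):
            self.synthon(genotype.reaction_id, i, sid)

    def digest(self) -> dict:
        """JSON-serializable provenance summary with a stable content hash."""
        payload = {
            "fingerprint": self.fingerprint_config.as_dict(),
            "reactions": [
                {
                    "reaction_id": r.reaction_id,
                    "smarts": r.smarts,
                    "position_sizes": [len(p) for p in r.positions],
                    "product_count": count_products(r),
                    "synthon_ids": [[s.synthon_id for s in p] for p in r.positions],
                }
                for r in self.reactions
            ],
            "total_products": self.total_products,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        payload["sha256"] = hashlib.sha256(blob).hexdigest()
        return payload


def load_library(
    reactions_source,
    reagents_source,
    fingerprint_config: Optional[FingerprintConfig] = None,
) -> CombinatorialLibrary:
    """Load and validate a library from the two tab-separated files.

    Synthons whose SMILES fail to parse, or which do not match their
    position's reactant template, are dropped with a logged warning — real
    reagent files are noisy and a single bad row should not abort a load.
    A position left with zero valid synthons is a hard error, as is a
    reaction with fewer than two components.
    """
    fingerprint_config = fingerprint_config or FingerprintConfig()
    reactions_path, reagents_path = Path(reactions_source), Path(reagents_source)
    for p in (reactions_path, reagents_path):
        if not p.exists():
            raise FileNotFoundError(p)

    reactions_df = pd.read_csv(reactions_path, sep="\t", dtype=str)
    required = {"reaction_id", "smarts", "n_positions"}
    if not required.issubset(reactions_df.columns):
        raise LibraryValidationError(
            f"reactions file missing columns {sorted(required - set(reactions_df.columns))}"
        )
    reagents_df = pd.read_csv(reagents_path, sep="\t", dtype=str)
    required = {"smiles", "synthon_id", "reaction_id", "position"}
    if not required.issubset(reagents_df.columns):
        raise LibraryValidationError(
            f"reagents file missing columns {sorted(required - set(reagents_df.columns))}"
        )

    dropped = 0
    reactions: list[ReactionRecord] = []
    for row in reactions_df.itertuples(index=False):
        n_positions = int(row.n_positions)
        if n_positions < 2:
            raise LibraryValidationError(
                f"reaction {row.reaction_id!r} declares {n_positions} position(s); "
                "at least two components are required"
            )
        rxn = reaction_from_smarts(row.smarts)
        if rxn.GetNumReactantTemplates() != n_positions:
            raise LibraryValidationError(
                f"reaction {row.reaction_id!r}: SMARTS has "
                f"{rxn.GetNumReactantTemplates()} reactant templates but "
                f"n_positions = {n_positions}"
            )
        positions: list[list[SynthonRecord]] = [[] for _ in range(n_positions)]
        rows = reagents_df[reagents_df["reaction_id"] == row.reaction_id]
        for reagent in rows.itertuples(index=False):
            pos = int(reagent.position)
            if not 0 <= pos < n_positions:
                logger.warning(
                    "dropping synthon %s of reaction %s: position %d out of range",
                    reagent.synthon_id, row.reaction_id, pos,
                )
                dropped += 1
                continue
            mol = Chem.MolFromSmiles(reagent.smiles)
            if mol is None:
                logger.warning(
                    "dropping synthon %s of reaction %s: unparsable SMILES %r",
                    reagent.synthon_id, row.reaction_id, reagent.smiles,
                )
                dropped += 1
                continue
            if not mol.HasSubstructMatch(rxn.GetReactantTemplate(pos)):
                logger.warning(
                    "dropping synthon %s of reaction %s: does not match "
                    "reactant template %d",
                    reagent.synthon_id, row.reaction_id, pos,
                )
                dropped += 1
                continue
            positions[pos].append(
                SynthonRecord(
                    synthon_id=str(reagent.synthon_id),
                    smiles=str(reagent.smiles),
                    fingerprint=fingerprint_mol(mol, fingerprint_config),
                    mol=mol,
                )
            )
        for i, pos_list in enumerate(positions):
            if not pos_list:
                raise LibraryValidationError(
                    f"reaction {row.reaction_id!r} position {i} has no valid synthons"
                )
        reactions.append(
            ReactionRecord(reaction_id=str(row.reaction_id), smarts=str(row.smarts),
                           positions=positions)
        )
    if dropped:
        logger.warning("dropped %d invalid synthon(s) during load", dropped)
    library = CombinatorialLibrary(reactions=reactions,
                                   fingerprint_config=fingerprint_config)
    if library.total_products < 1:
        raise LibraryValidationError("library enumerates zero products")
    return library


def sample_random_genotype(
    library: CombinatorialLibrary, rng: np.random.Generator
) -> LigandGenotype:
    """Draw a random genotype: reaction weighted by its product count, then
    one uniform synthon per position.

    This is both the initial-population sampler and the random screening
    baseline — using the same distribution for both is what makes the
    enrichment factor a like-for-like comparison.
    """
    if not library.reactions or library.total_products < 1:
        raise ValueError("cannot sample from an empty library")
    weights = np.array([count_products(r) for r in library.reactions], dtype=float)
    reaction = library.reactions[rng.choice(len(weights), p=weights / weights.sum())]
    synthon_ids = tuple(
        pos[rng.integers(len(pos))].synthon_id for pos in reaction.positions
    )
    return LigandGenotype(reaction_id=reaction.reaction_id, synthon_ids=synthon_ids)


def enumerate_genotypes(reaction: ReactionRecord) -> Iterator[LigandGenotype]:
    """Yield every genotype of a reaction exactly once, lexicographic in
    position-list (file) order; the stream length equals ``count_products``."""
    id_lists = [[s.synthon_id for s in pos] for pos in reaction.positions]
    for combo in itertools.product(*id_lists):
        yield LigandGenotype(reaction_id=reaction.reaction_id, synthon_ids=combo)
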