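"""Fitness evaluation: backends, ligand-efficiency normalization, caching
and the intra-population similarity penalty.

The raw score of a molecule is an interface energy in the docking sense:
a real number, lower is better.  Selection never acts on the raw energy
directly but on

    fitness_n(x) = energy(x) / heavyatoms(x)**(1/n)

the "lid_root" family of ligand-efficiency scores.  n = 1 is classic
ligand efficiency per heavy atom; n = 2 (the default, "lid_root2") is the
geometric mean of total energy and per-atom efficiency and counteracts the
well-known bias of docking scores toward ever larger molecules.

On top of the fitness a nonnegative *penalty* is added for near-duplicate
molecules within one population, so a single good scorer cannot take over
the gene pool.  Selection uses the effective score ``fitness + penalty``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol

import numpy as np

from .chemtools import AssemblyError, ProductMolecule, assemble_product, bulk_tanimoto
from .library_model import CombinatorialLibrary, LigandGenotype

logger = logging.getLogger(__name__)

SIMILARITY_PENALTY_THRESHOLD = 0.95
SIMILARITY_PENALTY_STEP = 0.5
FAILURE_SENTINEL_OFFSET = 10.0


def lid_rootn(raw_energy: float, heavy_atoms: int, n: int = 2) -> float:
    """Ligand-efficiency-normalized score: raw_energy / heavy_atoms**(1/n)."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    if n not in (1, 2, 3, 4):
        raise ValueError(f"n must be one of 1..4, got {n}")
    return raw_energy / heavy_atoms ** (1.0 / n)


class FitnessBackend(Protocol):
    """Anything that maps an assembled product to a raw energy (lower = better).

    Implementations must be deterministic per molecule key.  A docking
    adapter would live behind this same contract; the package ships a score
    lookup table and a deterministic surrogate.
    """

    name: str

    def evaluate(self, molecule: ProductMolecule) -> float: ...


@dataclass
class Individual:
    """One member of a population: genotype plus its scores and provenance."""

    genotype: LigandGenotype
    generation_born: int = 0
    lineage: tuple = ()  # (operator, parent molecule keys...)
    molecule_key: Optional[str] = None
    fingerprint: object = None
    heavy_atoms: Optional[int] = None
    raw_energy: float = math.nan
    fitness: float = math.nan
    penalty: float = 0.0
    failed: bool = False

    @property
    def effective_score(self) -> float:
        return self.fitness + self.penalty


@dataclass
class ScoreCache:
    """Molecule-key -> (raw_energy, fitness) memo.

    A molecule scored in an earlier generation, or duplicated within one
    population, is never re-submitted to the backend.
    """

    _table: dict = field(default_factory=dict)
    backend_calls: int = 0
    hits: int = 0

    def __contains__(self, key: str) -> bool:
        return key in self._table

    def get(self, key: str):
        return self._table.get(key)

    def store(self, key: str, raw_energy: float, fitness: float) -> None:
        self._table[key] = (raw_energy, fitness)

    def __len__(self) -> int:
        return len(self._table)


def apply_similarity_penalty(
    individuals: list,
    threshold: float = SIMILARITY_PENALTY_THRESHOLD,
    step: float = SIMILARITY_PENALTY_STEP,
) -> list:
    """Penalize near-duplicates within one population, best-first.

    Individuals are processed in ascending (pre-penalty) fitness order.
    Each one's fingerprint is compared against all already-stored
    fingerprints; its penalty is ``step`` times the number with Tanimoto
    similarity strictly above ``threshold``, and its fingerprint is stored
    regardless.  Three identical copies therefore receive 0, 0.5, 1.0 —
    duplicates may persist but lose ground with every extra copy.

    Individuals without a fingerprint (assembly failures) get penalty 0 and
    are not stored.  Returns the input list (penalties set in place).
    """
    order = sorted(
        (ind for ind in individuals if not ind.failed),
        key=lambda ind: (ind.fitness, ind.molecule_key),
    )
    stored: list = []
    for ind in order:
        sims = bulk_tanimoto(ind.fingerprint, stored)
        ind.penalty = step * sum(1 for s in sims if s > threshold)
        stored.append(ind.fingerprint)
    for ind in individuals:
        if ind.failed:
            ind.penalty = 0.0
    return individuals


def evaluate_population(
    population: list,
    backend: FitnessBackend,
    cache: ScoreCache,
    library: CombinatorialLibrary,
    lid_n: int = 2,
    penalty_threshold: float = SIMILARITY_PENALTY_THRESHOLD,
    penalty_step: float = SIMILARITY_PENALTY_STEP,
) -> list:
    """Assemble, score, normalize and penalize a population of individuals.

    The backend is invoked exactly once per distinct molecule key that is
    not already cached; intra-population duplicates and previously seen
    molecules reuse the cached score.  Assembly or backend failures do not
    abort the run: the individual is marked failed and assigned a sentinel
    fitness ``FAILURE_SENTINEL_OFFSET`` above the worst successful fitness
    in the population, so selection reliably discards it.
    """
    # Assemble every genotype (memoized per library).
    for ind in population:
        if ind.molecule_key is not None or ind.failed:
            continue
        try:
            product = assemble_product(ind.genotype, library)
        except AssemblyError:
            logger.warning("assembly failed for genotype %s", ind.genotype)
            ind.failed = True
            continue
        ind.molecule_key = product.canonical_smiles
        ind.fingerprint = product.fingerprint
        ind.heavy_atoms = product.heavy_atoms

    # One backend call per distinct uncached molecule key.
    pending: dict[str, Individual] = {}
    for ind in population:
        if ind.failed or ind.molecule_key in cache:
            continue
        pending.setdefault(ind.molecule_key, ind)
    for key, ind in pending.items():
        product = ProductMolecule(
            canonical_smiles=key,
            heavy_atoms=ind.heavy_atoms,
            fingerprint=ind.fingerprint,
        )
        try:
            raw = float(backend.evaluate(product))
        except Exception as exc:
            logger.warning("backend failed for %s: %s", key, exc)
            ind.failed = True
            continue
        cache.backend_calls += 1
        cache.store(key, raw, lid_rootn(raw, ind.heavy_atoms, lid_n))

    for ind in population:
        if ind.failed:
            continue
        entry = cache.get(ind.molecule_key)
        if entry is None:  # backend failed for this key above
            ind.failed = True
            continue
        ind.raw_energy, ind.fitness = entry
        cache.hits += 1

    # Sentinel for failures: reliably worse than anything real.
    worst = max(
        (ind.fitness for ind in population if not ind.failed), default=0.0
    )
    for ind in population:
        if ind.failed:
            ind.raw_energy = math.nan
            ind.fitness = worst + FAILURE_SENTINEL_OFFSET

    apply_similarity_penalty(population, penalty_threshold, penalty_step)
    return population


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

def _mix32(x: int) -> int:
    x &= 0xFFFFFFFF
    x = (x ^ (x >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    x = (x ^ (x >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    return x ^ (x >> 16)


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the deterministic surrogate energy.

    ``base`` centers scores in a docking-like negative range;
    ``substructure_weight`` scales the rugged hashed-substructure term;
    ``size_weight`` adds a mild reward per heavy atom (so that lid_root
    normalization has real work to do); ``seed`` reshuffles the landscape.
    """

    base: float = -12.0
    substructure_weight: float = 4.0
    size_weight: float = 0.05
    seed: int = 0


def surrogate_energy(
    molecule: ProductMolecule, params: SurrogateParams = SurrogateParams()
) -> float:
    """Deterministic pseudo-energy standing in for a docking score.

    Each on-bit of the molecule's fingerprint (a circular substructure)
    contributes a fixed pseudo-random value in [-1, 1); the normalized sum
    gives a rugged but locally correlated landscape — molecules sharing
    substructures score alike, which is the feature an evolutionary search
    exploits — plus a mild size term.  Same molecule, same params => same
    value, across runs and platforms.
    """
    bits = list(molecule.fingerprint.GetOnBits())
    if bits:
        acc = 0.0
        for b in bits:
            h = _mix32(b * 2654435761 + params.seed * 40503)
            acc += (h / 2**32) * 2.0 - 1.0
        rugged = acc / math.sqrt(len(bits))
    else:
        rugged = 0.0
    return (
        params.base
        + params.substructure_weight * rugged
        - params.size_weight * molecule.heavy_atoms
    )


@dataclass(frozen=True)
class SurrogateBackend:
    params: SurrogateParams = SurrogateParams()
    name: str = "surrogate"

    def evaluate(self, molecule: ProductMolecule) -> float:
        return surrogate_energy(molecule, self.params)


class LookupBackend:
    """Backend serving energies from a pre-computed score table.

    This is the pre-docked mode: every enumerable molecule has been scored
    ahead of time, so an unknown key is a hard error, not a silent default.
    """

    name = "lookup"

    def __init__(self, table: dict):
        self._table = dict(table)

    @classmethod
    def from_csv(cls, path) -> "LookupBackend":
        table = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table[row["canonical_smiles"]] = float(row["raw_energy"])
        return cls(table)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["canonical_smiles", "raw_energy"])
            for key, energy in self._table.items():
                writer.writerow([key, repr(energy)])

    def __len__(self) -> int:
        return len(self._table)

    def evaluate(self, molecule: ProductMolecule) -> float:
        key = molecule.canonical_smiles
        if key not in self._table:
            raise KeyError(f"molecule {key!r} missing from score table")
        return self._table[key]


def lookup_backend(score_table) -> LookupBackend:
    """Load a ``canonical_smiles,raw_energy`` CSV as a fitness backend."""
    return LookupBackend.from_csv(Path(score_table))
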