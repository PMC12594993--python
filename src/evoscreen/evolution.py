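"""The evolutionary engine: selectors, reproduction operators and the
generation loop.

A run starts from a product-count-weighted random population, scores it,
and then repeats a fixed sequence of reproduction steps for a set number of
generations.  Each step pairs a selector (elitist, tournament or roulette)
with an offspring factory (identity, mutator or crossover).  Offspring are
always expressed as library genotypes, so every molecule the search ever
touches is synthesizable by construction.

The default protocol (one generation):

1. moderate mutations — roulette 15 -> 30 offspring, fragment:reaction 2:1,
   minimum mutation similarity 0.6, parents kept in the pool;
2. excessive crossover — roulette 15 -> 60 offspring, parents kept;
3. drastic mutations — as (1) but fragment-only with maximum similarity 0.25;
4. reaction mutation — as (1) but reaction-only;
5. identity — elitist 15 copied unchanged to the next generation and
   *removed* from the pool;
6. as (1) on the depleted pool (worse molecules now get their turn);
7. as (2) on the depleted pool.

New offspring (240 per generation) are evaluated, merged with the identity
copies, and a main selector (tournament, size 15, accept 0.75) reduces the
candidates to the 50 survivors of the next generation.  With the default
initial population of 200 and 30 generations, every run evaluates exactly
200 + 30 * 240 = 7400 individuals.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .fitness import (
    FitnessBackend,
    Individual,
    ScoreCache,
    evaluate_population,
)
from .library_model import (
    CombinatorialLibrary,
    LigandGenotype,
    sample_random_genotype,
)

logger = logging.getLogger(__name__)

ROULETTE_WEIGHT_FLOOR = 0.01  # fraction of the weight span added to every weight


# ---------------------------------------------------------------------------
# Selectors
# ---------------------------------------------------------------------------

def _score_key(ind: Individual):
    # Effective (penalty-adjusted) score; molecule key breaks ties so that
    # selection is reproducible across runs.
    return (ind.effective_score, ind.molecule_key or "")


def elitist_select(pop: list, k: int, remove_selected: bool = False) -> list:
    """The k individuals with the lowest effective scores."""
    if k > len(pop):
        raise ValueError(f"cannot select {k} from a population of {len(pop)}")
    selected = sorted(pop, key=_score_key)[:k]
    if remove_selected:
        chosen = {id(ind) for ind in selected}
        pop[:] = [ind for ind in pop if id(ind) not in chosen]
    return selected


def roulette_weights(scores: np.ndarray, anchor: Optional[float] = None,
                     floor: float = ROULETTE_WEIGHT_FLOOR) -> np.ndarray:
    """Linear fitness-proportional weights that survive negative scores.

    Docking-style scores are negative, so naive score ratios are
    meaningless.  Weights are linear distances from an *anchor* (default:
    the pool's worst score), plus a small floor so the worst individual
    retains a nonzero chance: ``w_i = (anchor - s_i) + floor * span`` where
    span = anchor - best score.  With an explicit anchor the stated
    proportionality holds: scores -4 and -2 against anchor 0 select ~2:1.
    All-equal scores degrade to uniform weights.
    """
    scores = np.asarray(scores, dtype=float)
    if anchor is None:
        anchor = float(scores.max())
    span = anchor - float(scores.min())
    if span <= 0:
        return np.ones_like(scores)
    return (anchor - scores) + floor * span


def roulette_select(
    pop: list,
    k: int,
    rng: np.random.Generator,
    remove_selected: bool = False,
    anchor: Optional[float] = None,
) -> list:
    """Fitness-proportional sampling without replacement within one call."""
    if k > len(pop):
        raise ValueError(f"cannot select {k} from a population of {len(pop)}")
    candidates = list(pop)
    selected = []
    for _ in range(k):
        weights = roulette_weights(
            np.array([ind.effective_score for ind in candidates]), anchor=anchor
        )
        idx = int(rng.choice(len(candidates), p=weights / weights.sum()))
        selected.append(candidates.pop(idx))
    if remove_selected:
        chosen = {id(ind) for ind in selected}
        pop[:] = [ind for ind in pop if id(ind) not in chosen]
    return selected


def tournament_select(
    pop: list,
    k: int,
    tournament_size: int,
    accept_chance: float,
    rng: np.random.Generator,
    remove_selected: bool = False,
) -> list:
    """Rank-based selection: k tournaments of ``tournament_size`` random
    entrants each; entrants are ranked by effective score and walked
    best-first, each accepting with probability ``accept_chance``.  If every
    entrant declines, the tournament's best is taken, so each tournament
    yields exactly one selection.

    Without removal the same individual may win several tournaments; with
    removal each winner leaves the pool before the next tournament.
    """
    if not 0 < accept_chance <= 1:
        raise ValueError(f"accept_chance must be in (0, 1], got {accept_chance}")
    working = pop if remove_selected else list(pop)
    selected = []
    for _ in range(k):
        if tournament_size > len(working):
            raise ValueError(
                f"tournament size {tournament_size} exceeds pool size {len(working)}"
            )
        entrant_idx = rng.choice(len(working), size=tournament_size, replace=False)
        entrants = sorted((working[i] for i in entrant_idx), key=_score_key)
        winner = None
        for entrant in entrants:
            if rng.random() < accept_chance:
                winner = entrant
                break
        if winner is None:
            winner = entrants[0]
        selected.append(winner)
        if remove_selected:
            working.remove(winner)
    return selected


@dataclass(frozen=True)
class SelectorSpec:
    kind: str  # elitist | tournament | roulette
    k: int
    remove_selected: bool = False
    tournament_size: int = 15
    accept_chance: float = 0.75

    def __post_init__(self):
        if self.kind not in ("elitist", "tournament", "roulette"):
            raise ValueError(f"unknown selector kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def select(self, pop: list, rng: np.random.Generator) -> list:
        if self.kind == "elitist":
            return elitist_select(pop, self.k, self.remove_selected)
        if self.kind == "roulette":
            return roulette_select(pop, self.k, rng, self.remove_selected)
        return tournament_select(
            pop, self.k, self.tournament_size, self.accept_chance, rng,
            self.remove_selected,
        )


# ---------------------------------------------------------------------------
# Reproduction operators
# ---------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, n: int, weights: np.ndarray) -> int:
    total = float(weights.sum())
    if total <= 0:
        return int(rng.integers(n))
    return int(rng.choice(n, p=weights / total))


def mutate_fragment(
    genotype: LigandGenotype,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
    min_similarity: Optional[float] = None,
    max_similarity: Optional[float] = None,
) -> LigandGenotype:
    """Swap one synthon for a similarity-windowed alternative.

    One position is chosen uniformly; alternatives at that position are
    filtered to ``min_similarity <= tanimoto <= max_similarity`` against the
    current synthon and sampled with similarity as weight.  An empty window
    is widened rather than erroring: the max bound is dropped first, then
    the min bound; a position with no alternatives at all is a logged no-op.
    """
    from .chemtools import bulk_tanimoto

    reaction = library.reaction(genotype.reaction_id)
    position = int(rng.integers(reaction.arity))
    current_id = genotype.synthon_ids[position]
    current = library.synthon(genotype.reaction_id, position, current_id)
    alternatives = [s for s in reaction.positions[position]
                    if s.synthon_id != current_id]
    if not alternatives:
        logger.debug("no alternative synthons at %s position %d; mutation no-op",
                     genotype.reaction_id, position)
        return genotype

    sims = np.array(bulk_tanimoto(current.fingerprint,
                                  [s.fingerprint for s in alternatives]))
    for lo, hi in ((min_similarity, max_similarity), (min_similarity, None),
                   (None, None)):
        mask = np.ones(len(alternatives), dtype=bool)
        if lo is not None:
            mask &= sims >= lo
        if hi is not None:
            mask &= sims <= hi
        if mask.any():
            break
    idx_pool = np.flatnonzero(mask)
    pick = idx_pool[_weighted_choice(rng, len(idx_pool), sims[idx_pool])]
    new_ids = list(genotype.synthon_ids)
    new_ids[position] = alternatives[pick].synthon_id
    return LigandGenotype(reaction_id=genotype.reaction_id,
                          synthon_ids=tuple(new_ids))


def _best_by_similarity(candidates: list, reference_fps: list) -> "SynthonRecord":
    """The candidate synthon maximizing Tanimoto similarity to any of the
    reference fingerprints; ties broken by synthon id for determinism."""
    from .chemtools import bulk_tanimoto

    best, best_score = None, -1.0
    sim_rows = [bulk_tanimoto(ref, [c.fingerprint for c in candidates])
                for ref in reference_fps]
    for j, cand in enumerate(candidates):
        score = max(row[j] for row in sim_rows)
        if score > best_score or (score == best_score and
                                  (best is None or cand.synthon_id < best.synthon_id)):
            best, best_score = cand, score
    return best


def mutate_reaction(
    genotype: LigandGenotype,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
) -> LigandGenotype:
    """Move the genotype to a different, uniformly chosen reaction, filling
    each new position with the synthon most similar to the old fragments.

    Position pairing is by index; new positions beyond the old arity match
    against all old fragments.  Only the reaction draw is random — the
    fragment fill is a deterministic argmax, which keeps the mutation a
    small perturbation in chemical space.
    """
    others = [r for r in library.reactions if r.reaction_id != genotype.reaction_id]
    if not others:
        logger.warning("single-reaction library: reaction mutation is a no-op")
        return genotype
    new_reaction = others[int(rng.integers(len(others)))]
    old_fps = [
        library.synthon(genotype.reaction_id, i, sid).fingerprint
        for i, sid in enumerate(genotype.synthon_ids)
    ]
    new_ids = []
    for i, pos_list in enumerate(new_reaction.positions):
        refs = [old_fps[i]] if i < len(old_fps) else old_fps
        new_ids.append(_best_by_similarity(list(pos_list), refs).synthon_id)
    return LigandGenotype(reaction_id=new_reaction.reaction_id,
                          synthon_ids=tuple(new_ids))


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
) -> LigandGenotype:
    """Recombine two parents into one offspring genotype.

    One parent (uniform) donates the reaction; positions are partitioned
    randomly between the parents with each contributing at least one
    fragment (for two-component reactions: exactly one each).  Fragments
    contributed by a parent with a different reaction are mapped into the
    donor reaction's position list by the same maximal-similarity search
    used for reaction mutation, so the offspring always stays inside the
    library.
    """
    donor, other = (parent_a, parent_b) if rng.random() < 0.5 else (parent_b, parent_a)
    g_donor, g_other = donor.genotype, other.genotype
    reaction = library.reaction(g_donor.reaction_id)
    arity = reaction.arity

    from_other = rng.integers(2, size=arity).astype(bool)
    if from_other.all():
        from_other[int(rng.integers(arity))] = False
    elif not from_other.any():
        from_other[int(rng.integers(arity))] = True

    same_reaction = g_other.reaction_id == g_donor.reaction_id
    other_fps = [
        library.synthon(g_other.reaction_id, i, sid).fingerprint
        for i, sid in enumerate(g_other.synthon_ids)
    ]
    new_ids = []
    for p in range(arity):
        if not from_other[p]:
            new_ids.append(g_donor.synthon_ids[p])
        elif same_reaction:
            new_ids.append(g_other.synthon_ids[p])
        else:
            refs = [other_fps[p]] if p < len(other_fps) else other_fps
            new_ids.append(
                _best_by_similarity(list(reaction.positions[p]), refs).synthon_id
            )
    return LigandGenotype(reaction_id=g_donor.reaction_id,
                          synthon_ids=tuple(new_ids))


# ---------------------------------------------------------------------------
# Protocol configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolStep:
    name: str
    selector: SelectorSpec
    factory: str  # identity | mutator | crossover
    n_offspring: int = 0
    fragment_reaction_ratio: float = 2.0  # fragment mutations per reaction mutation
    min_similarity: Optional[float] = None
    max_similarity: Optional[float] = None
    fragment_only: bool = False
    reaction_only: bool = False

    def __post_init__(self):
        if self.factory not in ("identity", "mutator", "crossover"):
            raise ValueError(f"unknown factory {self.factory!r}")
        if self.factory != "identity" and self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1 for non-identity factories")
        if (self.min_similarity is not None and self.max_similarity is not None
                and self.min_similarity > self.max_similarity):
            raise ValueError("min_similarity must be <= max_similarity")


def default_protocol() -> tuple:
    """The seven-step protocol used by default (see the module docstring)."""
    roulette15 = SelectorSpec(kind="roulette", k=15, remove_selected=False)
    return (
        ProtocolStep("moderate_mutations", roulette15, "mutator", 30,
                     min_similarity=0.6),
        ProtocolStep("excessive_crossover", roulette15, "crossover", 60),
        ProtocolStep("drastic_mutations", roulette15, "mutator", 30,
                     max_similarity=0.25, fragment_only=True),
        ProtocolStep("reaction_mutation", roulette15, "mutator", 30,
                     reaction_only=True),
        ProtocolStep("identity",
                     SelectorSpec(kind="elitist", k=15, remove_selected=True),
                     "identity"),
        ProtocolStep("moderate_mutations_2", roulette15, "mutator", 30,
                     min_similarity=0.6),
        ProtocolStep("excessive_crossover_2", roulette15, "crossover", 60),
    )


@dataclass(frozen=True)
class EvolutionConfig:
    initial_population: int = 200
    survivors_per_generation: int = 50
    generations: int = 30
    main_selector: SelectorSpec = field(
        default_factory=lambda: SelectorSpec(
            kind="tournament", k=50, remove_selected=True,
            tournament_size=15, accept_chance=0.75,
        )
    )
    steps: tuple = field(default_factory=default_protocol)
    lid_n: int = 2
    seed: int = 0

    def expected_individuals(self) -> int:
        """Evaluated-individual count implied by the configuration."""
        per_gen = sum(s.n_offspring for s in self.steps if s.factory != "identity")
        return self.initial_population + self.generations * per_gen


@dataclass
class RunResult:
    individuals: list  # every evaluated Individual, in creation order
    generation_stats: pd.DataFrame
    config: EvolutionConfig
    final_population: list
    backend_calls: int

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def distinct_molecules(self) -> int:
        return len({ind.molecule_key for ind in self.individuals
                    if not ind.failed})

    def individuals_frame(self) -> pd.DataFrame:
        rows = [
            {
                "generation": ind.generation_born,
                "reaction_id": ind.genotype.reaction_id,
                "synthon_ids": "|".join(ind.genotype.synthon_ids),
                "molecule_key": ind.molecule_key,
                "raw_energy": ind.raw_energy,
                "fitness": ind.fitness,
                "penalty": ind.penalty,
                "failed": ind.failed,
                "lineage": "|".join(str(x) for x in ind.lineage),
            }
            for ind in self.individuals
        ]
        return pd.DataFrame(rows)

    def digest(self) -> str:
        """Content hash of the full individual log (replay check)."""
        csv_text = self.individuals_frame().to_csv(index=False, float_format="%.10g")
        return hashlib.sha256(csv_text.encode()).hexdigest()

    def best_molecules(self, n: int = 50) -> pd.DataFrame:
        frame = self.individuals_frame()
        frame = frame[~frame["failed"]].drop_duplicates("molecule_key")
        return frame.nsmallest(n, "fitness")


def _make_offspring(
    step: ProtocolStep,
    parents: list,
    library: CombinatorialLibrary,
    rng: np.random.Generator,
    generation: int,
) -> list:
    """Produce ``step.n_offspring`` new individuals from the selected parents."""
    offspring = []
    if step.factory == "mutator":
        # Parents are cycled round-robin: 15 parents, 30 offspring => each
        # parent mutated twice.
        p_fragment = step.fragment_reaction_ratio / (1.0 + step.fragment_reaction_ratio)
        for i in range(step.n_offspring):
            parent = parents[i % len(parents)]
            if step.fragment_only:
                do_fragment = True
            elif step.reaction_only:
                do_fragment = False
            else:
                do_fragment = rng.random() < p_fragment
            if do_fragment:
                child = mutate_fragment(
                    parent.genotype, library, rng,
                    min_similarity=step.min_similarity,
                    max_similarity=step.max_similarity,
                )
                op = "mutate_fragment"
            else:
                child = mutate_reaction(parent.genotype, library, rng)
                op = "mutate_reaction"
            offspring.append(Individual(
                genotype=child, generation_born=generation,
                lineage=(op, parent.molecule_key),
            ))
    elif step.factory == "crossover":
        for _ in range(step.n_offspring):
            i, j = rng.choice(len(parents), size=2, replace=False)
            child = crossover(parents[i], parents[j], library, rng)
            offspring.append(Individual(
                genotype=child, generation_born=generation,
                lineage=("crossover", parents[i].molecule_key,
                         parents[j].molecule_key),
            ))
    return offspring


def _cumulative_stats(fitnesses: list, generation: int) -> dict:
    values = np.sort(np.array(fitnesses, dtype=float))
    def nth(i):
        return float(values[i]) if len(values) > i else math.nan
    return {
        "generation": generation,
        "n_evaluated": len(values),
        "best": nth(0),
        "top10": nth(9),
        "top100": nth(99),
        "median": float(np.median(values)) if len(values) else math.nan,
    }


def run_evolution(
    config: EvolutionConfig,
    library: CombinatorialLibrary,
    backend: FitnessBackend,
    cache: Optional[ScoreCache] = None,
) -> RunResult:
    """Execute a full evolutionary run and report every individual created.

    A single seeded random stream drives sampling, selection and
    reproduction in protocol order, so two runs with the same seed, library
    and backend produce identical results.
    """
    rng = np.random.default_rng(config.seed)
    cache = cache if cache is not None else ScoreCache()

    population = [
        Individual(genotype=sample_random_genotype(library, rng),
                   generation_born=0, lineage=("random",))
        for _ in range(config.initial_population)
    ]
    evaluate_population(population, backend, cache, library, lid_n=config.lid_n)
    all_individuals = list(population)
    stats = [_cumulative_stats([i.fitness for i in all_individuals if not i.failed], 0)]

    survivors = config.main_selector.select(list(population), rng)
    logger.info("generation 0: %d evaluated, best fitness %.3f",
                len(population), min(i.fitness for i in survivors))

    for generation in range(1, config.generations + 1):
        pool = list(survivors)
        new_offspring: list = []
        identity_copies: list = []
        for step in config.steps:
            parents = step.selector.select(pool, rng)
            if step.factory == "identity":
                identity_copies.extend(parents)
            else:
                new_offspring.extend(
                    _make_offspring(step, parents, library, rng, generation)
                )
        evaluate_population(new_offspring, backend, cache, library,
                            lid_n=config.lid_n)
        all_individuals.extend(new_offspring)
        stats.append(_cumulative_stats(
            [i.fitness for i in all_individuals if not i.failed], generation))

        candidates = new_offspring + identity_copies
        survivors = config.main_selector.select(candidates, rng)
        logger.info("generation %d: %d evaluated so far, best fitness %.3f",
                    generation, len(all_individuals),
                    min(i.fitness for i in survivors))

    return RunResult(
        individuals=all_individuals,
        generation_stats=pd.DataFrame(stats),
        config=config,
        final_population=survivors,
        backend_calls=cache.backend_calls,
    )
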