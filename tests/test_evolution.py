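"""Selectors, reproduction operators and the generation loop."""

import numpy as np
import pytest
import scipy.stats
from rdkit import Chem
from rdkit.DataStructs import ExplicitBitVect

from evoscreen import (
    CombinatorialLibrary,
    SelectorSpec,
    EvolutionConfig,
    FingerprintConfig,
    Individual,
    LigandGenotype,
    ReactionRecord,
    SurrogateBackend,
    SynthonRecord,
    crossover,
    elitist_select,
    mutate_fragment,
    mutate_reaction,
    roulette_select,
    run_evolution,
    tournament_select,
)
from evoscreen.chemtools import bulk_tanimoto, fingerprint_smiles
from evoscreen.evolution import default_protocol, roulette_weights

FP = FingerprintConfig()


def _ind(key, score):
    return Individual(genotype=LigandGenotype("r", (key,)), molecule_key=key,
                      fitness=score, raw_energy=score)


def _scored_pop(scores):
    return [_ind(f"m{i:02d}", s) for i, s in enumerate(scores)]


class TestElitist:
    def test_k_equals_pop_returns_everything(self):
        pop = _scored_pop([-3, -1, -2])
        assert {id(i) for i in elitist_select(pop, 3)} == {id(i) for i in pop}

    def test_k1_returns_single_best(self):
        pop = _scored_pop([-3, -5, -2])
        assert elitist_select(pop, 1)[0].fitness == -5

    def test_ties_broken_lexicographically_matches_sort_oracle(self):
        pop = [_ind("b", -2.0), _ind("a", -2.0), _ind("c", -3.0), _ind("d", -2.0)]
        selected = elitist_select(pop, 2)
        oracle = sorted(pop, key=lambda i: (i.fitness, i.molecule_key))[:2]
        assert selected == oracle
        assert [i.molecule_key for i in selected] == ["c", "a"]

    def test_remove_selected_depletes_pool_best_first(self):
        """After removing the elite, the best remaining score is worse."""
        pop = _scored_pop([-5, -4, -3, -2, -1])
        before_best = min(i.effective_score for i in pop)
        elite = elitist_select(pop, 2, remove_selected=True)
        assert len(pop) == 3
        assert min(i.effective_score for i in pop) > before_best
        assert {i.fitness for i in elite} == {-5, -4}

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            elitist_select(_scored_pop([-1]), 2)


class TestRoulette:
    def test_two_to_one_ratio_with_explicit_anchor(self, rng):
        """Scores -4 and -2 against anchor 0 select approximately 2:1."""
        pop = _scored_pop([-4.0, -2.0])
        n = 20_000
        wins = sum(
            roulette_select(pop, 1, rng, anchor=0.0)[0].fitness == -4.0
            for _ in range(n))
        w = roulette_weights(np.array([-4.0, -2.0]), anchor=0.0)
        p = w[0] / w.sum()  # ~0.664 including the weight floor
        lo, hi = scipy.stats.binom.interval(0.99, n, p)
        assert lo <= wins <= hi

    def test_equal_scores_select_uniformly(self, rng):
        pop = _scored_pop([-3.0] * 4)
        n = 20_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[pop.index(roulette_select(pop, 1, rng)[0])] += 1
        _, p = scipy.stats.chisquare(counts)
        assert p > 0.001

    def test_frequencies_match_normalized_weights(self, rng):
        """Five-individual frequencies against the closed-form multinomial."""
        scores = [-6.0, -5.0, -4.5, -3.0, -2.0]
        pop = _scored_pop(scores)
        n = 20_000
        counts = np.zeros(5)
        for _ in range(n):
            counts[pop.index(roulette_select(pop, 1, rng)[0])] += 1
        w = roulette_weights(np.array(scores))
        _, p = scipy.stats.chisquare(counts, n * w / w.sum())
        assert p > 0.001

    def test_without_replacement_within_call(self, rng):
        pop = _scored_pop([-4, -3, -2, -1])
        selected = roulette_select(pop, 4, rng)
        assert len({id(i) for i in selected}) == 4

    def test_remove_selected(self, rng):
        pop = _scored_pop([-4, -3, -2, -1])
        selected = roulette_select(pop, 2, rng, remove_selected=True)
        assert len(pop) == 2
        assert not set(map(id, selected)) & set(map(id, pop))


def _tournament_rank_probs(size, accept):
    """Exhaustive decline-path oracle: probability each fitness rank wins a
    single tournament.  All-decline falls back to the best entrant."""
    probs = [accept * (1 - accept) ** r for r in range(size)]
    probs[0] += (1 - accept) ** size  # fallback mass
    return probs


class TestTournament:
    def test_accept_one_always_selects_best(self, rng):
        pop = _scored_pop([-5, -4, -3])
        for _ in range(100):
            assert tournament_select(pop, 1, 3, 1.0, rng)[0].fitness == -5

    @pytest.mark.parametrize("size", [2, 3])
    def test_rank_frequencies_match_path_oracle(self, size, rng):
        """Winner-rank distribution vs the exhaustive decline-path oracle
        (tournament = whole pool, so entrant ranks are deterministic)."""
        pop = _scored_pop([-5.0 - i for i in range(size)][::-1])
        ranked = sorted(pop, key=lambda i: i.fitness)
        n = 50_000
        counts = np.zeros(size)
        for _ in range(n):
            winner = tournament_select(pop, 1, size, 0.75, rng)[0]
            counts[ranked.index(winner)] += 1
        expected = np.array(_tournament_rank_probs(size, 0.75)) * n
        _, p = scipy.stats.chisquare(counts, expected)
        assert p > 0.001

    def test_size_2_best_probability_closed_form(self, rng):
        # P(best) = 0.75 + 0.25^2 (both decline -> fallback) = 0.8125
        assert _tournament_rank_probs(2, 0.75)[0] == pytest.approx(0.8125)

    def test_size_larger_than_pool_errors(self, rng):
        with pytest.raises(ValueError):
            tournament_select(_scored_pop([-1, -2]), 1, 3, 0.75, rng)

    def test_remove_selected_yields_distinct(self, rng):
        pop = _scored_pop([-5, -4, -3, -2, -1])
        selected = tournament_select(pop, 3, 2, 0.75, rng, remove_selected=True)
        assert len({id(i) for i in selected}) == 3
        assert len(pop) == 2


# ---------------------------------------------------------------------------
# Reproduction operators
# ---------------------------------------------------------------------------

def _records(tag, smiles_list):
    return [
        SynthonRecord(synthon_id=f"{tag}{i}", smiles=s,
                      fingerprint=fingerprint_smiles(s, FP),
                      mol=Chem.MolFromSmiles(s))
        for i, s in enumerate(smiles_list)
    ]


AMIDE = "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]"
ESTER = "[C:1](=[O:2])[OX2H1].[OX2H1:3][#6:4]>>[C:1](=[O:2])[O:3][#6:4]"

AMINES = ["NC", "NCC", "NCCC", "NCCCC", "NCc1ccccc1"]


@pytest.fixture()
def two_reaction_library():
    amide = ReactionRecord("amide", AMIDE, positions=[
        _records("acid", ["CC(=O)O"]), _records("amine", AMINES)])
    ester = ReactionRecord("ester", ESTER, positions=[
        _records("eacid", ["CC(=O)O", "CCC(=O)O"]),
        _records("alc", ["OC", "OCC", "OCCC", "OCc1ccccc1"])])
    return CombinatorialLibrary(reactions=[amide, ester],
                                fingerprint_config=FP)


class TestMutateFragment:
    def test_single_in_window_alternative_is_chosen(self, two_reaction_library,
                                                    rng):
        lib = two_reaction_library
        g = LigandGenotype("amide", ("acid0", "amine0"))
        current = lib.synthon("amide", 1, "amine0")
        others = [s for s in lib.reaction("amide").positions[1]
                  if s.synthon_id != "amine0"]
        sims = bulk_tanimoto(current.fingerprint,
                             [s.fingerprint for s in others])
        # window around the single most similar alternative
        target = others[int(np.argmax(sims))]
        lo = max(sorted(sims)[-2], 0.0) + 1e-9
        for _ in range(50):
            mutated = mutate_fragment(g, lib, rng, min_similarity=lo)
            if mutated != g:  # position 0 has no alternatives -> no-op
                assert mutated.synthon_ids[1] == target.synthon_id

    def test_offspring_satisfy_closure(self, library, rng):
        from evoscreen import sample_random_genotype
        for _ in range(1000):
            g = sample_random_genotype(library, rng)
            library.validate_genotype(
                mutate_fragment(g, library, rng, min_similarity=0.0))

    def test_sampling_frequencies_proportional_to_similarity(
            self, two_reaction_library, rng):
        """Window of 4 candidates: pick frequencies match normalized
        similarity weights (chi-square, n = 20,000 effective draws)."""
        lib = two_reaction_library
        g = LigandGenotype("amide", ("acid0", "amine0"))
        current = lib.synthon("amide", 1, "amine0")
        others = [s for s in lib.reaction("amide").positions[1]
                  if s.synthon_id != "amine0"]
        sims = np.array(bulk_tanimoto(current.fingerprint,
                                      [s.fingerprint for s in others]))
        counts = {s.synthon_id: 0 for s in others}
        changed = 0
        while changed < 20_000:
            mutated = mutate_fragment(g, lib, rng)
            if mutated != g:
                counts[mutated.synthon_ids[1]] += 1
                changed += 1
        observed = np.array([counts[s.synthon_id] for s in others])
        _, p = scipy.stats.chisquare(observed, changed * sims / sims.sum())
        assert p > 0.001

    def test_empty_window_widens_then_noops(self, two_reaction_library, rng):
        lib = two_reaction_library
        g = LigandGenotype("amide", ("acid0", "amine0"))
        # impossible window: min > 1; must widen and still mutate position 1
        seen_change = False
        for _ in range(50):
            mutated = mutate_fragment(g, lib, rng, min_similarity=1.1,
                                      max_similarity=1.2)
            lib.validate_genotype(mutated)
            seen_change |= mutated != g
        assert seen_change

    def test_single_synthon_position_is_noop(self, two_reaction_library, rng):
        lib = two_reaction_library
        single = CombinatorialLibrary(
            reactions=[ReactionRecord("amide", AMIDE, positions=[
                _records("acid", ["CC(=O)O"]), _records("amine", ["NC"])])],
            fingerprint_config=FP)
        g = LigandGenotype("amide", ("acid0", "amine0"))
        assert mutate_fragment(g, single, rng) == g


class TestMutateReaction:
    def test_two_reaction_library_always_switches(self, two_reaction_library,
                                                  rng):
        g = LigandGenotype("amide", ("acid0", "amine4"))
        for _ in range(20):
            assert mutate_reaction(g, two_reaction_library,
                                   rng).reaction_id == "ester"

    def test_fragments_match_bruteforce_argmax(self, two_reaction_library, rng):
        lib = two_reaction_library
        g = LigandGenotype("amide", ("acid0", "amine4"))
        mutated = mutate_reaction(g, lib, rng)
        old_fps = [lib.synthon("amide", i, sid).fingerprint
                   for i, sid in enumerate(g.synthon_ids)]
        for i, chosen in enumerate(mutated.synthon_ids):
            candidates = lib.reaction("ester").positions[i]
            sims = bulk_tanimoto(old_fps[i], [c.fingerprint for c in candidates])
            top = max(sims)
            best_ids = {c.synthon_id for c, s in zip(candidates, sims) if s == top}
            assert chosen == min(best_ids)  # ties broken by synthon id

    def test_offspring_satisfy_closure(self, library, rng):
        from evoscreen import sample_random_genotype
        for _ in range(200):
            g = sample_random_genotype(library, rng)
            library.validate_genotype(mutate_reaction(g, library, rng))

    def test_single_reaction_library_noop(self, rng):
        lib = CombinatorialLibrary(
            reactions=[ReactionRecord("amide", AMIDE, positions=[
                _records("acid", ["CC(=O)O"]), _records("amine", AMINES)])],
            fingerprint_config=FP)
        g = LigandGenotype("amide", ("acid0", "amine0"))
        assert mutate_reaction(g, lib, rng) == g


class TestCrossover:
    def _parent(self, reaction_id, synthon_ids):
        return Individual(genotype=LigandGenotype(reaction_id, synthon_ids),
                          molecule_key="|".join(synthon_ids))

    def test_same_reaction_parents_always_mix(self, two_reaction_library, rng):
        lib = two_reaction_library
        a = self._parent("ester", ("eacid0", "alc0"))
        b = self._parent("ester", ("eacid1", "alc1"))
        mixed = {("eacid0", "alc1"), ("eacid1", "alc0")}
        for _ in range(200):
            child = crossover(a, b, lib, rng)
            assert child.synthon_ids in mixed

    def test_identical_parents_reproduce_themselves(self, two_reaction_library,
                                                    rng):
        a = self._parent("ester", ("eacid0", "alc2"))
        b = self._parent("ester", ("eacid0", "alc2"))
        for _ in range(20):
            assert crossover(a, b, two_reaction_library,
                             rng).synthon_ids == ("eacid0", "alc2")

    def test_cross_reaction_closure_and_argmax_mapping(self,
                                                       two_reaction_library,
                                                       rng):
        lib = two_reaction_library
        a = self._parent("amide", ("acid0", "amine4"))
        b = self._parent("ester", ("eacid1", "alc3"))
        for _ in range(100):
            child = crossover(a, b, lib, rng)
            lib.validate_genotype(child)
            donor = lib.reaction(child.reaction_id)
            other = a if child.reaction_id == "ester" else b
            for i, sid in enumerate(child.synthon_ids):
                own = (a if child.reaction_id == "amide" else b).genotype
                if sid == own.synthon_ids[i]:
                    continue  # donated by the reaction donor itself
                # mapped fragment must be the argmax-similarity synthon
                ref = lib.synthon(other.genotype.reaction_id, i,
                                  other.genotype.synthon_ids[i]).fingerprint
                candidates = donor.positions[i]
                sims = bulk_tanimoto(ref, [c.fingerprint for c in candidates])
                top = max(sims)
                best_ids = {c.synthon_id
                            for c, s in zip(candidates, sims) if s == top}
                assert sid == min(best_ids)


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------

class TestRunEvolution:
    def test_accounting_formula_small_run(self, library, backend):
        config = EvolutionConfig(initial_population=40,
                                 survivors_per_generation=30,
                                 generations=3, seed=5,
                                 main_selector=SelectorSpec(
                                     kind="tournament", k=30,
                                     remove_selected=True, tournament_size=5,
                                     accept_chance=0.75))
        result = run_evolution(config, library, backend)
        assert result.n_individuals == config.expected_individuals() == 40 + 3 * 240

    def test_zero_generations_gives_initial_population_only(self, library,
                                                            backend):
        result = run_evolution(EvolutionConfig(generations=0, seed=2),
                               library, backend)
        assert result.n_individuals == 200

    def test_same_seed_identical_digests(self, library, backend):
        config = EvolutionConfig(initial_population=40,
                                 survivors_per_generation=30, generations=2,
                                 seed=9,
                                 main_selector=SelectorSpec(
                                     kind="tournament", k=30,
                                     remove_selected=True, tournament_size=5,
                                     accept_chance=0.75))
        r1 = run_evolution(config, library, backend)
        r2 = run_evolution(config, library, backend)
        assert r1.digest() == r2.digest()

    def test_every_individual_satisfies_closure(self, library, backend):
        config = EvolutionConfig(initial_population=40,
                                 survivors_per_generation=30, generations=2,
                                 seed=4,
                                 main_selector=SelectorSpec(
                                     kind="tournament", k=30,
                                     remove_selected=True, tournament_size=5,
                                     accept_chance=0.75))
        result = run_evolution(config, library, backend)
        for ind in result.individuals:
            library.validate_genotype(ind.genotype)

    def test_default_protocol_shape(self):
        steps = default_protocol()
        assert [s.factory for s in steps] == [
            "mutator", "crossover", "mutator", "mutator", "identity",
            "mutator", "crossover"]
        assert [s.n_offspring for s in steps if s.factory != "identity"] == [
            30, 60, 30, 30, 30, 60]
        assert steps[4].selector.kind == "elitist"
        assert steps[4].selector.remove_selected
        assert all(s.selector.k == 15 for s in steps)
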