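"""Benchmarking: pre-docked test spaces, random baselines and enrichment.

The evaluation logic mirrors standard virtual-screening practice.  A method
samples a set of molecules M_i; given a score threshold x,

    HitRate_i(x) = |{m in M_i : score(m) < x}| / |M_i|
    EF_i(x)      = HitRate_i(x) / HitRate_rs(x)

where rs is a product-count-weighted random sample from the same library.
An EF above 1 means the method finds proportionally more good scorers than
random screening of the same space.

A *pre-docked benchmark* is a reduced library (diversity-selected reactions
and fragments) small enough to enumerate and score exhaustively, so the
global optimum and the exact top-quantile hit set are known.  Diversity
selection is deliberately greedy-min-similarity: it produces a rugged
similarity landscape that is hard to search, which is the point of the
benchmark.

This module also houses the fixture-library generator: procedurally
decorated reagents for a handful of robust two-component couplings,
emulating the structure (not the chemistry) of commercial synthon files.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemtools import AssemblyError, assemble_product, bulk_tanimoto, reaction_from_smarts
from .fitness import FitnessBackend, lid_rootn
from .library_model import (
    CombinatorialLibrary,
    LigandGenotype,
    ReactionRecord,
    SynthonRecord,
    count_products,
    enumerate_genotypes,
    sample_random_genotype,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hit rates and enrichment
# ---------------------------------------------------------------------------

def hit_rate(scores, x: float) -> float:
    """Fraction of scores strictly below the threshold x."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("hit_rate of an empty score set is undefined")
    return float(np.count_nonzero(scores < x)) / scores.size


@dataclass(frozen=True)
class EnrichmentResult:
    threshold: float
    method_hits: int
    method_rate: float
    baseline_hits: int
    baseline_rate: float
    ef: float  # inf when baseline rate is 0 and method rate > 0; nan for 0/0
    defined: bool

    @property
    def value(self) -> float:
        return self.ef


def enrichment_factor(method_scores, baseline_scores, x: float) -> EnrichmentResult:
    """EF_i(x) with explicit handling of a hitless baseline.

    When the random baseline contains no molecule under the threshold but
    the method does, no finite enrichment exists; the result carries
    ``ef = inf`` and ``defined = False`` rather than raising or clamping.
    """
    method_scores = np.asarray(list(method_scores), dtype=float)
    baseline_scores = np.asarray(list(baseline_scores), dtype=float)
    if method_scores.size == 0 or baseline_scores.size == 0:
        raise ValueError("enrichment_factor requires non-empty score sets")
    m_hits = int(np.count_nonzero(method_scores < x))
    b_hits = int(np.count_nonzero(baseline_scores < x))
    m_rate = m_hits / method_scores.size
    b_rate = b_hits / baseline_scores.size
    if b_rate > 0:
        ef, defined = m_rate / b_rate, True
    elif m_rate > 0:
        ef, defined = math.inf, False
    else:
        ef, defined = math.nan, False
    return EnrichmentResult(
        threshold=x, method_hits=m_hits, method_rate=m_rate,
        baseline_hits=b_hits, baseline_rate=b_rate, ef=ef, defined=defined,
    )


def enrichment_report(method_scores, baseline_scores, thresholds) -> pd.DataFrame:
    """One EF row per threshold (a Fig-2-style sweep)."""
    rows = [enrichment_factor(method_scores, baseline_scores, x).__dict__
            for x in thresholds]
    return pd.DataFrame(rows)


def hit_count(n_products: int, quantile: float) -> int:
    """Number of top-quantile hits, rounded half-up to an integer."""
    if n_products < 1:
        raise ValueError("n_products must be >= 1")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    return int(math.floor(n_products * quantile + 0.5))


# ---------------------------------------------------------------------------
# Diversity selection
# ---------------------------------------------------------------------------

def diversity_select_fragments(candidates: list, n: int,
                               rng: np.random.Generator) -> list:
    """Greedy minimum-mean-similarity subset of synthons.

    Seeds with one random candidate, then repeatedly adds the candidate
    with the lowest average Tanimoto similarity to the selected set (ties
    broken by synthon id).  The result maximizes spread, producing the
    rugged benchmark landscape described above.
    """
    if not 1 <= n <= len(candidates):
        raise ValueError(f"cannot select {n} from {len(candidates)} candidates")
    remaining = list(candidates)
    seed = remaining.pop(int(rng.integers(len(remaining))))
    selected = [seed]
    # running sum of similarities of each remaining candidate to the selected set
    sim_sum = np.array(bulk_tanimoto(seed.fingerprint,
                                     [c.fingerprint for c in remaining]))
    while len(selected) < n:
        mean_sim = sim_sum / len(selected)
        best = min(range(len(remaining)),
                   key=lambda j: (mean_sim[j], remaining[j].synthon_id))
        chosen = remaining.pop(best)
        sim_sum = np.delete(sim_sum, best)
        selected.append(chosen)
        if remaining:
            sim_sum = sim_sum + np.array(
                bulk_tanimoto(chosen.fingerprint,
                              [c.fingerprint for c in remaining]))
    return selected


def _reaction_fps(reaction: ReactionRecord) -> list:
    return [s.fingerprint for pos in reaction.positions for s in pos]


def diversity_select_reactions(library: CombinatorialLibrary, n: int,
                               rng: np.random.Generator) -> list:
    """Greedy minimum-mean-cross-similarity subset of reactions.

    A reaction's distance to the selected set is the mean Tanimoto
    similarity between all of its fragments and all fragments of the
    already-selected reactions; the reaction with the lowest mean is added
    until n are chosen.
    """
    if not 1 <= n <= len(library.reactions):
        raise ValueError(
            f"cannot select {n} from {len(library.reactions)} reactions")
    remaining = list(library.reactions)
    selected = [remaining.pop(int(rng.integers(len(remaining))))]
    while len(selected) < n:
        selected_fps = [fp for r in selected for fp in _reaction_fps(r)]
        means = []
        for r in remaining:
            sims = [s for fp in _reaction_fps(r)
                    for s in bulk_tanimoto(fp, selected_fps)]
            means.append(float(np.mean(sims)))
        best = min(range(len(remaining)),
                   key=lambda j: (means[j], remaining[j].reaction_id))
        selected.append(remaining.pop(best))
    return selected


# ---------------------------------------------------------------------------
# Pre-docked benchmark
# ---------------------------------------------------------------------------

@dataclass
class PredockedBenchmark:
    library: CombinatorialLibrary  # the reduced library
    score_table: pd.DataFrame  # one row per enumerated genotype
    hit_quantile: float
    hit_threshold: float  # worst score still inside the hit set
    hit_keys: frozenset  # molecule keys of the hit set

    @property
    def n_products(self) -> int:
        return len(self.score_table)

    @property
    def n_hits(self) -> int:
        return hit_count(self.n_products, self.hit_quantile)


def score_enumerated_library(
    library: CombinatorialLibrary,
    backend: FitnessBackend,
    lid_n: int = 2,
) -> pd.DataFrame:
    """Assemble and score every enumerable product of a library.

    Assembly or backend failures are logged and excluded from the
    hit-eligible set (score = NaN) instead of aborting the sweep.
    """
    rows = []
    for reaction in library.reactions:
        for genotype in enumerate_genotypes(reaction):
            row = {
                "reaction_id": genotype.reaction_id,
                "synthon_ids": "|".join(genotype.synthon_ids),
            }
            try:
                product = assemble_product(genotype, library)
                raw = float(backend.evaluate(product))
                row.update(
                    canonical_smiles=product.canonical_smiles,
                    raw_energy=raw,
                    score=lid_rootn(raw, product.heavy_atoms, lid_n),
                )
            except Exception as exc:  # assembly or backend failure
                logger.warning("excluding %s from benchmark: %s", genotype, exc)
                row.update(canonical_smiles=None, raw_energy=math.nan,
                           score=math.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def build_predocked_benchmark(
    library: CombinatorialLibrary,
    backend: FitnessBackend,
    n_reactions: int,
    n_fragments: int,
    hit_quantile: float = 0.001,
    rng: Optional[np.random.Generator] = None,
    lid_n: int = 2,
) -> PredockedBenchmark:
    """Reduce a library by diversity selection, enumerate it exhaustively,
    score every product, and mark the best ``hit_quantile`` as virtual hits.

    Fragment lists are diversity-reduced for every reaction and position
    first, then the most mutually dissimilar ``n_reactions`` reactions are
    kept; this ordering reduces every candidate reaction on equal footing
    before any is discarded.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reduced = []
    for reaction in library.reactions:
        positions = [
            diversity_select_fragments(list(pos), min(n_fragments, len(pos)), rng)
            for pos in reaction.positions
        ]
        reduced.append(ReactionRecord(reaction_id=reaction.reaction_id,
                                      smarts=reaction.smarts,
                                      positions=positions))
    reduced_library = CombinatorialLibrary(
        reactions=reduced, fingerprint_config=library.fingerprint_config)
    chosen = diversity_select_reactions(reduced_library, n_reactions, rng)
    final_library = CombinatorialLibrary(
        reactions=chosen, fingerprint_config=library.fingerprint_config)

    table = score_enumerated_library(final_library, backend, lid_n=lid_n)
    n_hits = hit_count(len(table), hit_quantile)
    scored = table.dropna(subset=["score"]).sort_values(
        ["score", "canonical_smiles"])
    hits = scored.head(n_hits)
    return PredockedBenchmark(
        library=final_library,
        score_table=table,
        hit_quantile=hit_quantile,
        hit_threshold=float(hits["score"].max()),
        hit_keys=frozenset(hits["canonical_smiles"]),
    )


def random_baseline(
    library: CombinatorialLibrary,
    n: int,
    rng: np.random.Generator,
    backend: FitnessBackend,
    lid_n: int = 2,
) -> pd.DataFrame:
    """Score ``n`` independent product-weighted random draws (duplicates
    allowed — the baseline models what a screening campaign would sample,
    not a deduplicated set)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = []
    for _ in range(n):
        genotype = sample_random_genotype(library, rng)
        product = assemble_product(genotype, library)
        raw = float(backend.evaluate(product))
        rows.append({
            "reaction_id": genotype.reaction_id,
            "synthon_ids": "|".join(genotype.synthon_ids),
            "canonical_smiles": product.canonical_smiles,
            "raw_energy": raw,
            "score": lid_rootn(raw, product.heavy_atoms, lid_n),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture library generator
# ---------------------------------------------------------------------------

_REACTIONS = {
    "amide": "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]",
    "sulfonamide": "[S:1](=[O:2])(=[O:3])[OX2H1].[NX3;H2,H1;!$(NC=O):4]"
                   ">>[S:1](=[O:2])(=[O:3])[N:4]",
    "ester": "[C:1](=[O:2])[OX2H1].[OX2H1:3][#6:4]>>[C:1](=[O:2])[O:3][#6:4]",
    "ether": "[CX4:1][Br].[OX2H1:2][#6:3]>>[CX4:1][O:2][#6:3]",
}

# Position 0 / position 1 reagent families per reaction.
_FAMILIES = {
    "amide": ("acid", "amine"),
    "sulfonamide": ("sulfonic_acid", "amine"),
    "ester": ("acid", "alcohol"),
    "ether": ("alkyl_bromide", "alcohol"),
}

_SUBSTITUENTS = ["F", "Cl", "Br", "C", "CC", "OC", "C(F)(F)F", "C#N", "N",
                 "OCC", "C(C)C", "CCC"]
_TAILS = ["C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCO", "CCN", "CCCN",
          "C1CC1", "CC1CC1", "C1CCC1", "CC=C", "CCF", "CC(C)(C)C", "CCCl"]


def _aryl_variants(core: str) -> list:
    # core must contain one "{sub}" slot on an aromatic ring
    return [core.format(sub=s) for s in _SUBSTITUENTS]


def _family_candidates(family: str) -> list:
    """Deterministic candidate SMILES pool for one reagent family."""
    if family == "acid":
        plain = [f"OC(=O){t}" for t in _TAILS] + ["OC(=O)c1ccccc1",
                                                  "OC(=O)c1ccncc1",
                                                  "OC(=O)c1ccco1",
                                                  "OC(=O)c1cccs1"]
        aryl = (_aryl_variants("OC(=O)c1ccc({sub})cc1")
                + _aryl_variants("OC(=O)c1cccc({sub})c1")
                + _aryl_variants("OC(=O)c1ccc({sub})cn1")
                + _aryl_variants("OC(=O)Cc1ccc({sub})cc1")
                + _aryl_variants("OC(=O)CCc1ccc({sub})cc1"))
        return plain + aryl
    if family == "sulfonic_acid":
        plain = [f"OS(=O)(=O){t}" for t in _TAILS] + ["OS(=O)(=O)c1ccccc1",
                                                      "OS(=O)(=O)c1ccco1"]
        aryl = (_aryl_variants("OS(=O)(=O)c1ccc({sub})cc1")
                + _aryl_variants("OS(=O)(=O)c1cccc({sub})c1")
                + _aryl_variants("OS(=O)(=O)Cc1ccc({sub})cc1"))
        return plain + aryl
    if family == "amine":
        plain = [f"N{t}" for t in _TAILS] + ["NCc1ccccc1", "NCCc1ccccc1",
                                             "Nc1ccccc1", "NC1CCCCC1",
                                             "NCc1ccco1", "NCc1cccs1",
                                             "NCc1ccncc1"]
        aryl = (_aryl_variants("NCc1ccc({sub})cc1")
                + _aryl_variants("NCCc1ccc({sub})cc1")
                + _aryl_variants("Nc1ccc({sub})cc1")
                + _aryl_variants("NCc1cccc({sub})c1"))
        return plain + aryl
    if family == "alcohol":
        plain = [f"O{t}" for t in _TAILS] + ["OCc1ccccc1", "OCCc1ccccc1",
                                             "OC1CCCCC1", "OCc1ccco1",
                                             "OCc1ccncc1"]
        aryl = (_aryl_variants("OCc1ccc({sub})cc1")
                + _aryl_variants("OCCc1ccc({sub})cc1")
                + _aryl_variants("OCc1cccc({sub})c1"))
        return plain + aryl
    if family == "alkyl_bromide":
        plain = [f"BrC{t}" for t in _TAILS] + ["BrCc1ccccc1", "BrCCc1ccccc1",
                                               "BrCC1CCCCC1"]
        aryl = (_aryl_variants("BrCc1ccc({sub})cc1")
                + _aryl_variants("BrCCc1ccc({sub})cc1")
                + _aryl_variants("BrCc1cccc({sub})c1"))
        return plain + aryl
    raise ValueError(f"unknown reagent family {family!r}")


def _valid_family_pool(family: str, reaction_name: str, position: int) -> list:
    """Parse-checked, template-checked, deduplicated candidate SMILES."""
    rxn = reaction_from_smarts(_REACTIONS[reaction_name])
    template = rxn.GetReactantTemplate(position)
    seen, pool = set(), []
    for smiles in _family_candidates(family):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or not mol.HasSubstructMatch(template):
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        pool.append(smiles)
    return pool


def generate_fixture_library(
    out_dir,
    n_reactions: int = 4,
    n_per_position: int = 20,
    seed: int = 0,
) -> tuple:
    """Write a deterministic toy library emulating commercial synthon files.

    Builds ``n_reactions`` (2-4) robust two-component couplings with
    ``n_per_position`` procedurally decorated reagents per position and
    writes the two tab-separated files the loader expects.  The same seed
    always produces byte-identical files.  Returns (reactions_path,
    reagents_path).
    """
    if not 2 <= n_reactions <= len(_REACTIONS):
        raise ValueError(
            f"n_reactions must be between 2 and {len(_REACTIONS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reaction_names = list(_REACTIONS)[:n_reactions]

    reagent_rows = []
    for name in reaction_names:
        for position, family in enumerate(_FAMILIES[name]):
            pool = _valid_family_pool(family, name, position)
            if len(pool) < n_per_position:
                raise ValueError(
                    f"family {family!r} has only {len(pool)} valid reagents; "
                    f"{n_per_position} requested")
            picks = rng.choice(len(pool), size=n_per_position, replace=False)
            for i, idx in enumerate(sorted(int(p) for p in picks)):
                reagent_rows.append({
                    "smiles": pool[idx],
                    "synthon_id": f"{name}_p{position}_{i:04d}",
                    "reaction_id": name,
                    "position": position,
                })

    reactions_path = out_dir / "reactions.tsv"
    reagents_path = out_dir / "reagents.tsv"
    pd.DataFrame(
        [{"reaction_id": name, "smarts": _REACTIONS[name], "n_positions": 2}
         for name in reaction_names]
    ).to_csv(reactions_path, sep="\t", index=False)
    pd.DataFrame(reagent_rows).to_csv(reagents_path, sep="\t", index=False)
    return reactions_path, reagents_path
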