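# Methods

## Model

A combinatorial make-on-demand library is modeled as a set of reactions,
each a reaction SMARTS with k ≥ 2 reactant templates and k ordered lists of
synthons (building-block SMILES with their reaction handles intact). A
molecule is identified by its genotype `(reaction_id, synthon_ids)`; the
product is obtained by running the reaction SMARTS on the ordered synthons
with RDKit and canonicalizing. If the SMARTS admits several product
candidates (multiple template matches), the lexicographically smallest
canonical SMILES is kept, making assembly a pure function. Stereochemistry
and protonation are ignored throughout; molecules are keyed by canonical
SMILES of the input connectivity.

All similarity logic — mutation windows, duplicate penalties, diversity
selection — uses Morgan (extended-connectivity) fingerprints, radius 2,
2048 bits, computed once per synthon at load time and once per assembled
product. The parameters are configurable but pinned by default so that
every threshold in the protocol means the same thing across runs. Tanimoto
similarity of two all-zero fingerprints is defined as 1.0 (they are
indistinguishable); RDKit's convention of 0.0 is overridden.

## Fitness

Backends map an assembled product to a raw interface-energy-like score,
lower = better. Selection acts on the size-normalized fitness

    fitness_n(x) = energy(x) / heavyatoms(x)^(1/n),   n ∈ {1, 2, 3, 4}

with n = 2 by default. n = 1 is ligand efficiency per heavy atom; larger n
weakens the size penalty. The n = 2 default is the geometric mean of total
energy and ligand efficiency and counteracts the additive-score bias toward
ever larger molecules without over-rewarding fragments.

Within each evaluated population a duplicate penalty is applied best-first:
individuals are sorted by pre-penalty fitness (ties broken by molecule
key), each is compared against all already-stored fingerprints, and gains
+0.5 per stored fingerprint with Tanimoto similarity strictly greater than
0.95; its own fingerprint is then stored. Three identical copies therefore
receive 0 / 0.5 / 1.0. Selection uses the effective score
`fitness + penalty` everywhere, including the elitist identity step —
the penalty exists to prevent population takeover, so exempting any
selector would defeat it.

Scores are cached by canonical SMILES: a molecule seen in any earlier
generation, or duplicated within a population, costs no backend call.
Assembly or backend failures do not abort a run; the individual is assigned
a sentinel fitness 10 units above the worst successful fitness in its
population, which reliably removes it from selection while keeping the
evolutionary loop total.

## Selectors

* **Elitist** — deterministic k-best by effective score.
* **Tournament** (default main selector: size 15, acceptance 0.75, k = 50,
  without replacement) — entrants are drawn uniformly, ranked, and walked
  best-first, each accepting with probability 0.75; if all decline the best
  entrant is taken, so every tournament yields exactly one selection. The
  implied winner-rank law is geometric, `P(rank r) = 0.75·0.25^(r−1)`, plus
  the all-decline mass on rank 1.
* **Roulette** — fitness-proportional selection is ill-defined for negative
  scores, so weights are linear distances from an anchor (default: the
  pool's worst effective score) plus a floor of 0.01 × span so the worst
  individual keeps a nonzero chance: `w_i = (anchor − s_i) + 0.01·span`.
  With an explicit anchor the intuitive proportionality holds (scores −4
  and −2 against anchor 0 select ≈ 2:1); with the default anchor the
  selector is sharper, which is what the reproduction steps want. All-equal
  scores degrade to uniform. Sampling is without replacement within a call.

## Reproduction

* **Fragment mutation** — one position uniform; alternatives at that
  position filtered to a Tanimoto window against the current synthon and
  sampled with similarity as weight. An empty window is widened rather than
  erroring (max bound dropped first, then min); a position with no
  alternatives is a logged no-op. The [0.6, 1] window makes refinements;
  the [0, 0.25] window forces scaffold-level changes at one position.
* **Reaction mutation** — a different reaction chosen uniformly; each new
  position is filled with the synthon maximizing Tanimoto similarity to the
  old fragment at the same index (new positions beyond the old arity match
  against all old fragments). The fill is a deterministic argmax with ties
  broken by synthon id.
* **Crossover** — one parent donates the reaction; positions are
  partitioned randomly with each parent contributing at least one fragment
  (two-component reactions: exactly one each). Fragments from a
  different-reaction parent are mapped into the donor's position lists by
  the same argmax-similarity search.

Offspring are genotypes of the library by construction (closure), which is
the synthesizability guarantee of the whole method.

## The generation loop

Defaults: 200 initial individuals, 50 survivors, 30 generations, the
seven-step protocol described in the README. "Fragment twice as often as
reaction" in the mixed mutation steps is a per-offspring categorical draw
with P(fragment) = 2/3. Mutator steps cycle their 15 parents round-robin
(each parent used twice for 30 offspring); crossover steps draw a random
parent pair per offspring. The identity step copies its 15 elites with
scores and penalties bit-exact and removes them from the reproduction pool,
so the two closing steps select from a best-depleted pool and worse
lineages advance. The next generation's candidates are the 240 newly
evaluated offspring plus the 15 identity copies; the previous population
survives only through the identity step. Per generation, the duplicate
penalty is computed within the newly evaluated offspring population;
identity copies keep theirs.

Accounting is exact: evaluated individuals = initial + generations × Σ
non-identity offspring = 200 + 30 × 240 = 7,400 with defaults. One seeded
`numpy` Generator drives sampling, selection and reproduction in protocol
order, so a run is replayable bit-for-bit from its seed; the CLI refuses
configurations without an explicit seed.

## Benchmarking

The pre-docked benchmark reduces a library to a space small enough to
enumerate: every reaction's position lists are first reduced by greedy
diversity selection (seed one random fragment, then repeatedly add the
candidate with the lowest mean Tanimoto similarity to the selected set),
then the n most mutually dissimilar reactions are kept by the same greedy
rule applied to whole fragment sets. Minimum-similarity selection
deliberately produces a rugged landscape — the hard case for a similarity-
guided search. Every product is then assembled and scored, and the best
`hit_quantile` (default 0.1%, count rounded half-up) are marked as virtual
hits, so search trajectories can be compared against the known global
optimum.

Hit rates use a strict `score < x` comparison. The enrichment factor is the
ratio of hit rates between a method and a product-count-weighted random
sample (duplicates allowed — the baseline models what a campaign would
actually draw, and both samplers share one distribution, which is what
makes EF a like-for-like comparison). A threshold where the baseline has
zero hits but the method has some yields an explicitly flagged non-finite
EF rather than an exception or a clamped value.

## Surrogate backend

The deterministic surrogate stands in for a docking scorer in tests and
demos. Each on-bit of the product fingerprint (a circular substructure)
contributes a fixed hash-derived value in [−1, 1); the sum normalized by
√(bit count) gives a rugged but locally correlated landscape — molecules
sharing substructures score alike, the property a similarity-guided search
exploits and a hash-random landscape would lack. Scores are centered at
−12 with weight 4 on the substructure term and a mild −0.05 per heavy
atom, landing in a docking-like range of roughly −22 to −3. It is exactly
reproducible across runs and platforms; a seed parameter reshuffles the
landscape.

What the surrogate does not emulate: the heavy-tailed noise of replicate
docking, activity cliffs uncorrelated with 2D fingerprints, and any
protein-specific structure. Results on the toy spaces therefore demonstrate
the search mechanics (closure, accounting, enrichment over random under a
correlated landscape), not docking performance on a real target.

## Problem sizes and numerical choices

The shipped fixture generator builds 2–4 robust couplings (amide,
sulfonamide, ester, ether) with procedurally decorated reagents; the
default benchmark space is 4 × 20 × 20 = 1,600 products, chosen so that
exhaustive enumeration (the oracle for every search experiment) is
instantaneous while the space remains large enough that a 7,400-draw
random sample does not trivially cover its top 0.1%. Statistical tests on
selector frequencies use 20,000–50,000 draws at α = 0.001 against
closed-form or exhaustively enumerated oracles.

Tie-breaks are lexicographic by molecule or synthon key everywhere a
deterministic order is needed (elitist cuts, argmax fills, penalty order).
Rounding of quantile hit counts is half-up. The failure sentinel (+10) and
the roulette weight floor (0.01 × span) are pragmatic constants: the first
only needs to dominate every real score, the second only needs to keep
weights strictly positive without distorting the stated proportionality.

## Known limitations

Single-host execution only (evaluation is a pure per-molecule function and
trivially parallelizable, but no distribution layer is shipped). No
stereochemistry, tautomer or protonation handling. Reaction mutation's
index-based position pairing is a heuristic that can mismatch chemically
analogous positions between reactions of different layout. The enrichment
analysis assumes the score is a perfect oracle above its threshold, as is
conventional for in-silico benchmarks.
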