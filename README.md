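# evoscreen

Evolutionary screening of reaction-defined (make-on-demand) combinatorial
chemical libraries.

Commercial make-on-demand catalogs (Enamine REAL and its peers) define
billions of purchasable molecules implicitly: a few hundred reactions, each
with lists of building blocks ("synthons") per reagent position. Exhaustive
docking of such a space is hopeless when the scoring function is expensive,
and most generative approaches propose molecules nobody can synthesize.
`evoscreen` searches the combinatorial space directly with an evolutionary
algorithm whose individuals *are* library members: each genotype is a
`(reaction, ordered synthon list)` pair, so every molecule the search ever
proposes is synthesizable by construction, and the number of expensive score
evaluations stays fixed (7,400 per run with defaults) regardless of library
size.

It is aimed at computational chemists who want to plug an expensive scoring
function — a docking protocol, an ML scorer, a lookup table of precomputed
energies — behind a small backend interface and get back an enriched,
synthesizable hit list.

## The algorithm

A run starts from 200 random genotypes (reaction drawn with probability
proportional to its product count, synthons uniform per position). Each
generation applies seven reproduction steps to the 50 survivors:
similarity-guided fragment mutations (Tanimoto-weighted replacement within a
[0.6, 1] window), drastic low-similarity mutations (window [0, 0.25]),
reaction swaps with maximal-similarity fragment mapping, two rounds of
crossover, and an elitist identity step that carries the 15 best forward
unchanged while removing them from the reproduction pool so weaker lineages
also get to reproduce. A tournament selector (size 15, acceptance 0.75)
reduces the candidates back to 50.

Raw scores are interface energies (lower = better), normalized for molecular
size by

    fitness_n(x) = energy(x) / heavyatoms(x)^(1/n)

with n = 2 by default ("lid_root2", the geometric mean of total energy and
per-heavy-atom ligand efficiency). Within a population, near-duplicate
molecules (fingerprint Tanimoto > 0.95) accumulate a +0.5 penalty per
already-stored copy — three identical copies score +0, +0.5, +1.0 — which
prevents takeover by a single good scorer while still letting it amplify its
genes. Duplicates are cached and never re-scored.

Performance is measured as in virtual screening: for a score threshold x,
`HitRate(x)` is the fraction of sampled molecules scoring strictly below x,
and the enrichment factor `EF(x)` is the method's hit rate divided by that
of a product-count-weighted random sample of the same space.

## Worked example

Generate a deterministic toy library (4 two-component couplings — amide,
sulfonamide, ester, ether — with 20 decorated reagents per position, i.e.
1,600 products), run the default protocol against the built-in deterministic
surrogate scorer, and compare against an equal-budget random sample:

```
$ evoscreen fixtures --n-reactions 4 --n-per-position 20 --seed 7 --out lib
$ printf 'seed: 1\n' > config.yaml
$ evoscreen run --config config.yaml --reactions lib/reactions.tsv \
    --reagents lib/reagents.tsv --backend surrogate --out run1
run complete: 7400 individuals, 608 distinct molecules, best fitness -5.557
```

7,400 individuals is the exact accounting of the default protocol (200
initial + 30 generations x 240 offspring); only 608 distinct molecules were
scored because duplicates are cached. `run1/generations.csv` tracks the
Fig.-1-style score trajectory — best, 10th, 100th and median fitness over
everything evaluated so far:

```
generation,n_evaluated,best,top10,top100,median
0,200,-4.166,-3.473,-2.627,-2.626
1,440,-5.557,-4.491,-3.301,-2.829
...
30,7400,-5.557,-5.557,-5.557,-4.003
```

The global optimum of this 1,600-molecule space (fitness −5.557, findable by
exhaustive enumeration) is discovered in generation 1 here and held by the
identity step. Enrichment over a 7,400-draw random sample:

```
$ evoscreen enrich --method run1/individuals.csv --baseline baseline.csv \
    --score-column fitness --quantiles 0.001,0.01 --out enrich.csv
x=-5.3192  method 526 hits (0.07108)  baseline 5 hits (0.00068)  EF=105
x=-4.4288  method 2852 hits (0.38541)  baseline 71 hits (0.00959)  EF=40.2
```

At the baseline's top-0.1% score threshold the evolutionary sample contains
105× the hit fraction of random screening — the population has converged
onto the best-scoring region of the space.

The same workflow scales to a pre-docked benchmark: `evoscreen benchmark`
diversity-selects a reduced library (greedy minimum-mean-similarity over
fragments, then over reactions), enumerates and scores every product, and
marks the best 0.1% as virtual hits so that search trajectories can be
compared against a known global optimum.

## Library file formats

Tab-separated with headers — reactions: `reaction_id`, `smarts`
(reaction SMARTS, ≥ 2 reactant templates), `n_positions`; reagents:
`smiles`, `synthon_id`, `reaction_id`, `position` (0-based). Score tables
are CSV (`canonical_smiles`, `raw_energy`). See `docs/methods.md` for the
model details and design choices.
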