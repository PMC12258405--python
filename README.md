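# retroprompt

Human-guided multistep retrosynthesis planning via bond prompting.

AI retrosynthesis planners recursively decompose a target molecule into
purchasable building blocks, but out of the box they ignore the prior
knowledge of the chemist who will run the reactions: which bonds *should*
be disconnected somewhere in the route, and which bonds must survive every
step.  That knowledge is decisive when, for example, a series of analogues
shares a common disconnection site and the goal is a joint synthesis plan.

`retroprompt` lets the user annotate a target with two kinds of prompts:

* **bonds to break** — disconnections the routes should make, identified by
  pairs of atom-map numbers on the target SMILES (or with a `!` tag dialect,
  `CC(=O)!N!C`).  These are *soft* constraints: they bias search and ranking
  but never discard predictions.
* **bonds to freeze** — bonds that must remain intact in every reaction.
  These are *hard* constraints, enforced by a filter that discards any
  single-step prediction that would break one.

## The model

Routes are bipartite reaction trees rooted at the target; a route is
*solved* when every leaf is in the stock of purchasable building blocks.
Search is Monte-Carlo tree search over single-step retro predictions from a
retro-template library with prior weights, with atom maps propagated through
every step so the prompts stay anchored.

Two route objectives drive everything:

* the **state score** `0.95·f + 0.05·g(L)`, where `f` is the fraction of
  leaf molecules in stock and `g` a decreasing logistic squash of the route
  length `L` with `g(0) = 1` — it favours short, solved routes;
* the **broken bonds score**: given prompted bonds `B`, each bond broken by
  a reaction at depth `d(r)` (the first reaction has depth 0) earns credit
  `(D_max − d(r))/D_max`; bonds left unbroken contribute one joint term
  worth breaking at the maximum depth `D_max` (i.e. zero); the sum is
  normalised by the number of productive components (`|B|` when every
  prompted bond is broken, otherwise `n_broken + 1`).  The score is 1
  exactly when all prompted bonds break in the first reaction and 0 exactly
  when none break.

Five strategies combine them:

| strategy | search | expansion | route ranking |
|---|---|---|---|
| `standard` | MCTS (state) | template policy | state score |
| `route-ranking` | MCTS (state) | template policy | ½ state + ½ broken bonds |
| `mo-search` | MO-MCTS (state, broken bonds) | template policy | Pareto front |
| `da` | MCTS (state) | multi-expansion with disconnection-guaranteed policy | state score |
| `da-mo` | MO-MCTS | multi-expansion | Pareto front |

The multi-objective search backs up vector rewards, selects children by
Pareto dominance on per-objective mean-plus-UCB values, and extracts the
non-dominated front of routes.  The disconnection-aware expansion handles
each prompted bond separately and only proposes steps guaranteed to break
it, concatenated with the template policy at equally weighted priors.

Route sets are compared with a similarity in [0, 1] built from disconnected
target-atom pairs (Jaccard) and the agreement of leaf-induced target-atom
partitions; dissimilarity to a reference set is `γ = 1 − ζ_max` and
within-set diversity `κ = 1 − ζ_min`.

## Worked example

```bash
python examples/score_worked_examples.py
```

```
bonds to break: [(2, 3), (4, 5), (6, 7)]  (D_max = 21)
route 1: 2 reactions; prompted bonds broken at depths [0, 1], missed [(6, 7)] -> score 0.65
route 2: 5 reactions; prompted bonds broken at depths [2, 3, 4] -> score 0.86
route 3: 6 reactions; prompted bonds broken at depths [0, 2, 3] -> score 0.92
```

Three routes take apart the same chain: the first misses a prompted bond
(penalised as if it broke at the maximum depth), the second breaks all three
but late, the third starts with a prompted cut — more prompted bonds broken,
earlier, means a higher score.

Planning from Python:

```bash
python examples/plan_with_bond_prompts.py
```

```
target: CCC(=O)Nc1ccc(-c2ccccc2)cc1
bonds to break [(1, 3)], freeze [(7, 8)]
#1: 1 reactions, state=0.999, broken-bonds=1.000, solved=True, constraints satisfied=True
    starting material: CCC(=O)O (in stock: True)
    starting material: Nc1ccc(-c2ccccc2)cc1 (in stock: True)
```

The top route disconnects the prompted amide bond in its first reaction
(broken-bonds score 1.0) without touching the frozen biaryl bond, and both
precursors are purchasable.

The same workflow is available from the shell:

```bash
retroprompt plan "[CH3:10][C:1](=[O:2])[NH:3][CH3:11]" \
    --library library.json --stock stock.smi --break 1-3
retroprompt benchmark generate --out fixture/ --n-targets 20 --seed 1
retroprompt benchmark run --fixture fixture/ --strategy standard --strategy mo-search
retroprompt score route.json --break 2-3 --break 4-5 --d-max 21
```

`examples/benchmark_strategies.py` compares strategies on a synthetic
benchmark whose constraint-satisfying routes are deliberately longer than
the shortest solved route, and `examples/route_metrics.py` demonstrates the
γ/κ route metrics.

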