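# Methods

This note documents the models, scores and design choices behind
`retroprompt`, the assumptions they rest on, and what the synthetic
benchmark does and does not demonstrate.

## Bond prompts and their semantics

Constraints are anchored to atom-map numbers on the target: a bond
constraint is an unordered pair of map numbers, and maps are propagated
through every retro step (via the template atom correspondence), so the same
pair identifies the same bond throughout a route.  A bond `(i, j)` counts as
*broken* by a retro step when it is present in the product but absent from
every single reactant — including the case where `i` and `j` end up in
different reactants.  A change of bond order with the bond retained is *not*
a disconnection: the constraint language is about connectivity, so a frozen
bond whose order changes but persists is not violated.  Unmapped atoms never
participate in constraint logic.

*Bonds to freeze* are hard constraints, enforced by filtering every
violating prediction before it enters the search; consequently no reachable
search state, and no extracted route, can break a frozen bond (this is
asserted end-to-end in the test suite).  *Bonds to break* are soft: hard
filtering on them would forbid the unrelated disconnections that routes need
before or after the prompted ones, and partially satisfying routes are still
useful output.

## State score

`state = 0.95·f + 0.05·g(L)` with `f` the in-stock fraction of leaf
molecules and `g(L) = (1 + e^{−4}) / (1 + e^{L−4})` a logistic squash of the
number of reactions `L`, rescaled so that `g(0) = 1` and therefore a target
already in stock scores exactly 1.  The midpoint (4 reactions) and weights
follow the common planner convention of rewarding mostly solvability with a
mild preference for short routes; both are constants in `scoring.py` and
trivially adjustable.

## Broken bonds score

Given prompted bonds `B` and a route, let `B_b ⊆ B` be the bonds broken by
some reaction and `d(r) ∈ {0, 1, …}` the depth of the reaction breaking each
(0 = the reaction applied directly to the target).  Each broken bond earns
`(D_max − d(r)) / D_max`; if `B_b ≠ B` the unbroken remainder contributes a
single joint penalty term equal to the credit of breaking at the maximum
depth, `(D_max − D_max)/D_max = 0`.  The sum is divided by the number of
productive components: `|B|` when all bonds are broken, `|B_b| + 1`
otherwise.  Consequences used as test oracles: the score is exactly 1 iff
every prompted bond breaks at depth 0, exactly 0 iff none breaks, moving a
breaking reaction one level shallower strictly increases the score, and
breaking more of the prompted bonds at equal depths never decreases it.

`D_max` is the configured maximum search depth, not the realised depth of
the route being scored, so scores are comparable across all routes of one
search.  The three worked-example routes shipped with the package
(`benchmark.illustration_routes`) are synthetic stand-ins constructed on an
eight-atom chain and evaluated with `D_max = 21`; at two decimals they score
0.65 (two of three prompted bonds broken, at depths 0 and 1), 0.86 (all
three, at depths 2–4) and 0.92 (all three, first cut at depth 0).

## Search

Single-objective MCTS follows the usual select / expand / evaluate /
backpropagate loop with immediate state evaluation as the reward (no rollout
phase).  The state is the multiset of frontier molecules with per-branch
depths; expanding applies one filtered prediction to one frontier molecule.
Selection maximises mean value plus a UCB exploration bonus
(`c = 1.4` by default).  The search never stops at the first solution; it
runs to the iteration or time budget (defaults 100 iterations / 300 s) and
all solved states plus search-tree leaves become extraction candidates.

The multi-objective variant backs up reward *vectors* — (state score,
broken bonds score of the partial route) — and keeps per-objective running
means.  Child selection computes mean-plus-UCB per objective and picks
uniformly at random (seeded) among the Pareto-non-dominated children.  This
dominance-UCB rule is a documented stand-in for whichever acquisition the
surrounding literature uses; it is deliberately simple, reproducible under a
seed, and swappable.  Pareto machinery uses non-strict dominance for
maximisation (`p` dominates `q` iff `p ≥ q` componentwise and `p ≠ q`), so
duplicated vectors share a rank; ranks are peeled iteratively and verified
against an independent brute-force oracle in the tests.

Route extraction deduplicates on a canonical serialization of the reaction
tree.  `standard` returns the top-n by state score, `route_ranking` the
top-n by the equal-weight combined score `0.5·state + 0.5·broken_bonds`
(ranking only — the search itself is unchanged), and `mo_front` the entire
primary Pareto front padded from lower ranks up to n.  With a fixed seed
searches are bit-reproducible, and for the single-objective search the first
k iterations of a longer run coincide with a k-iteration run, so the best
extracted state score is monotone in the iteration budget.

## Expansion policies

The ranked template policy applies every retro template (mapped reaction
SMARTS with a prior weight), normalises weights over the successful
applications for that molecule and returns the top-k (default 50).  The
disconnection-guaranteed policy emulates the behavioural contract of a
prompt-conditioned single-step model without trained weights: it is applied
only when the molecule contains prompted bonds, handles each prompted bond
separately, returns up to `beam` (default 5) predictions whose broken set
covers that bond, and labels its output.  The multi-expansion strategy
concatenates both policies with per-policy normalised priors weighted
equally, resolves ties deterministically (template predictions first, then
lexicographic on canonical reactant SMILES) and deduplicates identical
reactant multisets keeping the higher-prior copy.  Per-policy prior
normalisation is one reading of "equally weighted" mixing; it is a policy
detail, not load-bearing for any guarantee.

## Route similarity, γ and κ

Two routes to the same target are compared by (a) the Jaccard overlap of
the sets of target-atom pairs they disconnect and (b) the agreement of the
partitions of target atoms induced by their leaf molecules — each leaf group
matched to its best Jaccard counterpart in the other route, summed both
ways — normalised by the *total* molecule count of both routes (roots and
intermediates included).  The similarity is the mean of the two components.
Because intermediates enter the normalisation but not the leaf matching, the
self-similarity of a multi-molecule route is strictly below one; this quirk
is intentional, documented behaviour of the metric family this approximates
and is reproduced in the tests.  Dissimilarity to a reference set is
`γ = 1 − ζ_max` (average maximum similarity of each route to the reference)
and diversity `κ = 1 − ζ_min` (average minimum similarity within the set).
One subtlety: because κ averages per-route minima, duplicating a route adds
a new low term and can shift κ; the monotone quantity is each route's own
minimum similarity, and that is what the suite asserts.  Exact agreement
with any particular published route-distance implementation is a non-goal;
the contract here is the stated one.

## Synthetic benchmark

The generator composes targets *forward* from a ~27-block catalogue through
six classic couplings (amide, ester, Suzuki biaryl, Williamson ether, SNAr
amination, reductive amination), tracking atom maps through explicit
molecular surgery, so every target carries a planted reference route that is
solved against the generated stock by construction.  The retro-template
library contains the corresponding six retro SMARTS, so the planted routes
are rediscoverable by search; deliberately permissive patterns (e.g. any
biaryl single bond for the Suzuki retro) add realistic decoy disconnections.

Bond constraints are extracted from the reference route: bonds to break are
taken one per reaction from the reactions with the highest convergent
disconnection score — `CDS = 1 − (max_i a_i − min_i a_i)/Σ a_i` over
reactant heavy-atom counts, 0 for single-reactant steps, a surrogate that
preserves the "prefer roughly equal-sized splits" ordering — and bonds to
freeze are sampled (seeded) from the target bonds untouched along the whole
route.  Freezing only unchanged bonds guarantees at least one solved,
satisfying route exists (the reference); fewer bonds are frozen than broken
(default: sample 1–3 breaks, freeze 1) to keep the focus on the
disconnection strategies.  The "hidden disconnection" recipe additionally
puts the reference intermediates into the stock and prompts the *deepest*
planted disconnection, so a short shortcut route solves every target without
satisfying the prompt — the regime where multi-objective guidance should and
does outperform the standard search direction-wise.

What the benchmark emulates: prompted bonds of varying depth, decoy
disconnections, dead ends, shortcut routes, solvable-by-construction
targets.  What it does not: drug-sized molecules, noisy single-step model
priors, stocks of millions of compounds, protecting-group logic or reaction
feasibility.  Passing results therefore demonstrate the correctness of the
constraint machinery, scores and search logic — not absolute performance
numbers on real route datasets, which depend on trained single-step models
and commercial stocks and are out of scope here.

## Problem sizes and defaults

Searches default to 100 MCTS iterations, 300 s time budget, depth 6,
expansion top-50 and beam 5.  The benchmark evaluation aggregates metrics
over batches (default 128 targets per batch; the test suite uses 3–8) and
reports mean ± standard deviation across batches.  The shipped study
conditions use 50-target fixtures at depths 1–3 for route recovery and the
frozen-bond guarantee (5 s per-target budget), and 5 seeds × 8 targets with
30 iterations and top-3 extraction for the directional comparison — small
enough to regenerate everything from scratch in seconds while leaving the
search non-trivial (top-3 extraction is exactly where ranking pressure
matters).

## Numerical choices and degenerate inputs

Ties in priors and rankings always break deterministically (policy order,
then canonical SMILES / route serialization).  The broken bonds scorer
refuses an empty prompted set rather than defaulting, to surface
misconfigured multi-objective runs.  Templates producing unsanitisable
reactants drop that embedding with a warning; a retro step that loses a
tracked map number raises.  Stock membership uses canonical, stereo-aware,
map-free SMILES.  An unexpandable, out-of-stock root yields a root-only
tree flagged unsolved; "unsolved" is a result, not an error, end to end.

## Known limitations

The disconnection-guaranteed policy can only propose disconnections the
template library can express, unlike a generative model.  The MO selection
rule is a stand-in, as noted.  Route similarity approximates its metric
family at the contract level.  The state-score squash constants are
conventions, not fitted values.  Atom-map propagation relies on the
toolkit's reactant-atom bookkeeping and ignores stereochemistry beyond what
SMARTS matching provides.
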