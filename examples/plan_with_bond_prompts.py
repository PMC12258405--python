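"""Plan routes for a prompted target: break one bond, freeze another.

Builds a small template library and stock, asks for routes to an anilide
target while requesting the amide C-N disconnection and freezing the biaryl
bond, then prints each extracted route with its scores.
"""

from retroprompt import parse_target, Stock, mcts_search, extract_routes, SearchConfig
from retroprompt.benchmark import default_template_library
from retroprompt.routes import satisfies_constraints

target, constraints = parse_target(
    "[CH3:20][CH2:21][C:1](=[O:2])[NH:3][c:4]1[cH:5][cH:6][c:7]"
    "(-[c:8]2[cH:9][cH:10][cH:11][cH:12][cH:13]2)[cH:14][cH:15]1",
    break_pairs=[(1, 3)],   # disconnect the amide C-N bond somewhere
    freeze_pairs=[(7, 8)],  # keep the biaryl link intact in every reaction
)
library = default_template_library()
stock = Stock(["CCC(=O)O", "Nc1ccc(-c2ccccc2)cc1", "Nc1ccc(Br)cc1", "OB(O)c1ccccc1"])

tree = mcts_search(target, constraints, library, stock,
                   SearchConfig(iteration_limit=100, time_limit=5.0, seed=0))
records = extract_routes(tree, strategy="standard", n=5)

print(f"target: {target.identity}")
print(f"bonds to break {sorted(constraints.bonds_to_break)}, "
      f"freeze {sorted(constraints.bonds_to_freeze)}")
for rank, rec in enumerate(records, 1):
    ok = satisfies_constraints(rec.tree, constraints)
    print(f"#{rank}: {rec.tree.n_reactions} reactions, "
          f"state={rec.scores['state']:.3f}, "
          f"broken-bonds={rec.scores['broken-bonds']:.3f}, "
          f"solved={rec.tree.is_solved}, constraints satisfied={ok}")
    for leaf in rec.tree.leaves():
        print(f"    starting material: {leaf.mol.identity} (in stock: {leaf.in_stock})")
# A route satisfies the prompt when it breaks the amide bond in some reaction
# and no reaction touches the frozen biaryl bond.
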