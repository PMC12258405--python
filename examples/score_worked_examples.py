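"""The depth-weighted broken bonds score on three alternative routes.

Three synthetic routes disassemble the same eight-atom chain with the same
three prompted bonds to break.  Breaking more of the prompted bonds, and
breaking them earlier in the tree, earns a higher score: the route that
misses one bond scores 0.65, the route that breaks all three late scores
0.86, and the route whose first reaction already makes a prompted cut
scores 0.92.
"""

from retroprompt import broken_bonds_score
from retroprompt.benchmark import illustration_routes

routes, break_set, d_max = illustration_routes()
print(f"bonds to break: {sorted(break_set)}  (D_max = {d_max})")
for i, route in enumerate(routes, 1):
    depths = {}
    for rxn, depth in route.reactions():
        for bond in rxn.broken & break_set:
            depths[bond] = depth
    missed = break_set - set(depths)
    score = broken_bonds_score(route, break_set, d_max)
    print(f"route {i}: {route.n_reactions} reactions; "
          f"prompted bonds broken at depths {sorted(depths.values())}"
          + (f", missed {sorted(missed)}" if missed else "")
          + f" -> score {score:.2f}")
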