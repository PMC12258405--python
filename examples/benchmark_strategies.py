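"""Compare search strategies on a synthetic prompted-bond benchmark.

Generates targets whose constraint-satisfying routes are deliberately longer
than the shortest solved route (reference intermediates are purchasable and
the prompted disconnection sits deepest in the planted route), then compares
how often each strategy returns a solved route that satisfies the prompts.
"""

from retroprompt.benchmark import evaluate, generate_fixture
from retroprompt.search import SearchConfig

library, stock, targets = generate_fixture(
    10, depth_range=(2, 3), seed=7,
    n_break=1, selection="deepest", intermediates_in_stock=True,
)
report = evaluate(
    ["standard", "mo-search", "da-mo"],
    targets, library, stock,
    SearchConfig(iteration_limit=30, time_limit=5.0, seed=0),
    n_routes=3, batch_size=5,
)
print(report.to_frame().to_string(index=False))
# percent_solved counts targets with any solved route; the constrained column
# additionally requires every prompted bond broken and no frozen bond touched.
# The multi-objective strategies keep digging for the prompted disconnection
# instead of stopping at the short shortcut route.
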