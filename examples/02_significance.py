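"""Empirical p-values by input randomization on a random network.

Simulates one deregulated node on a 30-node random signed DAG, then
builds a null distribution of activity scores from R random inputs of
the same shape and reports which nodes' alterations are specific to the
chosen input rather than to deregulating *anything*.
"""

import numpy as np

from perturbsim import (
    InputSpec,
    NetworkRecipe,
    PolarGaussian,
    random_network,
    run_significance,
    run_simulation,
)

graph = random_network(
    NetworkRecipe(n_nodes=30, edge_probability=0.12, inhibition_fraction=0.3,
                  n_pathways=3, seed=8)
)
input_spec = InputSpec(directions={"n000": 1})

rng = np.random.default_rng(1)
observed = run_simulation(graph, input_spec, T=500, gaussian=PolarGaussian(rng))
sig = run_significance(graph, input_spec, observed, R=200, T_inner=50, rng=rng)

print(f"{'id':8s} {'score':>8s} {'p':>6s} {'q':>6s}")
for (level, eid), p in sorted(sig.p_values.items(), key=lambda kv: kv[1]):
    if level != "node":
        continue
    score = observed.nodes[eid].activity_score
    if score == 0 and p > 0.2:
        continue  # untouched nodes are uninteresting here
    print(f"{eid:8s} {score:8.3f} {p:6.3f} {sig.q_values[(level, eid)]:6.3f}")

print(
    "\nNodes downstream of the deregulated input carry non-zero scores; a\n"
    "small p means random inputs of the same shape rarely produce a score\n"
    "of that magnitude there, i.e. the predicted alteration is specific."
)
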