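"""Simulate an up-regulated root on a small signalling cascade.

Builds a depth-2 binary activating cascade (with one inhibiting leaf
edge), marks the root as over-expressed, and runs the Monte-Carlo
simulation: each of T=1000 steps draws a synthetic LogFC for the root
and propagates it to the leaves.
"""

import numpy as np

from perturbsim import InputSpec, PolarGaussian, run_simulation, toy_cascade

graph = toy_cascade(depth=2, branching=2, inhibit_last=True)
input_spec = InputSpec(directions={"root": 1})

result = run_simulation(
    graph, input_spec, T=1000, gaussian=PolarGaussian(np.random.default_rng(0))
)

print(f"{'id':10s} {'level':8s} {'avg P':>8s} {'score':>8s} {'Pr(+1)':>7s} {'Pr(-1)':>7s}")
for rec in result.all_entities():
    pu, pd, _ = rec.probabilities
    print(f"{rec.id:10s} {rec.level:8s} {rec.avg_perturbation:8.3f} "
          f"{rec.activity_score:8.3f} {pu:7.3f} {pd:7.3f}")

print(
    "\nThe average perturbation halves at each level (each node splits its\n"
    "signal over two children); the inhibited leaf d2_003 mirrors its\n"
    "sibling with a negative sign, and every activity score has the sign\n"
    "of the predicted effect with magnitude = log2-odds of that state."
)
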